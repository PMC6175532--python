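"""Self-contained synthetic regulatory scenarios.

The generator builds complete modeling scenarios — enhancer sequence with
planted binding sites, motifs, TF concentration profiles along a spatial
axis, target expression profile, and (where applicable) a planted
ground-truth parameter setting — structurally emulating two
dorso-ventral-patterning systems of the early fly embryo:

* an *ind*-like system: 50 axis bins; five TFs (a graded ventral activator,
  a uniform ubiquitous activator, two ventral repressors and a uniform
  repressor whose action is attenuated in the neuroectodermal bins), one
  activator–activator cooperativity, and a 13-parameter ground-truth model
  whose predicted expression forms a lateral stripe peaking at bin 25 with
  support confined to bins 22–28;

* a *sim*-like system: 25 bins (the ventral half of the axis); two ventral
  activators, a ventral repressor, and a ubiquitous factor whose role
  switches from repressor (dorsally) to activator (ventrally) at the
  mesectoderm — modeled as two complementary single-role species sharing
  one motif; the target is a narrow Gaussian peaked at bin 12.

Scenario realism targets structure, not sequence identity: sequences and
motifs are generated, reproducibly from a seed, rather than taken from any
genome or motif database.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import thermo_model
from .thermo_model import (AnnotatedSite, ModelParameters, Motif, TFSpec,
                           annotate_sites_for_tfs, predict_profile, sse)
from .experiment_evaluation import (PerturbationExperiment, ProfileMatch,
                                    SiteMutagenesis, TFKnockout,
                                    apply_perturbation)

__all__ = [
    "Scenario",
    "make_tf_profile",
    "make_motif",
    "make_enhancer",
    "make_ind_like_scenario",
    "make_sim_like_scenario",
    "make_insilico_experiment_set",
]

TIER_MISMATCHES = {"strong": 0, "medium": 1, "weak": 2}


@dataclass
class Scenario:
    """A complete, self-contained modeling scenario."""

    name: str
    sequence: str
    motifs: dict
    tfs: list
    sites: list
    target: np.ndarray
    coop_pairs: tuple = ()
    coop_cutoff: float = thermo_model.DEFAULT_COOP_CUTOFF
    site_threshold: float = 0.5
    ground_truth: ModelParameters | None = None
    seed: int = 0
    extras: dict = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return len(self.target)

    def predict(self, params: ModelParameters) -> np.ndarray:
        return predict_profile(self.sites, self.tfs, params,
                               coop_cutoff=self.coop_cutoff)

    def score(self, params: ModelParameters) -> float:
        return sse(self.predict(params), self.target)


def make_tf_profile(shape: str, n_bins: int, **params) -> np.ndarray:
    """Sample a named concentration curve at ``n_bins`` 1-based bins.

    Shapes: ``uniform(level)``, ``sigmoid(midpoint, slope, decreasing)``
    (half-maximum at ``midpoint``), ``gaussian(center, width, amplitude)``,
    ``complement(profile)`` (bin-wise ``1 - profile``).  Values are clipped
    to [0, 1].
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    bins = np.arange(1, n_bins + 1, dtype=float)
    if shape == "uniform":
        level = params.pop("level", 1.0)
        profile = np.full(n_bins, float(level))
    elif shape == "sigmoid":
        midpoint = params.pop("midpoint")
        slope = params.pop("slope", 1.0)
        decreasing = params.pop("decreasing", True)
        if slope <= 0:
            raise ValueError("sigmoid slope must be positive")
        sign = 1.0 if decreasing else -1.0
        profile = 1.0 / (1.0 + np.exp(sign * (bins - midpoint) / slope))
    elif shape == "gaussian":
        center = params.pop("center")
        width = params.pop("width")
        amplitude = params.pop("amplitude", 1.0)
        power = params.pop("power", 2.0)  # >2 flattens the top (generalized Gaussian)
        if width <= 0 or power <= 0:
            raise ValueError("gaussian width and power must be positive")
        profile = amplitude * np.exp(-0.5 * np.abs((bins - center) / width) ** power)
    elif shape == "complement":
        base = np.asarray(params.pop("profile"), dtype=float)
        if len(base) != n_bins:
            raise ValueError("complement profile length mismatch")
        profile = 1.0 - base
    else:
        raise ValueError(f"unknown profile shape {shape!r}")
    if params:
        raise ValueError(f"unexpected profile parameters {sorted(params)}")
    return np.clip(profile, 0.0, 1.0)


def make_motif(name: str, consensus: str, p_consensus: float = 0.70) -> Motif:
    """A sharp position-frequency motif around a consensus string."""
    consensus = consensus.upper()
    if not 0.25 < p_consensus < 1:
        raise ValueError("p_consensus must lie in (0.25, 1)")
    other = (1.0 - p_consensus) / 3.0
    matrix = np.full((len(consensus), 4), other)
    for i, base in enumerate(consensus):
        matrix[i, thermo_model._BASE_INDEX[base]] = p_consensus
    return Motif(name=name, matrix=matrix)


def _site_string(motif: Motif, n_mismatches: int, rng) -> str:
    bases = list(motif.consensus)
    if n_mismatches:
        positions = rng.choice(len(bases), size=n_mismatches, replace=False)
        for pos in positions:
            choices = [b for b in thermo_model.BASES if b != bases[pos]]
            bases[pos] = choices[rng.integers(len(choices))]
    return "".join(bases)


def make_enhancer(motifs: dict, site_plan, length: int,
                  background: np.ndarray | None = None, seed: int = 0):
    """Generate a background sequence with planted motif instances.

    ``site_plan`` is a list of ``(tf, position, tier)`` with 0-based
    positions and tiers in {'strong', 'medium', 'weak'} (0/1/2 mismatches
    from the consensus).  Returns ``(sequence, expected_sites)`` where the
    expected sites record the planted annotations for test assertions.
    """
    background = np.full(4, 0.25) if background is None else np.asarray(background, float)
    background = background / background.sum()
    rng = np.random.default_rng(seed)
    occupied = []
    for tf, position, tier in site_plan:
        if tf not in motifs:
            raise ValueError(f"no motif for planted TF {tf!r}")
        if tier not in TIER_MISMATCHES:
            raise ValueError(f"unknown strength tier {tier!r}")
        end = position + len(motifs[tf])
        if position < 0 or end > length:
            raise ValueError(f"planted site {tf!r}@{position} does not fit in length {length}")
        for other_start, other_end in occupied:
            if position < other_end and other_start < end:
                raise ValueError(f"planted site {tf!r}@{position} overlaps another planted site")
        occupied.append((position, end))

    sequence = list(rng.choice(list(thermo_model.BASES), size=length, p=background))
    expected = []
    for tf, position, tier in site_plan:
        motif = motifs[tf]
        site = _site_string(motif, TIER_MISMATCHES[tier], rng)
        sequence[position:position + len(motif)] = list(site)
        lo = motif.log_odds
        llr = float(sum(lo[i, thermo_model._BASE_INDEX[b]] for i, b in enumerate(site)))
        expected.append(AnnotatedSite(
            start=position, tf=tf, strand="+", length=len(motif), llr=llr,
            rel_affinity=float(np.exp(llr - motif.max_llr))))
    expected.sort()
    return "".join(sequence), expected


# ------------------------------------------------------------------ scenarios

_IND_CONSENSUS = {
    "DL": "ACCTGAGCTT",
    "ZLD": "CAGGTAGGTC",
    "SNA": "CACCTTGTGC",
    "VND": "TTAAGTGGCG",
    "CIC": "TGATGAAGCC",
}

_SIM_CONSENSUS = {
    "DL": "ACCTGAGCTT",
    "TWI": "CACATGTTGG",
    "SNA": "CACCTTGTGC",
    "SUH": "CGTGGGATAC",
}


def make_ind_like_scenario(seed: int = 0) -> Scenario:
    """A lateral-stripe scenario on a 50-bin axis with five TFs.

    Activators: a graded ventral activator (DL-like, with a ventral-to-
    dorsal gradient) and a uniform ubiquitous activator (ZLD-like), with
    one activator–activator cooperativity.  Repressors: a ventral repressor
    (SNA-like), a repressor banded just ventral of the stripe (VND-like),
    and a uniform repressor (CIC-like) whose binding is attenuated in the
    neuroectodermal bins (Gaussian attenuation mask centered on bin 25).
    The planted ground truth has 13 parameters (2 per TF + cooperativity +
    baseline + attenuation); the target profile is its own prediction,
    peaking at bin 25 with support confined to bins 22–28.
    """
    n_bins = 50
    motifs = {name: make_motif(name, cons) for name, cons in _IND_CONSENSUS.items()}
    profiles = {
        "DL": make_tf_profile("sigmoid", n_bins, midpoint=35.0, slope=4.0),
        "ZLD": make_tf_profile("uniform", n_bins, level=1.0),
        "SNA": make_tf_profile("sigmoid", n_bins, midpoint=19.0, slope=1.2),
        "VND": make_tf_profile("gaussian", n_bins, center=19.5, width=1.5),
        "CIC": make_tf_profile("uniform", n_bins, level=1.0),
    }
    atten_mask = make_tf_profile("gaussian", n_bins, center=25.0, width=2.5, power=4.0)
    roles = {"DL": "activator", "ZLD": "activator",
             "SNA": "repressor", "VND": "repressor", "CIC": "repressor"}
    site_plan = [
        ("DL", 40, "strong"), ("ZLD", 60, "strong"), ("DL", 120, "medium"),
        ("SNA", 150, "strong"), ("VND", 200, "strong"), ("CIC", 250, "strong"),
        ("DL", 300, "medium"), ("ZLD", 330, "medium"), ("SNA", 400, "medium"),
        ("VND", 450, "medium"), ("CIC", 500, "medium"),
    ]
    sequence, planted = make_enhancer(motifs, site_plan, length=600, seed=seed)
    tfs = [TFSpec(name=name, role=roles[name], concentration=profiles[name],
                  motif=motifs[name],
                  attenuation_mask=atten_mask if name == "CIC" else None)
           for name in ("DL", "ZLD", "SNA", "VND", "CIC")]
    site_threshold = 0.7
    sites = annotate_sites_for_tfs(sequence, tfs, site_threshold)
    ground_truth = ModelParameters(
        K={"DL": 4.0, "ZLD": 2.0, "SNA": 30.0, "VND": 30.0, "CIC": 50.0},
        alpha={"DL": 8.0, "ZLD": 3.0, "SNA": 0.005, "VND": 0.005, "CIC": 0.005},
        coop={("DL", "ZLD"): 5.0},
        q_btm=0.02,
        atten={"CIC": 0.02},
    )
    scenario = Scenario(
        name="ind-like", sequence=sequence, motifs=motifs, tfs=tfs,
        sites=sites, target=np.zeros(n_bins), coop_pairs=(("DL", "ZLD"),),
        site_threshold=site_threshold, ground_truth=ground_truth, seed=seed,
        extras={"planted_sites": planted})
    scenario.target = scenario.predict(ground_truth)
    return scenario


def make_sim_like_scenario(seed: int = 0) -> Scenario:
    """A mesectoderm-stripe scenario on the ventral 25 bins of the axis.

    Activators DL-like and TWI-like (both ventral), repressor SNA-like
    (mesodermal, dropping sharply at bin ~12), and a ubiquitous role-switch
    factor split into an activator species (mesodermal domain extended into
    the mesectoderm) and a repressor species with the complementary
    profile.  The target is a narrow Gaussian peaked at bin 12, where the
    ventral repressor switches from high to low.
    """
    n_bins = 25
    motifs = {name: make_motif(name, cons) for name, cons in _SIM_CONSENSUS.items()}
    suh_act = make_tf_profile("sigmoid", n_bins, midpoint=13.0, slope=0.7)
    profiles = {
        "DL": make_tf_profile("sigmoid", n_bins, midpoint=16.0, slope=2.5),
        "TWI": make_tf_profile("sigmoid", n_bins, midpoint=13.0, slope=1.5),
        "SNA": make_tf_profile("sigmoid", n_bins, midpoint=11.5, slope=0.7),
        "SUH_ACT": suh_act,
        "SUH_REP": make_tf_profile("complement", n_bins, profile=suh_act),
    }
    site_plan = [
        ("DL", 30, "strong"), ("TWI", 80, "strong"), ("SNA", 130, "strong"),
        ("SUH", 180, "strong"), ("DL", 230, "medium"), ("TWI", 280, "medium"),
        ("SNA", 330, "medium"), ("SUH", 380, "medium"),
    ]
    sequence, planted = make_enhancer(motifs, site_plan, length=450, seed=seed)
    tfs = [
        TFSpec("DL", "activator", profiles["DL"], motifs["DL"]),
        TFSpec("TWI", "activator", profiles["TWI"], motifs["TWI"]),
        TFSpec("SNA", "repressor", profiles["SNA"], motifs["SNA"]),
        TFSpec("SUH_ACT", "activator", profiles["SUH_ACT"], motifs["SUH"],
               protein="SUH"),
        TFSpec("SUH_REP", "repressor", profiles["SUH_REP"], motifs["SUH"],
               protein="SUH"),
    ]
    site_threshold = 0.7
    sites = annotate_sites_for_tfs(sequence, tfs, site_threshold)
    target = make_tf_profile("gaussian", n_bins, center=12.0, width=1.3)
    return Scenario(
        name="sim-like", sequence=sequence, motifs=motifs, tfs=tfs,
        sites=sites, target=target, coop_pairs=(), seed=seed,
        site_threshold=site_threshold, extras={"planted_sites": planted})


def make_insilico_experiment_set(scenario: Scenario,
                                 sse_threshold: float = 0.005) -> list[PerturbationExperiment]:
    """In-silico experiments generated from the scenario's ground truth.

    For each protein, a knockout experiment and a strongest-site
    mutagenesis experiment; each criterion requires a model's perturbed
    prediction to match the ground truth's perturbed prediction within
    ``sse_threshold`` (mean squared error).  Proteins without annotated
    sites get only the knockout experiment (with a warning).
    """
    if scenario.ground_truth is None:
        raise ValueError("scenario has no planted ground truth")
    proteins = list(dict.fromkeys(tf.protein for tf in scenario.tfs))
    experiments = []
    for protein in proteins:
        for kind, perturbation in (
                ("KO", TFKnockout(protein)),
                ("site_mut", SiteMutagenesis(protein, strongest_k=1))):
            if kind == "site_mut":
                species = {tf.name for tf in scenario.tfs if tf.protein == protein}
                if not any(s.tf in species for s in scenario.sites):
                    warnings.warn(f"protein {protein!r} has no annotated site; "
                                  f"mutagenesis experiment omitted")
                    continue
            perturbed = apply_perturbation(scenario, perturbation)
            truth_outcome = perturbed.predict(scenario.ground_truth)
            experiments.append(PerturbationExperiment(
                name=f"{protein}_{kind}", perturbation=perturbation,
                criterion=ProfileMatch(target=truth_outcome,
                                       threshold=sse_threshold)))
    return experiments
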