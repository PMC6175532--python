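"""Thermodynamic sequence-to-expression model of enhancer readout.

The model follows the classical equilibrium-statistical-mechanics view of a
cis-regulatory module (CRM): transcription factor (TF) molecules bind the
enhancer at sequence-specific sites, and the basal transcriptional machinery
(BTM) is recruited with a probability determined by a Boltzmann sum over all
configurations of bound TFs.  Each TF contributes two free parameters — a
binding constant ``K`` (strength of TF–DNA interaction at its consensus site)
and a potency ``alpha`` (>1 for activators, <=1 for repressors) — plus
optional pairwise cooperativity weights ``w`` between adjacent bound sites of
declared TF pairs, a baseline-machinery weight ``q_btm`` and, for TFs whose
repressive activity is regionally attenuated (e.g. by signaling), an
attenuation factor in (0, 1].

For a configuration ``c`` of mutually compatible (non-overlapping) bound
sites the statistical weight is::

    W(c) = prod_{i in c} q_i  *  prod_{adjacent coop pairs} w

with per-site, per-bin weight ``q_i = K_tf * conc_tf(bin) * rel_affinity_i *
atten_tf(bin)``.  With ``Z_off = sum_c W(c)`` and ``Z_on = q_btm * sum_c W(c)
* prod_{i in c} alpha_i`` the predicted expression in a bin is
``Z_on / (Z_on + Z_off)``, a fractional occupancy of the BTM in [0, 1].

The configuration sums are computed by a dynamic program over sites ordered
along the sequence, vectorized across spatial bins; it is exactly equivalent
to brute-force enumeration of all compatible site subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Motif",
    "AnnotatedSite",
    "TFSpec",
    "ModelParameters",
    "scan_sites",
    "annotate_sites_for_tfs",
    "predict_expression",
    "predict_profile",
    "sse",
    "DEFAULT_COOP_CUTOFF",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT_INDEX = np.array([3, 2, 1, 0])  # A<->T, C<->G

#: default maximum gap (bp) between adjacent bound sites for cooperativity
DEFAULT_COOP_CUTOFF = 50.0


@dataclass(frozen=True)
class Motif:
    """Position weight matrix over {A, C, G, T}.

    ``matrix`` holds per-position base frequencies (rows sum to one);
    ``pseudocount`` records the value used when the motif was derived from
    counts.  ``background`` is the genomic base composition against which
    log-likelihood-ratio (LLR) scores are computed, in nats.
    """

    name: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.0

    def __post_init__(self):
        matrix = np.asarray(self.matrix, dtype=float)
        background = np.asarray(self.background, dtype=float)
        if matrix.ndim != 2 or matrix.shape[1] != 4 or matrix.shape[0] < 1:
            raise ValueError(f"motif {self.name!r}: matrix must be L x 4 with L >= 1")
        if np.any(matrix < 0):
            raise ValueError(f"motif {self.name!r}: negative frequencies")
        if not np.allclose(matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"motif {self.name!r}: rows must sum to 1")
        if background.shape != (4,) or np.any(background <= 0):
            raise ValueError(f"motif {self.name!r}: background must be 4 positive frequencies")
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "background", background / background.sum())

    @classmethod
    def from_counts(cls, name, counts, pseudocount=0.5, background=None):
        """Build a motif from a count matrix with additive smoothing."""
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError(f"motif {name!r}: counts must be L x 4")
        if np.any(counts.sum(axis=1) <= 0) and pseudocount <= 0:
            raise ValueError(f"motif {name!r}: zero count row requires a positive pseudocount")
        smoothed = counts + pseudocount
        matrix = smoothed / smoothed.sum(axis=1, keepdims=True)
        kwargs = {} if background is None else {"background": background}
        return cls(name=name, matrix=matrix, pseudocount=float(pseudocount), **kwargs)

    def __len__(self):
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """L x 4 matrix of ``log(f / bg)`` in nats."""
        return np.log(self.matrix) - np.log(self.background)[None, :]

    @property
    def max_llr(self) -> float:
        """LLR of the optimal (consensus) site."""
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.log_odds.argmax(axis=1))


@dataclass(frozen=True, order=True)
class AnnotatedSite:
    """A putative binding site: half-open interval [start, start+length)."""

    start: int
    tf: str
    strand: str
    length: int
    llr: float
    rel_affinity: float

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class TFSpec:
    """A transcription factor in a modeling scenario.

    ``concentration`` is the per-bin protein level scaled to [0, 1].
    ``attenuation_mask`` (optional) gives, per bin, the degree to which the
    TF's DNA binding is attenuated there: 0 means unaffected, 1 means fully
    subject to the model's attenuation parameter for this TF.  ``protein``
    names the underlying protein for TFs whose role is split into separate
    activator/repressor species (defaults to ``name``).
    """

    name: str
    role: str
    concentration: np.ndarray
    motif: Motif
    attenuation_mask: np.ndarray | None = None
    protein: str | None = None

    def __post_init__(self):
        if self.role not in ("activator", "repressor"):
            raise ValueError(f"TF {self.name!r}: role must be 'activator' or 'repressor'")
        conc = np.asarray(self.concentration, dtype=float)
        if np.any(conc < 0) or np.any(conc > 1):
            raise ValueError(f"TF {self.name!r}: concentration values must lie in [0, 1]")
        self.concentration = conc
        if self.attenuation_mask is not None:
            mask = np.asarray(self.attenuation_mask, dtype=float)
            if mask.shape != conc.shape:
                raise ValueError(f"TF {self.name!r}: attenuation mask length mismatch")
            if np.any(mask < 0) or np.any(mask > 1):
                raise ValueError(f"TF {self.name!r}: attenuation mask values must lie in [0, 1]")
            self.attenuation_mask = mask
        if self.protein is None:
            self.protein = self.name


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class ModelParameters:
    """One point in the model's parameter space.

    ``K``: TF -> binding constant; ``alpha``: TF -> potency; ``coop``:
    unordered TF pair -> cooperativity weight ``w``; ``q_btm``: baseline
    machinery weight; ``atten``: TF -> attenuation factor in (0, 1] applied
    in the bins flagged by that TF's attenuation mask.
    """

    K: dict
    alpha: dict
    q_btm: float
    coop: dict = field(default_factory=dict)
    atten: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coop = {_pair_key(*k): float(v) for k, v in self.coop.items()}
        for label, mapping in (("K", self.K), ("alpha", self.alpha),
                               ("coop", self.coop), ("atten", self.atten)):
            for key, value in mapping.items():
                if not np.isfinite(value) or value <= 0:
                    raise ValueError(f"parameter {label}[{key!r}] must be strictly positive")
        if not np.isfinite(self.q_btm) or self.q_btm <= 0:
            raise ValueError("q_btm must be strictly positive")
        for tf, value in self.atten.items():
            if value > 1:
                raise ValueError(f"atten[{tf!r}] must lie in (0, 1]")

    @property
    def dimension(self) -> int:
        return 2 * len(self.K) + len(self.coop) + 1 + len(self.atten)

    def coop_weight(self, tf_a: str, tf_b: str) -> float:
        return self.coop.get(_pair_key(tf_a, tf_b), 1.0)


def _validate_sequence(sequence: str) -> str:
    sequence = sequence.upper()
    invalid = set(sequence) - set("ACGTN")
    if invalid:
        raise ValueError(f"invalid sequence characters: {sorted(invalid)}")
    return sequence


def scan_sites(sequence: str, motif: Motif, llr_fraction_threshold: float = 0.5) -> list[AnnotatedSite]:
    """Annotate binding sites of ``motif`` on both strands of ``sequence``.

    A window is reported when its LLR is at least ``llr_fraction_threshold``
    times the motif's optimal LLR.  Windows containing ``N`` are skipped.
    Sites are sorted by start position.
    """
    if not 0 < llr_fraction_threshold <= 1:
        raise ValueError("llr_fraction_threshold must lie in (0, 1]")
    sequence = _validate_sequence(sequence)
    L = len(motif)
    if len(sequence) < L:
        return []
    codes = np.array([_BASE_INDEX.get(b, -1) for b in sequence], dtype=int)
    lo_fwd = motif.log_odds
    # reverse-strand scoring: score the window against the reverse complement
    # of the motif (equivalent to scoring the window's reverse complement
    # against the forward motif).
    lo_rev = lo_fwd[::-1, _COMPLEMENT_INDEX]
    threshold = llr_fraction_threshold * motif.max_llr
    sites = []
    for start in range(len(sequence) - L + 1):
        window = codes[start:start + L]
        if np.any(window < 0):
            continue
        idx = np.arange(L)
        for strand, lo in (("+", lo_fwd), ("-", lo_rev)):
            llr = float(lo[idx, window].sum())
            if llr >= threshold:
                sites.append(AnnotatedSite(
                    start=start, tf=motif.name, strand=strand, length=L,
                    llr=llr, rel_affinity=float(np.exp(llr - motif.max_llr)),
                ))
    sites.sort()
    return sites


def annotate_sites_for_tfs(sequence: str, tfs, llr_fraction_threshold: float = 0.5) -> list[AnnotatedSite]:
    """Scan the sequence with each TF's motif and label sites by TF name.

    TFs modeled as split-role species of one protein share a motif; their
    sites then appear once per species at identical coordinates, which the
    configuration sum treats as mutually exclusive binding alternatives.
    """
    sites: list[AnnotatedSite] = []
    for tf in tfs:
        for site in scan_sites(sequence, tf.motif, llr_fraction_threshold):
            sites.append(AnnotatedSite(
                start=site.start, tf=tf.name, strand=site.strand,
                length=site.length, llr=site.llr, rel_affinity=site.rel_affinity))
    sites.sort()
    return sites


def _site_weights(sites, tfs, params: ModelParameters) -> tuple[np.ndarray, np.ndarray]:
    """Per-site bin-wise weights q_i (n_sites x B) and potencies (n_sites,)."""
    tf_by_name = {tf.name: tf for tf in tfs}
    n_bins = len(next(iter(tf_by_name.values())).concentration) if tf_by_name else 0
    qs = np.empty((len(sites), n_bins))
    alphas = np.empty(len(sites))
    for i, site in enumerate(sites):
        spec = tf_by_name.get(site.tf)
        if spec is None:
            raise ValueError(f"site references unknown TF {site.tf!r}")
        if site.tf not in params.K or site.tf not in params.alpha:
            raise ValueError(f"missing K/alpha parameters for TF {site.tf!r}")
        q = params.K[site.tf] * spec.concentration * site.rel_affinity
        if spec.attenuation_mask is not None and site.tf in params.atten:
            q = q * (1.0 - spec.attenuation_mask * (1.0 - params.atten[site.tf]))
        qs[i] = q
        alphas[i] = params.alpha[site.tf]
    return qs, alphas


def _partition_sums(sites, qs, alphas, params, coop_cutoff):
    """Boltzmann sums over compatible site configurations, per bin.

    Returns ``(Z_off, S_on)`` where ``Z_off = sum_c W(c)`` and
    ``S_on = sum_c W(c) * prod alpha`` (both include the empty configuration
    with weight 1).  The recursion runs over sites sorted by end coordinate;
    ``A[i]`` accumulates all configurations whose last bound site is ``i``,
    so cooperativity applies between consecutive bound sites of a declared
    pair whose gap is within ``coop_cutoff``.
    """
    order = sorted(range(len(sites)), key=lambda i: (sites[i].end, sites[i].start))
    n_bins = qs.shape[1]
    z_off = np.ones(n_bins)
    s_on = np.ones(n_bins)
    A: list[np.ndarray] = []
    B: list[np.ndarray] = []
    for pos, i in enumerate(order):
        site = sites[i]
        acc_off = np.ones(n_bins)
        acc_on = np.ones(n_bins)
        for prev_pos in range(pos):
            j = order[prev_pos]
            other = sites[j]
            if other.end > site.start:  # overlap: mutually exclusive
                continue
            w = 1.0
            if site.start - other.end <= coop_cutoff:
                w = params.coop_weight(other.tf, site.tf)
            acc_off = acc_off + w * A[prev_pos]
            acc_on = acc_on + w * B[prev_pos]
        a_i = qs[i] * acc_off
        b_i = qs[i] * alphas[i] * acc_on
        A.append(a_i)
        B.append(b_i)
        z_off += a_i
        s_on += b_i
    return z_off, s_on


def predict_profile(sites, tfs, params: ModelParameters,
                    coop_cutoff: float = DEFAULT_COOP_CUTOFF) -> np.ndarray:
    """Predicted expression in every spatial bin; values in [0, 1]."""
    if not tfs:
        raise ValueError("at least one TF specification is required")
    n_bins = len(tfs[0].concentration)
    for tf in tfs:
        if len(tf.concentration) != n_bins:
            raise ValueError("TF concentration profiles have inconsistent lengths")
    if not sites:
        basal = params.q_btm / (1.0 + params.q_btm)
        return np.full(n_bins, basal)
    qs, alphas = _site_weights(sites, tfs, params)
    z_off, s_on = _partition_sums(sites, qs, alphas, params, coop_cutoff)
    z_on = params.q_btm * s_on
    return z_on / (z_on + z_off)


def predict_expression(sites, tfs, params: ModelParameters, bin: int,
                       coop_cutoff: float = DEFAULT_COOP_CUTOFF) -> float:
    """Predicted expression in one spatial bin (0-based index)."""
    profile = predict_profile(sites, tfs, params, coop_cutoff=coop_cutoff)
    return float(profile[bin])


def sse(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Goodness-of-fit between two expression profiles.

    Mean of squared per-bin differences, so that on [0, 1]-scaled profiles a
    threshold of "10%" reads as 0.10 independently of the number of bins.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError(f"profile length mismatch: {predicted.shape} vs {observed.shape}")
    return float(np.mean((predicted - observed) ** 2))
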