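"""Information-theoretic evaluation of perturbation experiments.

A perturbation experiment pairs a perturbation operator (TF knockout, site
mutagenesis, or a variant enhancer) with a machine-checkable consistency
criterion describing the observed outcome.  Each ensemble member predicts
the perturbed readout; members whose prediction violates the criterion are
discarded, yielding a *filtered ensemble*.  The distribution over the
filtered ensemble reuses the parent clustering: (a) cluster assignments and
covariances are retained, (b) clusters left empty are removed and the
remaining clusters re-weighted uniformly, (c) each surviving cluster's
Gaussian mixture is re-centered on its surviving members only.  The
experiment's value is the information gain — entropy of the parent
distribution minus entropy of the filtered one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd

from . import thermo_model
from .model_distribution import (EnsembleDistribution, ModelProbabilities,
                                 density, entropy, ClusteredEnsemble)

__all__ = [
    "TFKnockout",
    "SiteMutagenesis",
    "VariantEnhancer",
    "Unchanged",
    "ProfileMatch",
    "PeakFraction",
    "BoundaryShift",
    "Abolished",
    "PerturbationExperiment",
    "FilteredEnsemble",
    "InformationGainReport",
    "apply_perturbation",
    "half_max_crossing",
    "is_consistent",
    "consistency_mask",
    "filter_ensemble",
    "information_gain",
    "cluster_survival_table",
    "sequential_gain_matrix",
    "aggregate_prediction",
    "cross_predict",
    "select_synthetic_true_model",
]


# ---------------------------------------------------------------- perturbations

@dataclass(frozen=True)
class TFKnockout:
    """Zero the concentration profile of a TF.  For proteins modeled as two
    split-role species (separate activator/repressor profiles) the knockout
    zeroes every species of that protein."""

    tf: str


@dataclass(frozen=True)
class SiteMutagenesis:
    """Remove annotated binding sites of a TF: either the ``strongest_k``
    sites by relative affinity, or sites at explicit start positions."""

    tf: str
    strongest_k: int = 1
    positions: tuple | None = None


@dataclass(frozen=True)
class VariantEnhancer:
    """Replace the enhancer sequence; sites are re-annotated on the variant."""

    sequence: str


# -------------------------------------------------------------------- criteria

@dataclass(frozen=True)
class Unchanged:
    """Prediction matches the wild-type profile: sse < threshold."""

    threshold: float = 0.05


@dataclass(frozen=True)
class ProfileMatch:
    """Prediction matches a given target profile: sse < threshold."""

    target: np.ndarray
    threshold: float = 0.05


@dataclass(frozen=True)
class PeakFraction:
    """Peak of the prediction, relative to the wild-type peak, lies in
    [lo, hi] (e.g. [0.35, 0.65] encodes 'reduces to about half')."""

    lo: float
    hi: float

    def __post_init__(self):
        if not 0 <= self.lo <= self.hi:
            raise ValueError("peak-fraction window must satisfy 0 <= lo <= hi")


@dataclass(frozen=True)
class BoundaryShift:
    """The half-maximum boundary of the expression domain on the stated side
    ('ventral' = low bins, 'dorsal' = high bins) moves outward — expanding
    the domain toward that side — by at least ``min_bins``."""

    side: str
    min_bins: float = 2.0

    def __post_init__(self):
        if self.side not in ("dorsal", "ventral"):
            raise ValueError("side must be 'dorsal' or 'ventral'")
        if self.min_bins <= 0:
            raise ValueError("min_bins must be positive")


@dataclass(frozen=True)
class Abolished:
    """Expression is abolished: max(prediction) <= max_level."""

    max_level: float = 0.1


@dataclass(frozen=True)
class PerturbationExperiment:
    name: str
    perturbation: object
    criterion: object


# ------------------------------------------------------------ applying/judging

def apply_perturbation(scenario, perturbation):
    """Return a modified copy of ``scenario``; the input is untouched."""
    if isinstance(perturbation, TFKnockout):
        hit = [tf for tf in scenario.tfs
               if tf.name == perturbation.tf or tf.protein == perturbation.tf]
        if not hit:
            raise ValueError(f"knockout target {perturbation.tf!r} not in scenario")
        new_tfs = []
        for tf in scenario.tfs:
            if tf in hit:
                tf = _dc_replace(tf, concentration=np.zeros_like(tf.concentration))
            new_tfs.append(tf)
        return _dc_replace(scenario, tfs=new_tfs)
    if isinstance(perturbation, SiteMutagenesis):
        species = {tf.name for tf in scenario.tfs
                   if tf.name == perturbation.tf or tf.protein == perturbation.tf}
        targets = [s for s in scenario.sites if s.tf in species]
        if perturbation.positions is not None:
            removed = [s for s in targets if s.start in set(perturbation.positions)]
        else:
            # mutagenesis destroys the DNA element: rank distinct intervals by
            # their best relative affinity and remove every species' entry at
            # the chosen interval(s)
            intervals: dict[tuple, float] = {}
            for s in targets:
                key = (s.start, s.length)
                intervals[key] = max(intervals.get(key, 0.0), s.rel_affinity)
            ranked = sorted(intervals, key=lambda k: (-intervals[k], k))
            chosen = set(ranked[:perturbation.strongest_k])
            removed = [s for s in targets if (s.start, s.length) in chosen]
        if not removed:
            raise ValueError(f"site selector matched no site of TF {perturbation.tf!r}")
        removed_set = set(removed)
        return _dc_replace(scenario,
                           sites=[s for s in scenario.sites if s not in removed_set])
    if isinstance(perturbation, VariantEnhancer):
        sites = thermo_model.annotate_sites_for_tfs(
            perturbation.sequence, scenario.tfs, scenario.site_threshold)
        return _dc_replace(scenario, sequence=perturbation.sequence.upper(), sites=sites)
    raise TypeError(f"unknown perturbation type {type(perturbation).__name__}")


def half_max_crossing(profile: np.ndarray, side: str) -> float:
    """Outermost crossing of 50% of the profile's maximum on ``side``.

    Returns a 0-based fractional bin position, linearly interpolated between
    bins; if the profile never drops below half-maximum on that side the
    boundary of the axis is returned.
    """
    profile = np.asarray(profile, dtype=float)
    peak = profile.max()
    if peak <= 0:
        raise ValueError("boundary undefined for an all-zero profile")
    thr = 0.5 * peak
    above = np.flatnonzero(profile >= thr)
    if side == "dorsal":
        i = above[-1]
        if i == len(profile) - 1:
            return float(i)
        return float(i + (profile[i] - thr) / (profile[i] - profile[i + 1]))
    i = above[0]
    if i == 0:
        return 0.0
    return float(i - (profile[i] - thr) / (profile[i] - profile[i - 1]))


def is_consistent(prediction: np.ndarray, wild_type: np.ndarray, criterion) -> bool:
    """Judge a predicted perturbed profile against an experiment's criterion."""
    prediction = np.asarray(prediction, dtype=float)
    wild_type = np.asarray(wild_type, dtype=float)
    if prediction.shape != wild_type.shape:
        raise ValueError("profile length mismatch")
    if isinstance(criterion, Unchanged):
        return thermo_model.sse(prediction, wild_type) < criterion.threshold
    if isinstance(criterion, ProfileMatch):
        return thermo_model.sse(prediction, criterion.target) < criterion.threshold
    if isinstance(criterion, PeakFraction):
        wt_peak = wild_type.max()
        if wt_peak <= 0:
            raise ValueError("peak fraction undefined for a flat wild-type profile")
        frac = prediction.max() / wt_peak
        return criterion.lo <= frac <= criterion.hi
    if isinstance(criterion, BoundaryShift):
        wt_cross = half_max_crossing(wild_type, criterion.side)
        pred_cross = half_max_crossing(prediction, criterion.side)
        shift = (pred_cross - wt_cross if criterion.side == "dorsal"
                 else wt_cross - pred_cross)
        return shift >= criterion.min_bins
    if isinstance(criterion, Abolished):
        return prediction.max() <= criterion.max_level
    raise TypeError(f"unknown criterion type {type(criterion).__name__}")


# ---------------------------------------------------------- filtered ensembles

@dataclass
class FilteredEnsemble:
    """Survivors of an experiment's filter, with the rebuilt distribution."""

    parent: EnsembleDistribution
    experiment_name: str
    indices: np.ndarray          # surviving model indices into the parent
    probabilities: ModelProbabilities  # over survivors, parent cluster labels
    entropy: float
    survival_counts: np.ndarray  # per parent cluster

    def __len__(self):
        return len(self.indices)


@dataclass(frozen=True)
class InformationGainReport:
    experiment_name: str
    H_parent: float
    H_filtered: float

    @property
    def gain(self) -> float:
        return self.H_parent - self.H_filtered


def consistency_mask(parent: EnsembleDistribution, experiment: PerturbationExperiment,
                     scenario) -> np.ndarray:
    """Boolean mask over parent models: does each model's prediction under
    the perturbed scenario satisfy the experiment's criterion?  The
    wild-type reference profile is the scenario's target."""
    perturbed = apply_perturbation(scenario, experiment.perturbation)
    space = parent.ensemble.space
    mask = np.zeros(len(parent.ensemble), dtype=bool)
    for i, vec in enumerate(parent.ensemble.vectors):
        prediction = perturbed.predict(space.from_vector(vec))
        mask[i] = is_consistent(prediction, scenario.target, experiment.criterion)
    return mask


def _distribution_over_subset(parent: EnsembleDistribution, mask: np.ndarray):
    """Rebuild the distribution over the surviving subset per the update
    rules: parent labels and covariances retained, empty clusters dropped,
    surviving clusters weighted 1/N', mixtures re-centered on survivors."""
    indices = np.flatnonzero(mask)
    if len(indices) == 0:
        raise RuntimeError("experiment refutes the entire ensemble: no model survives")
    clustered = parent.clustered
    labels = clustered.labels[indices]
    surviving_clusters = np.unique(labels)
    remap = {int(c): i for i, c in enumerate(surviving_clusters)}
    new_labels = np.array([remap[int(l)] for l in labels])
    sub = ClusteredEnsemble(
        scaled_models=clustered.scaled_models[indices],
        labels=new_labels,
        cluster_covs=clustered.cluster_covs[surviving_clusters],
        selected=dict(clustered.selected))
    dens = density(sub, sub.scaled_models)
    N = sub.n_clusters
    p = np.empty_like(dens)
    for c in range(N):
        members = sub.members(c)
        p[members] = dens[members] / (dens[members].sum() * N)
    probs = ModelProbabilities(p=p, labels=clustered.labels[indices].copy())
    counts = np.zeros(clustered.n_clusters, dtype=int)
    for c, n in zip(*np.unique(clustered.labels[indices], return_counts=True)):
        counts[int(c)] = int(n)
    return indices, probs, entropy(p), counts


def filter_ensemble(parent: EnsembleDistribution, experiment: PerturbationExperiment,
                    scenario) -> FilteredEnsemble:
    """Filter the parent ensemble by an experiment and rebuild the
    distribution over the survivors."""
    mask = consistency_mask(parent, experiment, scenario)
    indices, probs, H, counts = _distribution_over_subset(parent, mask)
    return FilteredEnsemble(
        parent=parent, experiment_name=experiment.name, indices=indices,
        probabilities=probs, entropy=H, survival_counts=counts)


def information_gain(H_parent: float, H_filtered: float) -> float:
    """Entropy reduction attributed to an experiment (signed, not clamped)."""
    return H_parent - H_filtered


def cluster_survival_table(parent: EnsembleDistribution,
                           filtered: list[FilteredEnsemble]) -> pd.DataFrame:
    """Per-cluster survivor counts, totals, entropies and information gains,
    one row per ensemble, with the parent (wild-type) ensemble first."""
    n = parent.clustered.n_clusters
    columns = [f"cluster_{c + 1}" for c in range(n)]
    rows, index = [], []
    parent_counts = parent.clustered.cluster_sizes
    rows.append(list(parent_counts) + [int(parent_counts.sum()), parent.entropy, 0.0])
    index.append("wild-type")
    for f in filtered:
        rows.append(list(f.survival_counts)
                    + [int(f.survival_counts.sum()), f.entropy,
                       information_gain(parent.entropy, f.entropy)])
        index.append(f.experiment_name)
    return pd.DataFrame(rows, index=index,
                        columns=columns + ["total", "entropy", "information_gain"])


def sequential_gain_matrix(experiments: list[PerturbationExperiment],
                           parent: EnsembleDistribution, scenario) -> pd.DataFrame:
    """Entry (i, j): information gain of experiment j performed after
    experiment i, i.e. H(filtered by i) - H(filtered by i then j).
    Undefined entries (empty intermediate ensembles) are NaN."""
    masks = [consistency_mask(parent, e, scenario) for e in experiments]
    names = [e.name for e in experiments]
    n = len(experiments)
    out = np.full((n, n), np.nan)
    for i in range(n):
        if not masks[i].any():
            continue
        _, _, H_i, _ = _distribution_over_subset(parent, masks[i])
        for j in range(n):
            both = masks[i] & masks[j]
            if not both.any():
                continue
            _, _, H_ij, _ = _distribution_over_subset(parent, both)
            out[i, j] = H_i - H_ij
    return pd.DataFrame(out, index=names, columns=names)


def aggregate_prediction(dist, scenario):
    """Probability-weighted per-bin mean and variance of model predictions.

    ``dist`` may be an :class:`EnsembleDistribution` (all models, parent
    probabilities) or a :class:`FilteredEnsemble` (survivors, recomputed
    probabilities)."""
    if isinstance(dist, FilteredEnsemble):
        parent = dist.parent
        vectors = parent.ensemble.vectors[dist.indices]
        weights = dist.probabilities.p
        space = parent.ensemble.space
    else:
        vectors = dist.ensemble.vectors
        weights = dist.probabilities.p
        space = dist.ensemble.space
    predictions = np.array([scenario.predict(space.from_vector(v)) for v in vectors])
    mean = weights @ predictions
    var = weights @ (predictions - mean) ** 2
    return mean, var


@dataclass(frozen=True)
class CrossPredictionReport:
    """Aggregate predictions for experiment B's perturbation, under the
    parent ensemble versus under the ensemble filtered by experiment A."""

    experiment_a: str
    experiment_b: str
    parent_mean: np.ndarray
    parent_var: np.ndarray
    filtered_mean: np.ndarray
    filtered_var: np.ndarray

    @property
    def variance_reduction(self) -> np.ndarray:
        return self.parent_var - self.filtered_var


def cross_predict(experiment_a: PerturbationExperiment,
                  experiment_b: PerturbationExperiment,
                  parent: EnsembleDistribution, scenario) -> CrossPredictionReport:
    """How does filtering by experiment A change the ensemble's prediction
    for experiment B's perturbation?  (An interpretation device: a large
    difference says A taught us something B would have probed.)"""
    scenario_b = apply_perturbation(scenario, experiment_b.perturbation)
    parent_mean, parent_var = aggregate_prediction(parent, scenario_b)
    filtered = filter_ensemble(parent, experiment_a, scenario)
    filtered_mean, filtered_var = aggregate_prediction(filtered, scenario_b)
    return CrossPredictionReport(
        experiment_a=experiment_a.name, experiment_b=experiment_b.name,
        parent_mean=parent_mean, parent_var=parent_var,
        filtered_mean=filtered_mean, filtered_var=filtered_var)


@dataclass(frozen=True)
class TruthSelectionReport:
    satisfied: tuple
    unsatisfied: tuple
    chosen_index: int
    chosen_sse: float


def select_synthetic_true_model(parent: EnsembleDistribution,
                                experiments: list[PerturbationExperiment],
                                scenario):
    """Choose a single 'synthetic true' model from the ensemble.

    Experiments are applied in order; a filter that would leave no model is
    reported as unsatisfied and skipped.  Among the models passing the
    experiments that could be jointly satisfied, the one with the best
    wild-type fit is returned along with a report of what was satisfiable.
    """
    if not experiments:
        raise ValueError("at least one experiment is required")
    current = np.ones(len(parent.ensemble), dtype=bool)
    satisfied, unsatisfied = [], []
    for exp in experiments:
        mask = consistency_mask(parent, exp, scenario)
        combined = current & mask
        if combined.any():
            current = combined
            satisfied.append(exp.name)
        else:
            unsatisfied.append(exp.name)
    candidates = np.flatnonzero(current)
    if len(candidates) == 0:
        raise RuntimeError("no model passes even the wild-type fit")
    best = candidates[np.argmin(parent.ensemble.scores[candidates])]
    report = TruthSelectionReport(
        satisfied=tuple(satisfied), unsatisfied=tuple(unsatisfied),
        chosen_index=int(best), chosen_sse=float(parent.ensemble.scores[best]))
    return parent.ensemble.parameters(int(best)), report
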