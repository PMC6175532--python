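"""Cluster-balanced probability distribution over a model ensemble.

The ensemble's parameter vectors are min–max scaled to the unit cube,
clustered with Gaussian mixtures (component count and covariance structure
selected by BIC), and the distribution over parameter space is defined as

    P(theta) = (1/N) sum_C (1/n_C) sum_i Normal(theta; mu_iC, Sigma_C)

where N is the number of clusters, n_C the size of cluster C, mu_iC its
member models and Sigma_C its (shared, regularized) covariance matrix.
Every cluster thus carries the same total mass 1/N regardless of how many
models landed in it, reflecting the view that each cluster is one
mechanistic hypothesis and none is a priori preferred.

Discrete model probabilities p_iC are proportional to the continuous
density evaluated at each model's position, renormalized within each
cluster to sum to 1/N.  Entropy is Shannon entropy of those discrete
probabilities in base 10.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as _la
from sklearn.mixture import GaussianMixture

__all__ = [
    "ScalingRecord",
    "ClusterConfig",
    "ClusteredEnsemble",
    "ModelProbabilities",
    "EnsembleDistribution",
    "minmax_scale",
    "cluster_models",
    "density",
    "discrete_probabilities",
    "entropy",
    "fit_distribution",
]


@dataclass(frozen=True)
class ScalingRecord:
    """Per-dimension min/max used for scaling; degenerate dimensions
    (min == max) are mapped to 0 and cannot be inverted."""

    mins: np.ndarray
    maxs: np.ndarray

    @property
    def degenerate(self) -> np.ndarray:
        return self.maxs == self.mins

    def transform(self, vectors: np.ndarray) -> np.ndarray:
        vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
        span = np.where(self.degenerate, 1.0, self.maxs - self.mins)
        scaled = (vectors - self.mins) / span
        scaled[:, self.degenerate] = 0.0
        return scaled

    def inverse(self, scaled: np.ndarray) -> np.ndarray:
        scaled = np.atleast_2d(np.asarray(scaled, dtype=float))
        return scaled * (self.maxs - self.mins) + self.mins


def minmax_scale(vectors: np.ndarray):
    """Scale each dimension affinely to [0, 1] by its ensemble min/max.

    Returns ``(scaled_matrix, ScalingRecord)``.
    """
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    if vectors.size == 0:
        raise ValueError("cannot scale an empty ensemble")
    record = ScalingRecord(mins=vectors.min(axis=0), maxs=vectors.max(axis=0))
    return record.transform(vectors), record


@dataclass(frozen=True)
class ClusterConfig:
    """Mixture-model search settings.

    ``n_components`` is the inclusive range of component counts tried,
    ``covariance_types`` the sklearn covariance structures considered;
    the (count, structure) pair with the lowest BIC wins.  ``reg`` is added
    to covariance diagonals (on the scaled space) for numerical stability.
    """

    n_components: tuple = (1, 20)
    covariance_types: tuple = ("spherical", "diag", "full")
    seed: int = 0
    reg: float = 1e-6
    n_init: int = 2


@dataclass
class ClusteredEnsemble:
    """Scaled models with cluster labels and per-cluster covariances."""

    scaled_models: np.ndarray
    labels: np.ndarray
    cluster_covs: np.ndarray  # (N, D, D)
    bic: float = float("nan")
    selected: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return self.cluster_covs.shape[0]

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)

    def members(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.labels == c)


def _full_covariances(gm: GaussianMixture) -> np.ndarray:
    """Expand sklearn's covariance parameterization to full D x D matrices."""
    D = gm.means_.shape[1]
    k = gm.n_components
    cov = gm.covariances_
    if gm.covariance_type == "full":
        return np.array(cov)
    if gm.covariance_type == "tied":
        return np.repeat(cov[None], k, axis=0)
    if gm.covariance_type == "diag":
        return np.array([np.diag(c) for c in cov])
    return np.array([np.eye(D) * c for c in cov])  # spherical


def cluster_models(scaled: np.ndarray, config: ClusterConfig = ClusterConfig()) -> ClusteredEnsemble:
    """Cluster scaled parameter vectors by BIC-selected Gaussian mixtures.

    Each model is assigned to its maximum-responsibility component; empty
    components are dropped and labels relabeled contiguously.  Per-cluster
    covariances come from the selected mixture, regularized by ``reg * I``.
    """
    scaled = np.atleast_2d(np.asarray(scaled, dtype=float))
    M, D = scaled.shape
    if M < 2:
        raise ValueError("clustering requires at least two models")
    lo, hi = config.n_components
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k, cov_type in itertools.product(range(lo, min(hi, M) + 1),
                                             config.covariance_types):
            gm = GaussianMixture(
                n_components=k, covariance_type=cov_type,
                random_state=config.seed, reg_covar=max(config.reg, 1e-6),
                n_init=config.n_init, max_iter=300)
            try:
                gm.fit(scaled)
            except (ValueError, _la.LinAlgError):
                continue
            bic = gm.bic(scaled)
            if best is None or bic < best[0]:
                best = (bic, gm, k, cov_type)
    if best is None:
        raise RuntimeError("no mixture model could be fit to the ensemble")
    bic, gm, k, cov_type = best
    labels = gm.predict(scaled)
    covs = _full_covariances(gm) + config.reg * np.eye(D)[None]
    # drop components with no assigned model, relabel contiguously
    occupied = np.flatnonzero(np.bincount(labels, minlength=gm.n_components) > 0)
    remap = {int(old): new for new, old in enumerate(occupied)}
    labels = np.array([remap[int(l)] for l in labels])
    covs = covs[occupied]
    for c in range(covs.shape[0]):
        _la.cholesky(covs[c], lower=True)  # raises if not positive-definite
    return ClusteredEnsemble(
        scaled_models=scaled, labels=labels, cluster_covs=covs, bic=float(bic),
        selected={"n_components": int(k), "covariance_type": cov_type})


def _cluster_pdf_matrix(queries: np.ndarray, means: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Matrix of Normal(query; mean, cov) values, shape (n_queries, n_means)."""
    D = means.shape[1]
    chol = _la.cholesky(cov, lower=True)
    log_norm = -0.5 * D * np.log(2 * np.pi) - np.sum(np.log(np.diag(chol)))
    diff = queries[:, None, :] - means[None, :, :]  # (m, n, D)
    sol = _la.solve_triangular(chol, diff.reshape(-1, D).T, lower=True)
    maha = np.sum(sol ** 2, axis=0).reshape(diff.shape[:2])
    return np.exp(log_norm - 0.5 * maha)


def density(clustered: ClusteredEnsemble, theta: np.ndarray) -> float | np.ndarray:
    """Evaluate the cluster-balanced mixture density at ``theta``.

    ``theta`` may be a single scaled D-vector or an ``(m, D)`` matrix.
    """
    theta = np.asarray(theta, dtype=float)
    single = theta.ndim == 1
    queries = np.atleast_2d(theta)
    D = clustered.scaled_models.shape[1]
    if queries.shape[1] != D:
        raise ValueError(f"expected dimension {D}, got {queries.shape[1]}")
    N = clustered.n_clusters
    total = np.zeros(len(queries))
    for c in range(N):
        members = clustered.members(c)
        pdf = _cluster_pdf_matrix(queries, clustered.scaled_models[members],
                                  clustered.cluster_covs[c])
        total += pdf.sum(axis=1) / (N * len(members))
    return float(total[0]) if single else total


@dataclass
class ModelProbabilities:
    """Discrete probability per model, aligned with the clustering labels."""

    p: np.ndarray
    labels: np.ndarray

    def __len__(self):
        return len(self.p)

    def cluster_mass(self, c: int) -> float:
        return float(self.p[self.labels == c].sum())


def discrete_probabilities(clustered: ClusteredEnsemble) -> ModelProbabilities:
    """Discrete model probabilities p_iC ∝ density at the model's position,
    normalized within each cluster so that each cluster's mass is 1/N."""
    dens = density(clustered, clustered.scaled_models)
    N = clustered.n_clusters
    p = np.empty_like(dens)
    for c in range(N):
        members = clustered.members(c)
        mass = dens[members].sum()
        if mass <= 0:
            raise RuntimeError(f"all densities vanished numerically in cluster {c}")
        p[members] = dens[members] / (mass * N)
    return ModelProbabilities(p=p, labels=clustered.labels.copy())


def entropy(p) -> float:
    """Shannon entropy, base 10, of discrete model probabilities."""
    values = p.p if isinstance(p, ModelProbabilities) else np.asarray(p, dtype=float)
    values = values[values > 0]
    return float(-(values * np.log10(values)).sum())


@dataclass
class EnsembleDistribution:
    """An ensemble together with its fitted distribution: scaling record,
    clustering, discrete probabilities, and entropy."""

    ensemble: "object"
    scaling: ScalingRecord
    clustered: ClusteredEnsemble
    probabilities: ModelProbabilities
    entropy: float

    def __len__(self):
        return len(self.probabilities)


def fit_distribution(ensemble, config: ClusterConfig = ClusterConfig()) -> EnsembleDistribution:
    """Scale, cluster and weight an :class:`~regens.ensemble_builder.Ensemble`."""
    scaled, record = minmax_scale(ensemble.vectors)
    clustered = cluster_models(scaled, config)
    probs = discrete_probabilities(clustered)
    return EnsembleDistribution(
        ensemble=ensemble, scaling=record, clustered=clustered,
        probabilities=probs, entropy=entropy(probs))
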