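"""Construction of an ensemble of well-fitting models.

The wild-type ensemble is built in four stages: (1) stratified uniform
sampling of the parameter space — the range of each of the D parameters is
split into two halves on its declared scale and the same number of points is
drawn uniformly in each of the 2^D cells; (2) a coarse filter keeping models
whose goodness-of-fit (mean squared error against the target profile) is
below a modest threshold; (3) derivative-free local optimization seeded at
every retained model; (4) a strict filter on the optimized models, followed
by de-duplication of near-identical parameter vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as _sciopt

from .thermo_model import ModelParameters, _pair_key

__all__ = [
    "Dimension",
    "ParameterSpace",
    "Ensemble",
    "EnsembleConfig",
    "OptimizerSettings",
    "BudgetError",
    "EmptyEnsembleError",
    "parameter_space_for",
    "grid_plan",
    "sample_parameter_grid",
    "iter_parameter_cells",
    "score_vectors",
    "coarse_filter",
    "local_optimize",
    "build_ensemble",
]

# default parameter ranges, per parameter kind
DEFAULT_BOUNDS = {
    "K": (1e-2, 1e2, "log"),
    "alpha_activator": (1.0, 50.0, "linear"),
    "alpha_repressor": (1e-3, 1.0, "log"),
    "coop": (1.0, 10.0, "linear"),
    "q_btm": (5e-3, 0.5, "log"),
    "atten": (1e-2, 1.0, "linear"),
}


class BudgetError(ValueError):
    """Requested sampling plan exceeds the configured budget."""


class EmptyEnsembleError(RuntimeError):
    """No model survived the strict goodness-of-fit filter."""


@dataclass(frozen=True)
class Dimension:
    """One axis of the parameter space."""

    name: str
    lower: float
    upper: float
    scale: str = "linear"

    def __post_init__(self):
        if self.scale not in ("linear", "log"):
            raise ValueError(f"dimension {self.name!r}: scale must be 'linear' or 'log'")
        if not self.lower < self.upper:
            raise ValueError(f"dimension {self.name!r}: lower must be < upper")
        if self.scale == "log" and self.lower <= 0:
            raise ValueError(f"dimension {self.name!r}: log scale requires positive bounds")


class ParameterSpace:
    """A box in R^D with per-dimension sampling scales and a naming
    convention mapping coordinates to :class:`ModelParameters` entries:
    ``K_<tf>``, ``alpha_<tf>``, ``coop_<a>__<b>``, ``q_btm``, ``atten_<tf>``.
    """

    def __init__(self, dims):
        self.dims = tuple(dims)
        names = [d.name for d in self.dims]
        if len(set(names)) != len(names):
            raise ValueError("duplicate dimension names")
        self._index = {d.name: i for i, d in enumerate(self.dims)}

    @property
    def D(self) -> int:
        return len(self.dims)

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.dims]

    def __repr__(self):
        return f"ParameterSpace(D={self.D}, dims={self.names})"

    # transformed ("sampling") coordinates: log dims in log10 space
    def transform(self, vectors: np.ndarray) -> np.ndarray:
        vectors = np.atleast_2d(np.asarray(vectors, dtype=float)).copy()
        for i, d in enumerate(self.dims):
            if d.scale == "log":
                vectors[:, i] = np.log10(vectors[:, i])
        return vectors

    def inverse_transform(self, coords: np.ndarray) -> np.ndarray:
        coords = np.atleast_2d(np.asarray(coords, dtype=float)).copy()
        for i, d in enumerate(self.dims):
            if d.scale == "log":
                coords[:, i] = 10.0 ** coords[:, i]
        return coords

    def transformed_bounds(self) -> np.ndarray:
        bounds = np.empty((self.D, 2))
        for i, d in enumerate(self.dims):
            lo, hi = d.lower, d.upper
            if d.scale == "log":
                lo, hi = math.log10(lo), math.log10(hi)
            bounds[i] = (lo, hi)
        return bounds

    def unit_scale(self, vectors: np.ndarray) -> np.ndarray:
        """Map vectors to the unit cube on the declared scales."""
        bounds = self.transformed_bounds()
        t = self.transform(vectors)
        return (t - bounds[:, 0]) / (bounds[:, 1] - bounds[:, 0])

    def contains(self, vector: np.ndarray, atol: float = 1e-9) -> bool:
        vector = np.asarray(vector, dtype=float)
        lo = np.array([d.lower for d in self.dims])
        hi = np.array([d.upper for d in self.dims])
        return bool(np.all(vector >= lo - atol) and np.all(vector <= hi + atol))

    def clip(self, vector: np.ndarray) -> np.ndarray:
        lo = np.array([d.lower for d in self.dims])
        hi = np.array([d.upper for d in self.dims])
        return np.clip(np.asarray(vector, dtype=float), lo, hi)

    # mapping to/from ModelParameters
    def to_vector(self, params: ModelParameters) -> np.ndarray:
        vec = np.empty(self.D)
        for i, d in enumerate(self.dims):
            kind, key = _parse_dim_name(d.name)
            if kind == "K":
                vec[i] = params.K[key]
            elif kind == "alpha":
                vec[i] = params.alpha[key]
            elif kind == "coop":
                vec[i] = params.coop[_pair_key(*key)]
            elif kind == "q_btm":
                vec[i] = params.q_btm
            else:
                vec[i] = params.atten[key]
        return vec

    def from_vector(self, vector: np.ndarray) -> ModelParameters:
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (self.D,):
            raise ValueError(f"expected vector of length {self.D}, got {vector.shape}")
        K, alpha, coop, atten = {}, {}, {}, {}
        q_btm = None
        for i, d in enumerate(self.dims):
            kind, key = _parse_dim_name(d.name)
            if kind == "K":
                K[key] = float(vector[i])
            elif kind == "alpha":
                alpha[key] = float(vector[i])
            elif kind == "coop":
                coop[_pair_key(*key)] = float(vector[i])
            elif kind == "q_btm":
                q_btm = float(vector[i])
            else:
                atten[key] = float(vector[i])
        if q_btm is None:
            raise ValueError("parameter space lacks a q_btm dimension")
        return ModelParameters(K=K, alpha=alpha, q_btm=q_btm, coop=coop, atten=atten)


def _parse_dim_name(name: str):
    if name == "q_btm":
        return "q_btm", None
    for prefix in ("K_", "alpha_", "atten_"):
        if name.startswith(prefix):
            return prefix[:-1], name[len(prefix):]
    if name.startswith("coop_"):
        a, b = name[len("coop_"):].split("__")
        return "coop", (a, b)
    raise ValueError(f"unrecognized dimension name {name!r}")


def parameter_space_for(scenario, bounds: dict | None = None) -> ParameterSpace:
    """Build the canonical parameter space for a modeling scenario.

    Binding constants ``K`` of all TFs, potencies of repressors and
    ``q_btm`` are sampled on log scale; activator potencies, cooperativity
    weights and attenuation factors on linear scale.  ``bounds`` may
    override entries of :data:`DEFAULT_BOUNDS` by kind, or individual
    dimensions by full name.
    """
    table = dict(DEFAULT_BOUNDS)
    overrides = bounds or {}
    table.update({k: v for k, v in overrides.items() if k in table})

    def _dim(name, kind):
        lo, hi, scale = overrides.get(name, table[kind])
        return Dimension(name, lo, hi, scale)

    dims = []
    for tf in scenario.tfs:
        dims.append(_dim(f"K_{tf.name}", "K"))
    for tf in scenario.tfs:
        kind = "alpha_activator" if tf.role == "activator" else "alpha_repressor"
        dims.append(_dim(f"alpha_{tf.name}", kind))
    for a, b in scenario.coop_pairs:
        a, b = _pair_key(a, b)
        dims.append(_dim(f"coop_{a}__{b}", "coop"))
    dims.append(_dim("q_btm", "q_btm"))
    for tf in scenario.tfs:
        if tf.attenuation_mask is not None:
            dims.append(_dim(f"atten_{tf.name}", "atten"))
    return ParameterSpace(dims)


def grid_plan(space: ParameterSpace, samples_per_cell: int) -> dict:
    """Sampling plan of the half-range stratification, without materializing
    any sample: each dimension is split into two halves on its declared
    scale, giving ``2**D`` cells with ``samples_per_cell`` points each."""
    if samples_per_cell < 1:
        raise ValueError("samples_per_cell must be >= 1")
    n_cells = 2 ** space.D
    return {
        "n_dimensions": space.D,
        "n_cells": n_cells,
        "samples_per_cell": int(samples_per_cell),
        "total": n_cells * int(samples_per_cell),
    }


def iter_parameter_cells(space: ParameterSpace, samples_per_cell: int, seed: int):
    """Yield ``(cell_index, vectors)`` for each of the 2^D half-range cells.

    ``vectors`` is a ``samples_per_cell x D`` array on the natural scale.
    Bit ``d`` of ``cell_index`` selects the upper half of dimension ``d``.
    Streaming generation keeps memory flat for large plans.
    """
    plan = grid_plan(space, samples_per_cell)
    rng = np.random.default_rng(seed)
    bounds = space.transformed_bounds()
    mids = bounds.mean(axis=1)
    for cell in range(plan["n_cells"]):
        lows = np.where([(cell >> d) & 1 for d in range(space.D)], mids, bounds[:, 0])
        highs = np.where([(cell >> d) & 1 for d in range(space.D)], bounds[:, 1], mids)
        coords = rng.uniform(lows, highs, size=(samples_per_cell, space.D))
        yield cell, space.inverse_transform(coords)


def sample_parameter_grid(space: ParameterSpace, samples_per_cell: int, seed: int,
                          budget: int = 2_000_000) -> np.ndarray:
    """Materialize the full stratified sample (total = 2^D * samples_per_cell).

    Raises :class:`BudgetError` when the plan exceeds ``budget`` points;
    use :func:`iter_parameter_cells` to stream larger plans.
    """
    plan = grid_plan(space, samples_per_cell)
    if plan["total"] > budget:
        raise BudgetError(
            f"plan of {plan['total']} points exceeds budget {budget}; reduce "
            f"samples_per_cell or the number of dimensions, or stream with "
            f"iter_parameter_cells()")
    out = np.empty((plan["total"], space.D))
    for cell, vectors in iter_parameter_cells(space, samples_per_cell, seed):
        out[cell * samples_per_cell:(cell + 1) * samples_per_cell] = vectors
    return out


def score_vectors(vectors: np.ndarray, scenario, space: ParameterSpace) -> np.ndarray:
    """Goodness-of-fit (mean squared error vs. the scenario target) per model."""
    vectors = np.atleast_2d(vectors)
    return np.array([scenario.score(space.from_vector(v)) for v in vectors])


def coarse_filter(vectors: np.ndarray, scenario, space: ParameterSpace,
                  threshold: float, scores: np.ndarray | None = None):
    """Keep models whose score is below ``threshold``; returns (vectors, scores)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    vectors = np.atleast_2d(vectors)
    if scores is None:
        scores = score_vectors(vectors, scenario, space)
    keep = scores < threshold
    return vectors[keep], scores[keep]


@dataclass(frozen=True)
class OptimizerSettings:
    """Bounded Nelder–Mead settings (run on the declared sampling scales)."""

    maxfev: int = 2000
    xatol: float = 1e-4
    fatol: float = 1e-8


def local_optimize(seed_vector: np.ndarray, objective, space: ParameterSpace,
                   settings: OptimizerSettings = OptimizerSettings()):
    """Locally optimize ``objective`` (a function of the natural-scale
    vector) starting at ``seed_vector``; log-scaled dimensions are optimized
    in log space, and the search is bounded to the space.

    Returns ``(vector, score)`` with ``score <= objective(seed_vector)``.
    """
    seed_vector = space.clip(seed_vector)
    bounds = space.transformed_bounds()
    x0 = space.transform(seed_vector)[0]

    def _transformed_objective(coords):
        value = objective(space.inverse_transform(coords)[0])
        if not np.isfinite(value):
            params = space.inverse_transform(coords)[0]
            bad = [d.name for d, v in zip(space.dims, params) if not np.isfinite(v)]
            raise FloatingPointError(
                f"non-finite objective at parameters {bad or list(space.names)}")
        return value

    seed_score = _transformed_objective(x0)
    result = _sciopt.minimize(
        _transformed_objective, x0, method="Nelder-Mead",
        bounds=[tuple(b) for b in bounds],
        options={"maxfev": settings.maxfev, "xatol": settings.xatol,
                 "fatol": settings.fatol},
    )
    if result.fun <= seed_score:
        best = space.clip(space.inverse_transform(result.x)[0])
        return best, float(result.fun)
    return seed_vector, float(seed_score)


@dataclass(frozen=True)
class EnsembleConfig:
    """Pipeline settings: coarse threshold ``tau1``, strict threshold
    ``tau2`` (<= tau1), per-cell sample count, seed, de-duplication radius
    (max-norm on unit-scaled vectors), sampling budget, and an optional cap
    on the number of optimization seeds (best-scoring kept)."""

    samples_per_cell: int = 100
    seed: int = 0
    tau1: float = 0.10
    tau2: float = 0.05
    dedup_radius: float = 1e-3
    budget: int = 2_000_000
    max_seeds: int | None = None
    optimizer: OptimizerSettings = field(default_factory=OptimizerSettings)

    def __post_init__(self):
        if self.tau2 > self.tau1:
            raise ValueError("tau2 must be <= tau1")


@dataclass
class Ensemble:
    """Fit models (rows of ``vectors``, natural scale) with their scores."""

    vectors: np.ndarray
    scores: np.ndarray
    space: ParameterSpace
    provenance: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.vectors)

    def parameters(self, i: int) -> ModelParameters:
        return self.space.from_vector(self.vectors[i])

    def with_model(self, vector: np.ndarray, score: float) -> "Ensemble":
        """A new ensemble with one extra model appended (e.g. a reference
        model known to fit), skipped if a near-duplicate already exists."""
        unit = self.space.unit_scale(np.vstack([self.vectors, vector]))
        dist = np.abs(unit[:-1] - unit[-1]).max(axis=1)
        radius = self.provenance.get("dedup_radius", 1e-3)
        if len(self.vectors) and dist.min() < radius:
            return self
        return Ensemble(
            vectors=np.vstack([self.vectors, vector]),
            scores=np.append(self.scores, score),
            space=self.space,
            provenance=dict(self.provenance),
        )


def _deduplicate(vectors, scores, space, radius):
    order = np.argsort(scores, kind="stable")
    unit = space.unit_scale(vectors)
    kept: list[int] = []
    for i in order:
        if all(np.abs(unit[i] - unit[j]).max() >= radius for j in kept):
            kept.append(i)
    kept = sorted(kept)
    return vectors[kept], scores[kept]


def build_ensemble(space: ParameterSpace, scenario,
                   config: EnsembleConfig = EnsembleConfig()) -> Ensemble:
    """Run the full sample -> coarse filter -> optimize -> strict filter ->
    de-duplicate pipeline and return the resulting ensemble."""
    plan = grid_plan(space, config.samples_per_cell)
    if plan["total"] > config.budget:
        raise BudgetError(
            f"plan of {plan['total']} points exceeds budget {config.budget}")

    seeds: list[np.ndarray] = []
    seed_scores: list[float] = []
    for _, vectors in iter_parameter_cells(space, config.samples_per_cell, config.seed):
        kept, kept_scores = coarse_filter(vectors, scenario, space, config.tau1)
        seeds.extend(kept)
        seed_scores.extend(kept_scores)

    if config.max_seeds is not None and len(seeds) > config.max_seeds:
        order = np.argsort(seed_scores, kind="stable")[:config.max_seeds]
        seeds = [seeds[i] for i in order]
        seed_scores = [seed_scores[i] for i in order]

    objective = lambda v: scenario.score(space.from_vector(v))
    optimized = []
    optimized_scores = []
    for vec in seeds:
        best, score = local_optimize(vec, objective, space, config.optimizer)
        optimized.append(best)
        optimized_scores.append(score)

    optimized = np.array(optimized).reshape(-1, space.D)
    optimized_scores = np.array(optimized_scores)
    strict = optimized_scores < config.tau2
    if not strict.any():
        raise EmptyEnsembleError(
            f"no model reached the strict threshold {config.tau2}; consider "
            f"relaxing thresholds or increasing samples_per_cell")
    vectors, scores = _deduplicate(
        optimized[strict], optimized_scores[strict], space, config.dedup_radius)
    provenance = {
        "seed": config.seed,
        "samples_per_cell": config.samples_per_cell,
        "total_sampled": plan["total"],
        "tau1": config.tau1,
        "tau2": config.tau2,
        "dedup_radius": config.dedup_radius,
        "n_coarse": len(seeds),
        "optimizer": {"maxfev": config.optimizer.maxfev,
                      "xatol": config.optimizer.xatol,
                      "fatol": config.optimizer.fatol},
    }
    return Ensemble(vectors=vectors, scores=scores, space=space, provenance=provenance)
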