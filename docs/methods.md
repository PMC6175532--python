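# Methods

This note records the modeling assumptions, parameter conventions, and
numerical choices behind `regens`, in the spirit of a model-description
appendix.

## Thermodynamic readout

The readout model is an equilibrium configuration sum over binding states
of an enhancer.  A *configuration* is any subset of annotated sites whose
footprints (half-open intervals on the sequence) are pairwise disjoint;
overlapping sites are sterically exclusive.  Site weights are
`q_i(b) = K_f · c_f(b) · r_i · a_f(b)`:

- `K_f` — binding constant of factor `f` at its optimal site (free
  parameter, dimensionless, sampled on log scale over [1e-2, 1e2]);
- `c_f(b)` — factor concentration in spatial bin `b`, scaled to [0, 1];
- `r_i = exp(llr_i − llr_max)` — relative affinity of the specific site,
  from the PWM log-likelihood ratio in nats against the background
  composition;
- `a_f(b) = 1 − m_f(b) · (1 − atten_f)` — optional regional attenuation of
  binding: `m_f(b) ∈ [0, 1]` is a fixed per-bin mask describing *where*
  binding is attenuated (e.g. by signaling), `atten_f ∈ (0, 1]` a free
  parameter describing *how strongly*.  Where the mask is 1 the weight is
  multiplied by `atten_f`; where it is 0 nothing happens.

Activation and repression act through the potency `α_f` multiplying the
weight of BTM-bound configurations: `Z_on = q_btm · Σ_c W(c) Π α`,
`Z_off = Σ_c W(c)`, expression `= Z_on/(Z_on + Z_off)`.  With no sites (or
all concentrations zero) this reduces to the basal level
`q_btm/(1+q_btm)`.  Repression therefore operates by inflating `Z_off`
relative to `Z_on`: a strongly bound repressor with `α ≪ 1` sequesters
statistical weight into non-productive configurations.

Cooperativity `w` applies between *adjacent* bound sites of a declared
factor pair whose gap (end of one to start of the next) is at most 50 bp
(configurable).  The configuration sums are computed by a dynamic program
over sites sorted by end coordinate, vectorized across bins; the unit test
suite checks exact agreement with brute-force enumeration over all
compatible subsets on hundreds of random instances.

Goodness of fit is the mean squared per-bin error between prediction and
target on the common [0, 1] scale, so thresholds quoted as percentages
("below 10%") are scale- and bin-count-free.  Mean rather than summed
squares is a convention choice; the normalization behind published
percentage thresholds for this model family is not standardized.

## Parameter space and ensemble construction

The canonical space for a scenario has one `K` per factor, one `α` per
factor, one weight per declared cooperative pair, `q_btm`, and one
attenuation factor per masked factor — 13 dimensions for the five-factor
lateral-stripe scenario.  `K` (all factors), repressor `α`, and `q_btm`
are sampled and optimized on log10 scale; activator `α` (range [1, 50]),
cooperativity ([1, 10]) and attenuation ((0, 1]) on linear scale.

Ensemble construction: (1) split every dimension's range into two halves
on its declared scale and draw the same number of uniform points in each
of the 2^D cells (the plan's arithmetic is available without materializing
samples, and cells are generated streamingly so memory stays flat);
(2) retain samples scoring below a coarse threshold τ1; (3) locally
optimize each retained sample with bounded Nelder–Mead (`maxfev` capped;
the optimized point is never accepted if worse than its seed); (4) retain
optimized models scoring below a strict threshold τ2 < τ1; (5) de-duplicate:
two models are duplicates when their coordinates, affinely mapped to the
unit cube via the space bounds, differ by less than 1e-3 in max-norm; the
better-scoring member is kept.  The bounds-based map is used rather than
ensemble min–max because it does not change as the ensemble grows.

Default thresholds are τ1 = 0.10, τ2 = 0.05.  For the bundled synthetic
scenarios the study runs use τ1 = 0.02, τ2 = 0.005: the lateral-stripe
target is zero in 43 of 50 bins, so a model predicting *no expression
anywhere* already scores ≈ 0.049 — a 0.05 threshold cannot distinguish
fitting the stripe from ignoring it.  The stricter values sit an order of
magnitude below that null score while local optimization routinely reaches
1e-4; they are configuration values, not constants.

## Distribution over the ensemble, and entropy

Ensemble vectors are min–max scaled per dimension to [0, 1] (degenerate
dimensions map to 0).  Clustering fits Gaussian mixtures over component
counts 1–20 and covariance structures {spherical, diagonal, full},
selecting by BIC; each model is assigned to its maximum-responsibility
component, empty components are dropped, and each cluster's covariance
`Σ_C` is taken from its mixture component plus `1e-6·I` regularization.
The rationale for re-deriving a custom density rather than using the
fitted mixture directly: ensemble members are local optima grown from
uniform seeds, not i.i.d. draws, so cluster *occupancy* reflects sampling
artifacts, not plausibility.  The density therefore gives every cluster
equal total mass 1/N and represents a cluster as a uniform mixture of
Gaussians centered at its member models with the shared `Σ_C`.

Discrete model probabilities are proportional to this full density
(contributions from *all* Gaussians, not only the model's own cluster)
evaluated at each model, renormalized within each cluster to 1/N.  Entropy
is `−Σ p log10 p`; base 10 makes one unit of entropy "one decimal digit of
uncertainty" and keeps the uniform-within-cluster upper bound
`log10 N + (1/N) Σ log10 n_C` on a convenient scale.

## Experiments, filtering, information gain

A perturbation experiment is a perturbation operator plus a consistency
criterion.  Operators: knockout (concentration profile zeroed; for a
protein modeled as split-role species, both species are zeroed),
site mutagenesis (the strongest-k distinct site intervals of the protein
removed, ranked by relative affinity; every species' entry at a removed
interval disappears, since the DNA element is destroyed), and variant
enhancer (sites re-annotated on the new sequence).

Criterion vocabulary, with the numeric conventions for verbal effect
descriptions: `unchanged` (MSE to wild type below the strict threshold);
`profile_match` (MSE to a given profile); `peak_fraction` (peak relative
to the wild-type peak within a window — "reduced to about half" is encoded
as [0.35, 0.65]); `boundary_shift` (the outermost half-maximum crossing of
the profile on the stated side, linearly interpolated between bins, moves
outward by at least a given number of bins — "expands dorsally" defaults
to ≥ 2 bins); `abolished` (peak at or below a ceiling, default 0.1).  All
windows are configuration-exposed.

Filtering evaluates every parent model under the perturbed scenario and
keeps those satisfying the criterion, judged against the scenario's
observed wild-type profile.  The filtered distribution retains the
parent's cluster assignments and covariances, drops clusters left empty,
re-weights surviving clusters uniformly to 1/N′, and re-centers each
cluster's mixture on its surviving members only — in that order.
Information gain is the signed entropy difference; it is not clamped at
zero since nothing in the construction forbids a negative value.
Sequential gains (experiment j after experiment i) intersect the two
survivor sets and apply the same update rules at each stage; a pair of
criterion-identical experiments therefore has exactly zero mutual gain.

The "synthetic true model" selector applies experiments in order, skips
(and reports) any whose filter would empty the current candidate set, and
returns the best-fitting survivor — a greedy approximation to the maximal
jointly satisfiable subset.

## Synthetic scenarios

The generator reproduces the *structure* of two dorso-ventral patterning
systems, not their sequences: bin counts, factor roles, parameter
dimensionality and profile shapes.  Sequences are i.i.d. draws from a
uniform base composition (configurable) with motif instances planted at
chosen positions; motifs are sharp position-frequency matrices (consensus
probability 0.70, length 10) generated from consensus strings.  Planted
sites come in tiers — strong (consensus, relative affinity 1), medium
(1 mismatch, ≈ 0.14), weak (2 mismatches, ≈ 0.02) — all of which score
above the default 50%-of-optimum annotation threshold.  The bundled
scenarios annotate at 70%, which keeps the planted strong/medium tiers and
discards weak chance matches in the random background.

*Lateral-stripe scenario* (50 bins): a graded ventral activator (sigmoid,
half-max at bin 35), a uniform ubiquitous activator, a ventral repressor
(sigmoid, half-max bin 19), a banded repressor (Gaussian at bin 19.5,
width 1.5), and a uniform repressor whose binding is attenuated in the
neuroectoderm — mask a generalized Gaussian at bin 25 (width 2.5,
exponent 4, flatter-topped than a Gaussian so the stripe is not a needle).
The planted 13-parameter truth produces the target: peak at bin 25,
support confined to bins 22–28, everything outside below 8% of peak.
These constants were calibrated once so the planted model satisfies those
structural constraints, then frozen.

*Mesectoderm scenario* (25 bins): two ventral activators, a mesodermal
repressor dropping at bin ~12, and a ubiquitous role-switch factor
represented as complementary activator/repressor species sharing one motif
(their sites coincide and are treated as mutually exclusive binding
alternatives).  The target is a Gaussian at bin 12 with half-maximum width
≈ 3.1 bins.  No ground truth is planted; the target encodes an observed
pattern rather than a model output.

In-silico experiment sets: for each protein, a knockout and a
strongest-site mutagenesis whose criteria demand matching the planted
truth's perturbed prediction within MSE 0.005 (the strict fit threshold of
the study runs).

What the generator does *not* emulate: real motif information content and
site clustering, measurement noise in expression profiles, chromatin
accessibility, inter-enhancer interactions, and any dynamics.  Passing
tests demonstrate the machinery's correctness and the qualitative
phenomena (informative null results, redundant experiment pairs,
uncertainty collapse), not quantitative agreement with any real enhancer.

## Study sizes and determinism

Desk-scale study conditions: 6 samples per cell × 2^13 cells = 49,152
scored models, coarse threshold 0.02, optimization capped at 600 function
evaluations per seed, strict threshold 0.005 — a few minutes on one CPU.
The full-scale plan (1000 per cell ≈ 8.2 million models) is supported by
the streaming sampler but is a long-running job.  All randomness flows
through explicit integer seeds (sampling, mixture initialization, scenario
generation); repeated runs are byte-identical.  The planted ground truth,
which fits exactly, is appended to the built ensemble before clustering in
the recovery analyses, so that its survival under filtering is observable.

## Known limitations

- Entropies depend on ensemble size and clustering granularity; they are
  comparable between experiments on one ensemble, not across studies.
- BIC selection over mixture structures is discrete and can shift the
  cluster count under small ensemble changes; downstream gains are
  robust in the bundled studies but cluster identities are not stable
  labels.
- The Nelder–Mead cap trades optimality for throughput; optimized scores
  near τ2 may be improvable.
- `boundary_shift` assumes a single-domain profile; multi-peaked
  predictions use the outermost crossing only.
- The discrete entropy ignores cluster spans (a tight and a broad cluster
  with the same occupancy contribute alike); span information lives in
  `Σ_C` and the continuous density, not in `H`.
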