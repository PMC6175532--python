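"""Independent reference computations used to check the implementation.

These deliberately avoid the package's internal helpers: the partition
function is computed by explicit enumeration of all compatible site
subsets, and site weights are recomputed from their definitions.
"""

import itertools

import numpy as np

from regens.thermo_model import AnnotatedSite, Motif, ModelParameters, TFSpec

_DUMMY_MOTIF = Motif(name="dummy", matrix=np.full((1, 4), 0.25))


def brute_force_profile(sites, tfs, params, coop_cutoff=50.0):
    """Exhaustive configuration sum over all pairwise-disjoint site subsets."""
    by_name = {t.name: t for t in tfs}
    n_bins = len(tfs[0].concentration)
    z_off = np.ones(n_bins)
    s_on = np.ones(n_bins)
    for r in range(1, len(sites) + 1):
        for combo in itertools.combinations(sites, r):
            chain = sorted(combo, key=lambda s: (s.start, s.end))
            if any(a.end > b.start for a, b in zip(chain, chain[1:])):
                continue
            weight = np.ones(n_bins)
            alpha_product = 1.0
            for s in chain:
                spec = by_name[s.tf]
                q = params.K[s.tf] * spec.concentration * s.rel_affinity
                if spec.attenuation_mask is not None and s.tf in params.atten:
                    q = q * (1.0 - spec.attenuation_mask * (1.0 - params.atten[s.tf]))
                weight = weight * q
                alpha_product *= params.alpha[s.tf]
            for a, b in zip(chain, chain[1:]):
                if b.start - a.end <= coop_cutoff:
                    weight = weight * params.coop_weight(a.tf, b.tf)
            z_off += weight
            s_on += weight * alpha_product
    z_on = params.q_btm * s_on
    return z_on / (z_on + z_off)


def random_instance(rng, max_sites=12, n_bins=5):
    """A random (sites, tfs, params) triple for oracle comparisons."""
    n_tfs = int(rng.integers(1, 4))
    names = [f"T{i}" for i in range(n_tfs)]
    tfs = []
    for i, name in enumerate(names):
        mask = rng.uniform(size=n_bins) if (i == 0 and rng.random() < 0.5) else None
        tfs.append(TFSpec(
            name=name, role=("activator" if rng.random() < 0.5 else "repressor"),
            concentration=rng.uniform(size=n_bins), motif=_DUMMY_MOTIF,
            attenuation_mask=mask))
    n_sites = int(rng.integers(0, max_sites + 1))
    starts = np.sort(rng.integers(0, 200, size=n_sites))
    sites = [AnnotatedSite(
        start=int(start), tf=names[int(rng.integers(n_tfs))],
        strand="+-"[int(rng.integers(2))], length=int(rng.integers(3, 9)),
        llr=0.0, rel_affinity=float(rng.uniform(0.05, 1.0)))
        for start in starts]
    coop = {}
    if n_tfs >= 2 and rng.random() < 0.7:
        coop[(names[0], names[1])] = float(rng.uniform(1.0, 8.0))
    atten = {}
    if tfs[0].attenuation_mask is not None:
        atten[names[0]] = float(rng.uniform(0.05, 1.0))
    params = ModelParameters(
        K={n: float(10 ** rng.uniform(-1.5, 1.5)) for n in names},
        alpha={n: float(10 ** rng.uniform(-2, 1.5)) for n in names},
        coop=coop, q_btm=float(10 ** rng.uniform(-2, 0)), atten=atten)
    return sites, tfs, params


def eq1_density_reference(scaled_models, labels, covs, queries):
    """Direct evaluation of the cluster-balanced mixture density with
    scipy's multivariate normal, one Gaussian at a time."""
    from scipy.stats import multivariate_normal

    queries = np.atleast_2d(queries)
    clusters = np.unique(labels)
    N = len(clusters)
    total = np.zeros(len(queries))
    for c in clusters:
        members = scaled_models[labels == c]
        for mu in members:
            total += multivariate_normal.pdf(queries, mean=mu, cov=covs[c]) \
                / (N * len(members))
    return total
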