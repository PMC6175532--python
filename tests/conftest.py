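"""Shared fixtures: a fast 2-TF toy scenario, the ind/sim generators, and a
session-scoped desk-scale ensemble study used by the end-to-end tests."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from regens import ensemble_builder as eb
from regens.model_distribution import ClusterConfig, fit_distribution
from regens.synthetic_data import (Scenario, make_enhancer,
                                   make_ind_like_scenario, make_motif,
                                   make_sim_like_scenario, make_tf_profile,
                                   make_insilico_experiment_set)
from regens.thermo_model import ModelParameters, TFSpec, annotate_sites_for_tfs

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def build_toy_scenario(seed: int = 0) -> Scenario:
    """A 2-TF band scenario on 20 bins: a graded activator opposed by a
    ventral repressor, 4 planted sites, 5 free parameters."""
    n_bins = 20
    motifs = {"ACT": make_motif("ACT", "ACGGTCAGTT"),
              "REP": make_motif("REP", "TTGACCGATA")}
    act = make_tf_profile("sigmoid", n_bins, midpoint=13.0, slope=2.5)
    rep = make_tf_profile("sigmoid", n_bins, midpoint=7.0, slope=1.0)
    site_plan = [("ACT", 10, "strong"), ("REP", 40, "strong"),
                 ("ACT", 70, "medium"), ("REP", 100, "medium")]
    sequence, planted = make_enhancer(motifs, site_plan, length=140, seed=seed)
    tfs = [TFSpec("ACT", "activator", act, motifs["ACT"]),
           TFSpec("REP", "repressor", rep, motifs["REP"])]
    site_threshold = 0.7
    sites = annotate_sites_for_tfs(sequence, tfs, site_threshold)
    truth = ModelParameters(K={"ACT": 3.0, "REP": 30.0},
                            alpha={"ACT": 10.0, "REP": 0.005}, q_btm=0.02)
    scenario = Scenario(
        name="toy", sequence=sequence, motifs=motifs, tfs=tfs, sites=sites,
        target=np.zeros(n_bins), site_threshold=site_threshold,
        ground_truth=truth, seed=seed, extras={"planted_sites": planted})
    scenario.target = scenario.predict(truth)
    return scenario


@pytest.fixture(scope="session")
def toy_scenario() -> Scenario:
    return build_toy_scenario(0)


@pytest.fixture(scope="session")
def ind_scenario() -> Scenario:
    return make_ind_like_scenario(0)


@pytest.fixture(scope="session")
def sim_scenario() -> Scenario:
    return make_sim_like_scenario(0)


class DeskStudy:
    """Desk-scale ind-like study: built ensemble, ensemble + planted truth,
    fitted distribution, and the generated in-silico experiment set."""

    SAMPLES_PER_CELL = 6
    SEED = 1
    TAU1 = 0.02
    TAU2 = 0.005
    CRITERION_SSE = 0.005

    def __init__(self):
        self.scenario = make_ind_like_scenario(0)
        self.space = eb.parameter_space_for(self.scenario)
        config = eb.EnsembleConfig(
            samples_per_cell=self.SAMPLES_PER_CELL, seed=self.SEED,
            tau1=self.TAU1, tau2=self.TAU2,
            optimizer=eb.OptimizerSettings(maxfev=600))
        self.ensemble = eb.build_ensemble(self.space, self.scenario, config)
        self.truth_vector = self.space.to_vector(self.scenario.ground_truth)
        self.ensemble_with_truth = self.ensemble.with_model(
            self.truth_vector, self.scenario.score(self.scenario.ground_truth))
        self.truth_index = len(self.ensemble_with_truth) - 1
        self.distribution = fit_distribution(
            self.ensemble_with_truth, ClusterConfig(seed=0))
        self.experiments = make_insilico_experiment_set(
            self.scenario, sse_threshold=self.CRITERION_SSE)


@pytest.fixture(scope="session")
def desk_study() -> DeskStudy:
    return DeskStudy()
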