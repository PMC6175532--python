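"""Tests for perturbations, consistency criteria, ensemble filtering,
information gain, sequential gains and cross-prediction."""

import dataclasses

import numpy as np
import pytest

from regens.ensemble_builder import Dimension, Ensemble, ParameterSpace
from regens.experiment_evaluation import (Abolished, BoundaryShift,
                                          PeakFraction, PerturbationExperiment,
                                          ProfileMatch, SiteMutagenesis,
                                          TFKnockout, Unchanged,
                                          apply_perturbation,
                                          aggregate_prediction,
                                          cluster_survival_table,
                                          consistency_mask, cross_predict,
                                          filter_ensemble, half_max_crossing,
                                          information_gain, is_consistent,
                                          select_synthetic_true_model,
                                          sequential_gain_matrix)
from regens.model_distribution import (ClusteredEnsemble, EnsembleDistribution,
                                       ScalingRecord,
                                       discrete_probabilities, entropy)
from regens.synthetic_data import Scenario, make_motif
from regens.thermo_model import AnnotatedSite, TFSpec


def _stripe(n_bins=20, lo=8, hi=12, level=0.8):
    profile = np.zeros(n_bins)
    profile[lo:hi] = level
    return profile


class TestCriteria:
    def test_identical_prediction_is_unchanged(self):
        wt = _stripe()
        assert is_consistent(wt, wt, Unchanged(threshold=1e-9))

    def test_half_peak_satisfies_peak_fraction_window(self):
        wt = _stripe()
        assert is_consistent(0.5 * wt, wt, PeakFraction(0.35, 0.65))
        assert not is_consistent(0.8 * wt, wt, PeakFraction(0.35, 0.65))

    def test_flat_wild_type_makes_peak_fraction_undefined(self):
        with pytest.raises(ValueError, match="flat"):
            is_consistent(_stripe(), np.zeros(20), PeakFraction(0.35, 0.65))

    def test_dorsal_expansion_satisfies_boundary_shift(self):
        wt = _stripe(lo=8, hi=12)
        expanded = _stripe(lo=8, hi=15)
        assert is_consistent(expanded, wt, BoundaryShift("dorsal", 2))
        assert not is_consistent(wt, expanded, BoundaryShift("dorsal", 2))
        # expansion on the wrong side does not satisfy a ventral criterion
        assert not is_consistent(expanded, wt, BoundaryShift("ventral", 2))

    def test_abolished_checks_maximum_level(self):
        wt = _stripe()
        assert is_consistent(0.05 * wt, wt, Abolished(max_level=0.1))
        assert not is_consistent(0.5 * wt, wt, Abolished(max_level=0.1))

    def test_profile_match_uses_given_target(self):
        wt = _stripe()
        target = 0.5 * wt
        assert is_consistent(0.5 * wt, wt, ProfileMatch(target, 1e-9))
        assert not is_consistent(wt, wt, ProfileMatch(target, 1e-3))

    def test_half_max_crossing_interpolates_linearly(self):
        # profile rises 0 -> 1 between bins 2 and 3, falls 1 -> 0 between 5, 6
        profile = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 0.0, 0.0])
        assert half_max_crossing(profile, "ventral") == pytest.approx(2.5)
        assert half_max_crossing(profile, "dorsal") == pytest.approx(5.5)


def _two_mechanism_setup():
    """Two activators A and B; the target stripe is reachable using either.

    Cluster 0 models rely on A (alpha_B = 1, inert), cluster 1 models rely
    on B.  Knockout of A changes predictions only for cluster 0.
    """
    n_bins = 12
    conc = np.ones(n_bins)
    motif_a, motif_b = make_motif("A", "ACGTACGTAA"), make_motif("B", "GGATCCATGG")
    tfs = [TFSpec("A", "activator", conc, motif_a),
           TFSpec("B", "activator", conc.copy(), motif_b)]
    sites = [AnnotatedSite(0, "A", "+", 10, 0.0, 1.0),
             AnnotatedSite(20, "B", "+", 10, 0.0, 1.0)]
    space = ParameterSpace([
        Dimension("K_A", 0.01, 100, "log"), Dimension("K_B", 0.01, 100, "log"),
        Dimension("alpha_A", 1, 50, "linear"), Dimension("alpha_B", 1, 50, "linear"),
        Dimension("q_btm", 0.005, 0.5, "log")])
    base_a = np.array([2.0, 2.0, 20.0, 1.0, 0.02])   # uses A only
    base_b = np.array([2.0, 2.0, 1.0, 20.0, 0.02])   # uses B only
    rng = np.random.default_rng(0)
    vectors = np.vstack([base_a * (1 + 0.01 * rng.uniform(-1, 1, 5)) for _ in range(6)]
                        + [base_b * (1 + 0.01 * rng.uniform(-1, 1, 5)) for _ in range(6)])
    target_params = space.from_vector(base_a)
    scenario = Scenario(name="two-mech", sequence="N" * 40,
                        motifs={"A": motif_a, "B": motif_b}, tfs=tfs,
                        sites=sites, target=np.zeros(n_bins))
    scenario.target = scenario.predict(target_params)
    ensemble = Ensemble(vectors=vectors,
                        scores=np.array([scenario.score(space.from_vector(v))
                                         for v in vectors]),
                        space=space)
    scaled = space.unit_scale(vectors)
    labels = np.array([0] * 6 + [1] * 6)
    covs = np.stack([np.eye(5) * 1e-3, np.eye(5) * 1e-3])
    clustered = ClusteredEnsemble(scaled_models=scaled, labels=labels,
                                  cluster_covs=covs)
    probs = discrete_probabilities(clustered)
    record = ScalingRecord(mins=np.zeros(5), maxs=np.ones(5))
    dist = EnsembleDistribution(ensemble=ensemble, scaling=record,
                                clustered=clustered, probabilities=probs,
                                entropy=entropy(probs))
    return scenario, dist


ACCEPT_ALL = ProfileMatch(target=np.zeros(12), threshold=np.inf)


class TestApplyPerturbation:
    def test_knockout_zeroes_concentration(self):
        scenario, _ = _two_mechanism_setup()
        perturbed = apply_perturbation(scenario, TFKnockout("A"))
        assert np.all(perturbed.tfs[0].concentration == 0)
        assert np.all(perturbed.tfs[1].concentration == 1)
        assert np.all(scenario.tfs[0].concentration == 1)  # parent untouched

    def test_knockout_of_unknown_tf_rejected(self):
        scenario, _ = _two_mechanism_setup()
        with pytest.raises(ValueError, match="not in scenario"):
            apply_perturbation(scenario, TFKnockout("Z"))

    def test_inert_regulator_knockout_changes_nothing(self):
        scenario, dist = _two_mechanism_setup()
        perturbed = apply_perturbation(scenario, TFKnockout("B"))
        space = dist.ensemble.space
        params = space.from_vector(  # alpha_B exactly 1: B is inert
            np.array([2.0, 2.0, 20.0, 1.0, 0.02]))
        assert np.allclose(perturbed.predict(params), scenario.predict(params))

    def test_strongest_site_selection_agrees_with_argmax(self, ind_scenario):
        perturbed = apply_perturbation(ind_scenario, SiteMutagenesis("DL", 1))
        removed = set(ind_scenario.sites) - set(perturbed.sites)
        assert len(removed) == 1
        best = max((s for s in ind_scenario.sites if s.tf == "DL"),
                   key=lambda s: s.rel_affinity)
        assert removed == {best}

    def test_mutating_the_only_site_reduces_to_basal(self):
        scenario, dist = _two_mechanism_setup()
        only_a = dataclasses.replace(
            scenario, sites=[s for s in scenario.sites if s.tf == "A"])
        perturbed = apply_perturbation(only_a, SiteMutagenesis("A", 1))
        assert perturbed.sites == []
        params = dist.ensemble.parameters(0)
        basal = params.q_btm / (1 + params.q_btm)
        assert np.allclose(perturbed.predict(params), basal)

    def test_selector_matching_nothing_rejected(self):
        scenario, _ = _two_mechanism_setup()
        with pytest.raises(ValueError, match="no site"):
            apply_perturbation(scenario, SiteMutagenesis("A", positions=(999,)))

    def test_split_role_knockout_zeroes_both_species(self, sim_scenario):
        perturbed = apply_perturbation(sim_scenario, TFKnockout("SUH"))
        for tf in perturbed.tfs:
            if tf.protein == "SUH":
                assert np.all(tf.concentration == 0)


class TestFiltering:
    def test_accept_all_criterion_keeps_everything_with_zero_gain(self):
        scenario, dist = _two_mechanism_setup()
        exp = PerturbationExperiment("null", TFKnockout("A"), ACCEPT_ALL)
        filtered = filter_ensemble(dist, exp, scenario)
        assert len(filtered) == len(dist)
        assert information_gain(dist.entropy, filtered.entropy) == pytest.approx(0.0, abs=1e-12)

    def test_discriminating_knockout_leaves_single_cluster(self):
        scenario, dist = _two_mechanism_setup()
        # A-knockout leaves expression unchanged only for B-using models
        exp = PerturbationExperiment(
            "A_KO", TFKnockout("A"), Unchanged(threshold=0.005))
        filtered = filter_ensemble(dist, exp, scenario)
        labels = dist.clustered.labels[filtered.indices]
        assert set(labels) == {1}
        assert filtered.survival_counts.tolist() == [0, 6]
        assert filtered.probabilities.p.sum() == pytest.approx(1.0, abs=1e-10)

    def test_survivors_reverified_by_independent_reprediction(self):
        scenario, dist = _two_mechanism_setup()
        exp = PerturbationExperiment(
            "A_KO", TFKnockout("A"), Unchanged(threshold=0.005))
        filtered = filter_ensemble(dist, exp, scenario)
        perturbed = apply_perturbation(scenario, exp.perturbation)
        for i in range(len(dist)):
            prediction = perturbed.predict(dist.ensemble.parameters(i))
            expected = is_consistent(prediction, scenario.target, exp.criterion)
            assert (i in set(filtered.indices)) == expected

    def test_refuting_every_model_is_an_error(self):
        scenario, dist = _two_mechanism_setup()
        exp = PerturbationExperiment(
            "impossible", TFKnockout("A"),
            ProfileMatch(target=np.full(12, 0.5), threshold=1e-12))
        with pytest.raises(RuntimeError, match="refutes"):
            filter_ensemble(dist, exp, scenario)

    def test_survival_table_bookkeeping(self):
        scenario, dist = _two_mechanism_setup()
        exps = [PerturbationExperiment("A_KO", TFKnockout("A"), Unchanged(0.005)),
                PerturbationExperiment("null", TFKnockout("A"), ACCEPT_ALL)]
        table = cluster_survival_table(
            dist, [filter_ensemble(dist, e, scenario) for e in exps])
        cluster_cols = [c for c in table.columns if c.startswith("cluster_")]
        assert (table[cluster_cols].sum(axis=1) == table["total"]).all()
        assert table.loc["wild-type", "information_gain"] == 0.0
        assert table.loc["wild-type", "total"] == len(dist)


class TestSequentialGains:
    def test_diagonal_is_zero_and_telescoping_holds(self):
        scenario, dist = _two_mechanism_setup()
        exps = [PerturbationExperiment("A_KO", TFKnockout("A"), Unchanged(0.005)),
                PerturbationExperiment("null", TFKnockout("B"), ACCEPT_ALL)]
        matrix = sequential_gain_matrix(exps, dist, scenario)
        assert np.allclose(np.diag(matrix.to_numpy()), 0.0, atol=1e-12)
        # gain(i) + gain(j after i) telescopes to the entropy drop of i&j
        masks = [consistency_mask(dist, e, scenario) for e in exps]
        from regens.experiment_evaluation import _distribution_over_subset
        _, _, H_i, _ = _distribution_over_subset(dist, masks[0])
        _, _, H_ij, _ = _distribution_over_subset(dist, masks[0] & masks[1])
        total = dist.entropy - H_ij
        assert (dist.entropy - H_i) + matrix.loc["A_KO", "null"] == pytest.approx(total)

    def test_redundant_experiments_have_zero_mutual_gain(self):
        scenario, dist = _two_mechanism_setup()
        crit = Unchanged(threshold=0.005)
        exps = [PerturbationExperiment("first", TFKnockout("A"), crit),
                PerturbationExperiment("second", TFKnockout("A"), crit)]
        matrix = sequential_gain_matrix(exps, dist, scenario)
        solo = information_gain(
            dist.entropy, filter_ensemble(dist, exps[0], scenario).entropy)
        assert solo > 0
        assert matrix.loc["first", "second"] == pytest.approx(0.0, abs=1e-12)
        assert matrix.loc["second", "first"] == pytest.approx(0.0, abs=1e-12)


class TestAggregateAndCrossPredict:
    def test_unanimous_predictions_have_zero_variance(self):
        scenario, dist = _two_mechanism_setup()
        mean, var = aggregate_prediction(dist, scenario)
        assert np.all(var >= 0)
        per_model = np.array([scenario.predict(dist.ensemble.parameters(i))
                              for i in range(len(dist))])
        assert np.all(mean >= per_model.min(axis=0) - 1e-12)
        assert np.all(mean <= per_model.max(axis=0) + 1e-12)

    def test_accept_all_filter_leaves_cross_prediction_unchanged(self):
        scenario, dist = _two_mechanism_setup()
        null = PerturbationExperiment("null", TFKnockout("A"), ACCEPT_ALL)
        probe = PerturbationExperiment("B_KO", TFKnockout("B"), ACCEPT_ALL)
        report = cross_predict(null, probe, dist, scenario)
        assert np.allclose(report.parent_mean, report.filtered_mean, atol=1e-12)

    def test_informative_filter_sharpens_cross_prediction(self):
        scenario, dist = _two_mechanism_setup()
        # filtering by A-KO-unchanged removes the A-dependent mechanism;
        # the filtered ensemble then predicts B-KO to ablate expression
        a_ko = PerturbationExperiment("A_KO", TFKnockout("A"), Unchanged(0.005))
        b_ko = PerturbationExperiment("B_KO", TFKnockout("B"), ACCEPT_ALL)
        report = cross_predict(a_ko, b_ko, dist, scenario)
        assert np.all(report.filtered_var <= report.parent_var + 1e-12)
        basal = np.array([dist.ensemble.parameters(i).q_btm for i in range(len(dist))])
        assert report.filtered_mean.max() < report.parent_mean.max()


class TestSelectTruth:
    def test_single_accept_all_returns_best_fit_model(self):
        scenario, dist = _two_mechanism_setup()
        exp = PerturbationExperiment("null", TFKnockout("A"), ACCEPT_ALL)
        params, report = select_synthetic_true_model(dist, [exp], scenario)
        assert report.chosen_sse == dist.ensemble.scores.min()
        assert report.unsatisfied == ()

    def test_contradictory_criteria_flag_exactly_one_unsatisfied(self):
        scenario, dist = _two_mechanism_setup()
        changed = PerturbationExperiment(
            "changed", TFKnockout("A"), Abolished(max_level=0.1))
        unchanged = PerturbationExperiment(
            "unchanged", TFKnockout("A"), Unchanged(threshold=0.005))
        params, report = select_synthetic_true_model(
            dist, [changed, unchanged], scenario)
        assert len(report.unsatisfied) == 1
        assert set(report.satisfied) | set(report.unsatisfied) == \
               {"changed", "unchanged"}

    def test_requires_at_least_one_experiment(self):
        scenario, dist = _two_mechanism_setup()
        with pytest.raises(ValueError):
            select_synthetic_true_model(dist, [], scenario)
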