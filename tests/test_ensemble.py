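"""Random-parameter ensembles, knockouts, classification, statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from emtcircuits.kinetics import ConfigurationError
from emtcircuits.ensemble import (
    KNOCKOUTS,
    SamplingRanges,
    apply_knockout,
    classify_ensemble_solution,
    compare_conditions,
    ensemble_statistics,
    label_solutions,
    paired_t,
    pca_project,
    phenotype_frequencies,
    run_ensemble,
    sample_parameters,
)
from emtcircuits.model import build_rhs, validate_params


@pytest.fixture(scope="module")
def small_control(cd44_circuit):
    return run_ensemble(cd44_circuit, n_models=60, n_replicates=2, seed=5)


class TestSampling:
    def test_same_rng_state_identical(self, cd44_circuit):
        ranges = SamplingRanges()
        a = sample_parameters(cd44_circuit, ranges, np.random.default_rng(3))
        b = sample_parameters(cd44_circuit, ranges, np.random.default_rng(3))
        assert a == b

    def test_sampled_sets_are_complete_models(self, cd44_circuit):
        rng = np.random.default_rng(0)
        for _ in range(5):
            params = sample_parameters(cd44_circuit, SamplingRanges(), rng)
            validate_params(cd44_circuit, params)  # no missing, no orphans
            build_rhs(cd44_circuit, params)

    def test_range_containment(self, cd44_circuit):
        ranges = SamplingRanges()
        rng = np.random.default_rng(1)
        for _ in range(200):
            p = sample_parameters(cd44_circuit, ranges, rng)
            for k, v in p.values.items():
                if k.startswith("g_"):
                    assert ranges.production[0] <= v <= ranges.production[1]
                elif k.startswith("k_"):
                    assert ranges.degradation[0] <= v <= ranges.degradation[1]
                elif k.endswith("_n") and k.startswith("h_"):
                    assert v == int(v) and 1 <= v <= 6
                elif k.endswith("_lam"):
                    assert 1.0 / 100.0 <= v <= 100.0

    def test_degenerate_ranges_collapse_to_identical_models(self, cd44_circuit):
        ranges = SamplingRanges(production=(10.0, 10.0), degradation=(0.5, 0.5),
                                hill_coefficient=(2, 2), fold_change=(5.0, 5.0),
                                threshold_span=(1.0, 1.0))
        rng = np.random.default_rng(0)
        a = sample_parameters(cd44_circuit, ranges, rng)
        b = sample_parameters(cd44_circuit, ranges, rng)
        assert a == b

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            SamplingRanges(production=(-1.0, 5.0))


class TestKnockout:
    def test_removed_regulator_has_no_influence(self, cd44_circuit):
        rng = np.random.default_rng(2)
        params = sample_parameters(cd44_circuit, SamplingRanges(), rng)
        ko = apply_knockout(cd44_circuit, "Cs", "mZ")
        ko_params = {k: v for k, v in params.values.items()
                     if not k.startswith("h_Cs_mZ_")}
        from emtcircuits.kinetics import KineticParameterSet
        rhs = build_rhs(ko, KineticParameterSet(ko_params))
        x = np.array([100.0, 50.0, 500.0, 30.0, 10.0, 10.0])
        i_cs, i_mz = ko.index("Cs"), ko.index("mZ")
        f0 = rhs(x)[i_mz]
        for level in (0.0, 50.0, 5000.0):
            y = x.copy()
            y[i_cs] = level
            assert rhs(y)[i_mz] == pytest.approx(f0)  # former target unaffected

    def test_knockout_of_splicing_link_makes_isoform_constitutive(self, cd44_circuit):
        ko = apply_knockout(cd44_circuit, "E1", "Cs")
        # sampled ensembles give the freed isoform its own production rate
        rng = np.random.default_rng(4)
        params = sample_parameters(ko, SamplingRanges(), rng)
        rhs = build_rhs(ko, params)
        i_e1, i_cs = ko.index("E1"), ko.index("Cs")
        x = np.full(6, 20.0)
        base = rhs(x)[i_cs]
        x[i_e1] = 500.0
        kc = rhs.degradation[i_cs]
        assert rhs(x)[i_cs] == pytest.approx(base)  # ESRP1 no longer routes CD44s
        assert base + kc * 20.0 == pytest.approx(params["g_Cs"])

    def test_knockout_of_splicing_link_on_fixed_params_leaves_half_share(
            self, extended_circuit, extended_params):
        # a fixed parameter set has no g_Cs entry: the neutralized partition
        # falls back to a constitutive half share of g_C
        ko = apply_knockout(extended_circuit, "E1", "Cs")
        rhs = build_rhs(ko, extended_params, snail=2e5)
        i_cs = ko.index("Cs")
        x = np.full(8, 20.0)
        kc = rhs.degradation[i_cs]
        assert rhs(x)[i_cs] + kc * 20.0 == pytest.approx(0.5 * extended_params["g_C"])

    def test_double_knockout_rejected(self, cd44_circuit):
        ko = apply_knockout(cd44_circuit, *KNOCKOUTS["ZEB1-ESRP1"])
        with pytest.raises(ConfigurationError, match="not present"):
            apply_knockout(ko, *KNOCKOUTS["ZEB1-ESRP1"])


class TestEnsembleRuns:
    def test_frequencies_sum_to_one(self, small_control):
        sums = small_control.frequencies.sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_fixed_seed_bit_identical(self, cd44_circuit, small_control):
        again = run_ensemble(cd44_circuit, n_models=60, n_replicates=2, seed=5)
        pd.testing.assert_frame_equal(again.solutions, small_control.solutions)
        pd.testing.assert_frame_equal(again.frequencies, small_control.frequencies)

    def test_single_default_model_in_tristable_window(self, extended_circuit,
                                                      extended_params):
        """With degenerate sampling pinned to the calibrated defaults the
        ensemble machinery recovers the three coexisting phenotypes."""
        from emtcircuits.steady import find_steady_states
        rhs = build_rhs(extended_circuit, extended_params, snail=2.05e5)
        stable = [s for s in find_steady_states(rhs, n_starts=100, seed=0,
                                                zeb_index=extended_circuit.index("mZ"))
                  if s.stable]
        assert len(stable) == 3
        assert {s.phenotype for s in stable} == {"E", "hybrid", "M"}


class TestClassification:
    def _stats(self):
        return pd.DataFrame({"mean": [3.0, 2.0], "sd": [0.5, 0.4]},
                            index=["u200", "mZ"])

    def test_pooled_mean_is_hybrid(self):
        stats = self._stats()
        sol = {"u200": 10 ** 3.0, "mZ": 10 ** 2.0}
        assert classify_ensemble_solution(sol, stats) == "hybrid"

    def test_extremes(self):
        stats = self._stats()
        assert classify_ensemble_solution({"u200": 10 ** 1.0, "mZ": 10 ** 4.0},
                                          stats) == "M"
        assert classify_ensemble_solution({"u200": 10 ** 5.0, "mZ": 10 ** 0.0},
                                          stats) == "E"

    def test_degenerate_ensemble_rejected(self):
        stats = pd.DataFrame({"mean": [3.0, 2.0], "sd": [0.0, 0.4]},
                             index=["u200", "mZ"])
        with pytest.raises(ValueError, match="degenerate"):
            classify_ensemble_solution({"u200": 10.0, "mZ": 10.0}, stats)

    def test_control_labels_invariant_under_frozen_stats(self, small_control):
        """Labeling control solutions against its own (frozen) statistics is
        exactly what run_ensemble stored."""
        labels = label_solutions(small_control.solutions, small_control.stats)
        freqs = phenotype_frequencies(small_control.solutions, labels)
        pd.testing.assert_frame_equal(freqs, small_control.frequencies)


class TestPairedT:
    def test_matches_textbook_formula_on_toy_replicates(self):
        """Three-replicate toy frequencies, hand-computed: d = (0.05, 0.02,
        0.08); mean 0.05, sd 0.03, t = 0.05/(0.03/sqrt(3)) = 2.8868."""
        t, p, degenerate = paired_t(np.array([0.05, 0.02, 0.08]))
        assert not degenerate
        assert t == pytest.approx(0.05 / (0.03 / math.sqrt(3)), rel=1e-12)
        # two-tailed p from t_2: p = 2 * (1 - F(t)); cross-check via scipy
        from scipy import stats as sps
        ref = sps.ttest_rel([0.30, 0.27, 0.33], [0.25, 0.25, 0.25])
        assert t == pytest.approx(ref.statistic, rel=1e-9)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_identical_conditions_degenerate(self):
        t, p, degenerate = paired_t(np.zeros(3))
        assert degenerate and t == 0.0 and math.isnan(p)

    def test_needs_two_replicates(self):
        with pytest.raises(ValueError):
            paired_t(np.array([0.1]))

    def test_identical_ko_reports_zero_differences(self, small_control):
        report = compare_conditions(small_control, small_control)
        assert np.all(report["difference"] == 0.0)
        assert report["degenerate"].all()


class TestPCA:
    def test_exact_line_explained_by_first_component(self):
        t = np.linspace(1, 3, 30)
        sols = pd.DataFrame({"replicate": 0, "model": range(30),
                             "u200": 10 ** t, "mZ": 10 ** (2 * t)})
        _, evr = pca_project(sols)
        assert evr[0] == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(evr) <= 1e-12)

    def test_row_permutation_changes_nothing_but_order(self, small_control):
        coords, evr = pca_project(small_control.solutions)
        perm = np.random.default_rng(0).permutation(len(small_control.solutions))
        coords2, evr2 = pca_project(small_control.solutions.iloc[perm])
        assert evr == pytest.approx(evr2, rel=1e-9)
        # same components up to sign
        back = coords2[np.argsort(perm)]
        for j in range(coords.shape[1]):
            agree = np.allclose(back[:, j], coords[:, j], atol=1e-8)
            flipped = np.allclose(back[:, j], -coords[:, j], atol=1e-8)
            assert agree or flipped

    def test_phenotype_clusters_separate_in_projection(self, small_control):
        """The labeled E/hybrid/M partition has positive silhouette in the
        2-D principal-component projection."""
        from sklearn.metrics import silhouette_score
        labels = label_solutions(small_control.solutions, small_control.stats)
        coords, _ = pca_project(small_control.solutions)
        assert silhouette_score(coords, labels) > 0.0


def test_ensemble_statistics_are_log_level_moments(small_control):
    stats = ensemble_statistics(small_control.solutions, small_control.species_names)
    logs = np.log10(small_control.solutions[small_control.species_names].to_numpy() + 1e-12)
    assert stats.loc["mZ", "mean"] == pytest.approx(logs[:, 1].mean())
    assert stats.loc["mZ", "sd"] == pytest.approx(logs[:, 1].std())
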