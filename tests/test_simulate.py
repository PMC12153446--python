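"""Synthetic-data generator: planted truth, copula sampling, missingness."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from symptomnet.association import ItemResponseMatrix
from symptomnet.screening import apply_exclusions, parse_roster
from symptomnet.simulate import (
    DEFAULT_BRIDGE_SPEC,
    GroundTruthNetwork,
    OrdinalThresholds,
    SimulationConfig,
    default_thresholds,
    inject_missingness,
    make_demographics,
    make_ground_truth,
    make_roster,
    recovery_metrics,
    sample_ordinal,
    write_roster,
)


class TestMakeGroundTruth:
    def test_empty_bridge_spec_gives_block_structure(self):
        truth = make_ground_truth(bridge_spec=(), seed=0)
        cross = truth.partials[:7, 7:]
        np.testing.assert_array_equal(cross, np.zeros((7, 10)))

    def test_default_bridges_hit_requested_weights(self):
        truth = make_ground_truth(seed=0)
        idx = {lab: k for k, lab in enumerate(truth.node_labels)}
        for a, b, w in DEFAULT_BRIDGE_SPEC:
            assert truth.partials[idx[a], idx[b]] == pytest.approx(w, abs=0.02)

    def test_precision_positive_definite(self):
        truth = make_ground_truth(seed=42)
        assert np.linalg.eigvalsh(truth.precision).min() > 0

    def test_infeasible_weights_raise(self):
        heavy = tuple((a, b, 0.95) for a, b, _ in DEFAULT_BRIDGE_SPEC)
        with pytest.raises(ValueError, match="reduce"):
            make_ground_truth(bridge_spec=heavy, seed=0,
                              chain_weight_range=(0.5, 0.6))

    def test_bridge_inside_community_rejected(self):
        with pytest.raises(ValueError, match="cross"):
            make_ground_truth(bridge_spec=(("GAD1", "GAD2", 0.2),), seed=0)

    def test_determinism(self):
        t1 = make_ground_truth(seed=7)
        t2 = make_ground_truth(seed=7)
        np.testing.assert_array_equal(t1.precision, t2.precision)


class TestSampleOrdinal:
    def test_values_in_categories(self, small_truth):
        data = sample_ordinal(small_truth, n=500, seed=0)
        assert set(np.unique(data.values)) <= {0.0, 1.0, 2.0, 3.0}

    def test_determinism(self, small_truth):
        a = sample_ordinal(small_truth, n=100, seed=5).values
        b = sample_ordinal(small_truth, n=100, seed=5).values
        np.testing.assert_array_equal(a, b)

    def test_quartile_thresholds_give_uniform_categories(self, small_truth):
        cuts = stats.norm.ppf([0.25, 0.5, 0.75])
        thr = OrdinalThresholds({lab: cuts for lab in small_truth.node_labels})
        data = sample_ordinal(small_truth, thr, n=50000, seed=1)
        for k in range(data.p):
            freqs = np.bincount(data.values[:, k].astype(int), minlength=4) / data.n
            np.testing.assert_allclose(freqs, 0.25, atol=0.01)

    def test_linked_pair_correlates_more_than_unlinked(self, small_truth):
        # A1-D1 planted at 0.3; A1-D3 has no direct edge
        hits = 0
        for seed in range(20):
            data = sample_ordinal(small_truth, n=5000, seed=100 + seed)
            rho = stats.spearmanr(data.values).statistic
            hits += abs(rho[0, 3]) > abs(rho[0, 5])
        assert hits >= 19

    def test_item_means_match_threshold_targets(self, default_truth):
        from symptomnet.simulate import DEFAULT_ITEM_MEANS

        data = sample_ordinal(default_truth, n=50000, seed=3)
        means = data.values.mean(axis=0)
        for lab, m in zip(data.node_labels, means):
            assert m == pytest.approx(DEFAULT_ITEM_MEANS[lab], abs=0.06)


class TestThresholds:
    def test_category_probabilities_sum_to_one(self):
        thr = default_thresholds()
        for lab in thr.cuts:
            np.testing.assert_allclose(
                thr.category_probabilities(lab).sum(), 1.0
            )

    def test_non_monotone_cuts_rejected(self):
        with pytest.raises(ValueError):
            OrdinalThresholds({"X": np.array([0.5, 0.1, 1.0])})


class TestInjectMissingness:
    def _roster(self, truth, n, seed=0):
        data = sample_ordinal(truth, n=n, seed=seed)
        return make_roster(data, make_demographics(n, seed=seed), seed=seed)

    def test_flow_counts_reproduced_exactly(self, default_truth, tmp_path):
        roster = self._roster(default_truth, 2477, seed=11)
        cfg = SimulationConfig(n=2477, seed=11, stage_counts=(318, 120, 87))
        spoiled = inject_missingness(roster, cfg)
        path = tmp_path / "roster.csv"
        write_roster(spoiled, path)
        _, report = apply_exclusions(parse_roster(path))
        assert report.n_initial == 2477
        assert report.n_excluded_demographic_or_incomplete == 318
        assert report.n_excluded_missing_gad == 120
        assert report.n_excluded_missing_cesd == 87
        assert report.n_final == 1952

    def test_zero_counts_remove_nothing(self, small_truth, tmp_path):
        truth = make_ground_truth(seed=2)
        roster = self._roster(truth, 50)
        spoiled = inject_missingness(roster, SimulationConfig(n=50, seed=0))
        path = tmp_path / "r.csv"
        write_roster(spoiled, path)
        retained, report = apply_exclusions(parse_roster(path))
        assert report.n_final == 50

    def test_counts_exceeding_n_raise(self, default_truth):
        roster = self._roster(default_truth, 10)
        with pytest.raises(ValueError, match="exceed"):
            inject_missingness(
                roster, SimulationConfig(n=10, seed=0, stage_counts=(9, 9, 9))
            )


class TestRecoveryMetrics:
    def test_perfect_estimate(self, small_truth):
        rep = recovery_metrics(small_truth, small_truth.as_network_model())
        assert rep["tpr_all"] == 1.0
        assert rep["fpr"] == 0.0
        assert rep["weight_correlation"] == pytest.approx(1.0)
        assert all(rep["top_bridge_match"].values())

    def test_empty_estimate_zero_tpr(self, small_truth):
        from symptomnet.ggm import NetworkModel

        empty = NetworkModel(
            np.zeros((6, 6)), small_truth.node_labels,
            small_truth.communities, 1.0, 0.5,
        )
        rep = recovery_metrics(small_truth, empty)
        assert rep["tpr_all"] == 0.0
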