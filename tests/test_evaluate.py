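import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from timepls import (
    ConfusionCounts,
    ModelSpec,
    ResponseDesign,
    SimulationConfig,
    confusion,
    permutation_test,
    prf_scores,
    run_benchmark,
    ttest_flag,
    vs_roc,
)
from timepls.evaluate import summarize_benchmark

from conftest import make_cube


class TestConfusion:
    def test_perfect_selection(self):
        truth = np.array([True] * 80 + [False] * 20)
        c = confusion(np.arange(80), truth)
        assert (c.TP, c.FP, c.FN, c.TN) == (80, 0, 0, 20)

    def test_empty_selection(self):
        truth = np.array([True] * 80 + [False] * 20)
        c = confusion([], truth)
        assert (c.TP, c.FN) == (0, 80)

    def test_matches_exhaustive_tally(self, rng):
        truth = rng.random(500) < 0.3
        sel = rng.choice(500, size=100, replace=False)
        c = confusion(sel, truth)
        mask = np.zeros(500, bool)
        mask[sel] = True
        assert c.TP == np.sum(mask & truth)
        assert c.FP == np.sum(mask & ~truth)
        assert c.FN == np.sum(~mask & truth)
        assert c.TN == np.sum(~mask & ~truth)
        assert c.TP + c.FN == truth.sum()

    def test_out_of_range_index(self):
        with pytest.raises(IndexError):
            confusion([5], np.array([True, False]))


class TestPrf:
    def test_printed_definitions(self):
        recall, precision, f1 = prf_scores(ConfusionCounts(TP=77, FP=117, FN=3, TN=2803))
        assert recall == pytest.approx(77 / 80)
        assert precision == pytest.approx(77 / 194)
        assert f1 == pytest.approx(2 * precision * recall / (precision + recall))

    def test_harmonic_fixed_point(self):
        r, p, f = prf_scores(ConfusionCounts(TP=50, FP=50, FN=50, TN=0))
        assert r == p == f == pytest.approx(0.5)

    def test_undefined_precision_is_nan(self):
        r, p, f = prf_scores(ConfusionCounts(TP=0, FP=0, FN=10, TN=90))
        assert np.isnan(p) and np.isnan(f) and r == 0.0

    @pytest.mark.parametrize("beta", [0.5, 1.0, 2.0])
    def test_beta_grid_matches_formula(self, beta):
        c = ConfusionCounts(TP=30, FP=10, FN=20, TN=40)
        r, p, f = prf_scores(c, beta=beta)
        assert f == pytest.approx((beta**2 + 1) * p * r / (beta**2 * (p + r)))


class TestVsRoc:
    def test_perfect_ranking(self):
        truth = np.array([True] * 5 + [False] * 10)
        scores = np.r_[np.arange(10, 15), np.arange(5, dtype=float).repeat(2)]
        _, auvsc = vs_roc(scores, truth)
        assert auvsc == pytest.approx(1.0)

    def test_mann_whitney_identity(self, rng):
        truth = rng.random(200) < 0.4
        scores = rng.normal(size=200) + truth
        _, auvsc = vs_roc(scores, truth)
        u = mannwhitneyu(scores[truth], scores[~truth]).statistic
        assert auvsc == pytest.approx(u / (truth.sum() * (~truth).sum()))

    def test_random_ranking_near_half(self, rng):
        aucs = [
            vs_roc(rng.normal(size=400), np.arange(400) < 100)[1] for _ in range(50)
        ]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)

    def test_single_class_undefined(self):
        with pytest.raises(ValueError):
            vs_roc(np.ones(5), np.ones(5, bool))


class TestPermutationTest:
    def test_floor_when_observed_beats_all(self):
        cube = make_cube(n_per_group=4, J=8, seed=0, signal_cols=(0, 1, 2))
        p, obs, null = permutation_test(
            cube, ModelSpec(3), ResponseDesign(), A=1, n_perm=19, seed=1
        )
        assert p >= 1 / 20
        assert len(null) == 19

    def test_seed_determinism(self):
        cube = make_cube(n_per_group=3, J=6, seed=1)
        a = permutation_test(cube, ModelSpec(1), ResponseDesign(), A=1, n_perm=9, seed=3)
        b = permutation_test(cube, ModelSpec(1), ResponseDesign(), A=1, n_perm=9, seed=3)
        assert a[0] == b[0]
        np.testing.assert_array_equal(a[2], b[2])

    def test_null_p_values_not_extreme(self):
        """On label-independent data the p-value should average near 0.5."""
        ps = []
        for rep in range(20):
            cube = make_cube(n_per_group=3, J=6, seed=300 + rep, signal_cols=())
            p, *_ = permutation_test(
                cube, ModelSpec(1), ResponseDesign(), A=1, n_perm=19, seed=rep
            )
            ps.append(p)
        assert 0.25 < np.mean(ps) < 0.75

    def test_invalid_n_perm(self, small_cube, design):
        with pytest.raises(ValueError):
            permutation_test(small_cube, ModelSpec(1), design, A=1, n_perm=0)


class TestTtestFlag:
    def test_overwhelming_effect_flagged(self, small_table):
        flags = ttest_flag(small_table)
        assert flags[0]  # the engineered signal column

    def test_alpha_zero_flags_nothing(self, small_table):
        assert not ttest_flag(small_table, alpha=0.0).any()

    def test_type_one_error_calibration(self):
        """Per-time flagging of null variables should run near the nominal
        5% rate before the min over time points."""
        from timepls import from_cube

        rates = []
        for rep in range(10):
            cube = make_cube(n_per_group=30, J=200, seed=700 + rep, signal_cols=())
            flags = ttest_flag(from_cube(cube), alpha=0.05)
            rates.append(flags.mean())
        # union over 4 time points: expected approx 1 - 0.95^4 = 0.185
        assert np.mean(rates) == pytest.approx(0.185, abs=0.06)


class TestBenchmarkHarness:
    def test_smoke_emits_all_columns(self):
        cfg = SimulationConfig(n_units_per_group=3, n_variables=100, n_discriminating=12)
        res = run_benchmark(cfg, n_repeats=1, B=10, seed=0)
        expected = {
            "repeat", "model", "n_latent", "n_selected", "TP", "FP", "FN", "TN",
            "recall", "precision", "f1", "auvsc", "q2", "auc",
        }
        assert expected <= set(res.columns)
        assert sorted(res.model) == [1, 2, 3, 4, 5]
        summary = summarize_benchmark(res)
        assert "TP_mean" in summary.columns

    def test_model2_auc_near_half(self):
        """The time-response-only model carries no group information, so
        its group classification should be at chance."""
        cfg = SimulationConfig(n_units_per_group=6, n_variables=200, n_discriminating=20)
        res = run_benchmark(cfg, models=[2], n_repeats=4, B=5, seed=1)
        assert res.auc.mean() == pytest.approx(0.5, abs=0.15)

    def test_seed_determinism(self):
        cfg = SimulationConfig(n_units_per_group=3, n_variables=60, n_discriminating=10)
        a = run_benchmark(cfg, models=[1, 4], n_repeats=2, B=5, seed=9)
        b = run_benchmark(cfg, models=[1, 4], n_repeats=2, B=5, seed=9)
        assert a.equals(b)
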