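import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from timepls import (
    BilinearPLS,
    ModelSpec,
    ResponseDesign,
    TrilinearPLS,
    balanced_bootstrap_indices,
    bootstrap_vip,
    select_by_loading_weight,
    select_variables,
    vip_bilinear,
    vip_trilinear,
)
from timepls.vip import VipStats

from conftest import make_cube


class _FakeModel(BilinearPLS):
    """Bilinear model with weights/ssy set directly (for formula checks)."""

    def __init__(self, W, ssy):
        super().__init__(n_components=W.shape[1])
        self.x_weights_ = np.asarray(W, dtype=float)
        self.ssy_ = np.asarray(ssy, dtype=float)


class TestVipFormula:
    def test_uniform_weights_give_unit_vip(self):
        W = np.full((4, 1), 0.5)
        np.testing.assert_allclose(vip_bilinear(_FakeModel(W, [3.0])), 1.0)

    def test_single_concentrated_weight(self):
        W = np.array([[1.0], [0.0], [0.0], [0.0]])
        np.testing.assert_allclose(vip_bilinear(_FakeModel(W, [2.0])), [2, 0, 0, 0])

    def test_normalization_identity_bilinear(self, rng):
        X = rng.normal(size=(20, 7))
        y = X @ rng.normal(size=7) + rng.normal(size=20)
        m = BilinearPLS(n_components=3).fit(X, y)
        v = vip_bilinear(m)
        assert np.sum(v**2) == pytest.approx(7.0, abs=1e-6)

    def test_normalization_identity_trilinear(self, rng):
        cube = rng.normal(size=(8, 6, 4))
        y = rng.normal(size=8)
        m = TrilinearPLS(n_components=2).fit(cube, y)
        v = vip_trilinear(m)
        assert np.sum(v**2) == pytest.approx(6.0, abs=1e-6)

    def test_single_component_trilinear_reduction(self, rng):
        cube = rng.normal(size=(6, 5, 3))
        y = rng.normal(size=6)
        m = TrilinearPLS(n_components=1).fit(cube, y)
        np.testing.assert_allclose(
            vip_trilinear(m), np.sqrt(5) * np.abs(m.wj_[:, 0]), atol=1e-10
        )


class TestBalancedBootstrap:
    def test_exact_balance_small(self):
        sets = balanced_bootstrap_indices(3, 2, seed=0)
        counts = np.bincount(np.concatenate(sets), minlength=3)
        np.testing.assert_array_equal(counts, [2, 2, 2])

    def test_exact_balance_b200(self):
        sets = balanced_bootstrap_indices(10, 200, seed=1)
        assert len(sets) == 200 and all(len(s) == 10 for s in sets)
        counts = np.bincount(np.concatenate(sets), minlength=10)
        np.testing.assert_array_equal(counts, np.full(10, 200))

    def test_seed_determinism(self):
        a = balanced_bootstrap_indices(6, 5, seed=3)
        b = balanced_bootstrap_indices(6, 5, seed=3)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    @settings(max_examples=20, derandomize=True)
    @given(st.integers(2, 12), st.integers(1, 20))
    def test_balance_property(self, n, B):
        counts = np.bincount(
            np.concatenate(balanced_bootstrap_indices(n, B, seed=n * 31 + B)), minlength=n
        )
        np.testing.assert_array_equal(counts, np.full(n, B))


class TestBootstrapVip:
    def test_b1_degenerate(self, small_cube, design):
        stats = bootstrap_vip(small_cube, ModelSpec(1), design, A=1, B=1, seed=0)
        np.testing.assert_allclose(stats.sd, 0.0)
        assert stats.B == 1

    def test_seed_reproducibility(self, small_cube, design):
        a = bootstrap_vip(small_cube, ModelSpec(3), design, A=2, B=10, seed=4)
        b = bootstrap_vip(small_cube, ModelSpec(3), design, A=2, B=10, seed=4)
        np.testing.assert_array_equal(a.mean, b.mean)
        np.testing.assert_array_equal(a.sd, b.sd)

    def test_signal_variable_outranks_noise(self):
        """A strongly discriminating variable should attain a higher mean
        VIP than every pure-noise variable in nearly all replicates."""
        wins = 0
        reps = 25
        for rep in range(reps):
            cube = make_cube(n_per_group=4, J=8, seed=500 + rep, signal_cols=(0,))
            stats = bootstrap_vip(cube, ModelSpec(3), ResponseDesign(), A=1, B=30, seed=rep)
            wins += stats.mean[0] == stats.mean.max()
        assert wins / reps >= 0.95

    def test_ranks_are_permutation(self, small_cube, design):
        stats = bootstrap_vip(small_cube, ModelSpec(4), design, A=1, B=5, seed=2)
        assert sorted(stats.rank) == list(range(1, small_cube.shape[1] + 1))


class TestSelectionRules:
    @pytest.mark.parametrize(
        "mean,sd,expected",
        [
            (1.5, 0.4, True),  # 1.1 > 1
            (1.5, 0.5, False),  # boundary: strict inequality
            (0.9, 0.0, False),
        ],
    )
    def test_one_sd_rule(self, mean, sd, expected):
        stats = VipStats(["v1"], np.array([mean]), np.array([sd]), B=10)
        assert (0 in select_variables(stats)) is expected

    def test_monotone_in_threshold(self, small_cube, design):
        stats = bootstrap_vip(small_cube, ModelSpec(3), design, A=1, B=20, seed=9)
        low = set(select_variables(stats, threshold=0.8))
        high = set(select_variables(stats, threshold=1.2))
        assert high <= low

    def test_loading_weight_rule_recovers_dominant_variable(self):
        cube = make_cube(n_per_group=4, J=8, seed=77, signal_cols=(0,))
        sel, stats = select_by_loading_weight(
            cube, ModelSpec(4), ResponseDesign(), A=1, B=30, seed=0
        )
        assert 0 in sel
        assert stats.selection_rule == "loading_weight"

    def test_loading_weight_component_out_of_range(self, small_cube, design):
        with pytest.raises(ValueError):
            select_by_loading_weight(small_cube, ModelSpec(4), design, A=1, B=2, component=2)

    def test_csv_roundtrip(self, tmp_path, small_cube, design):
        stats = bootstrap_vip(small_cube, ModelSpec(1), design, A=1, B=3, seed=0)
        stats.to_csv(tmp_path / "vip.csv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "vip.csv")
        assert list(df.columns) == ["variable_id", "vip_mean", "vip_sd", "rank", "selected"]
        assert len(df) == small_cube.shape[1]
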