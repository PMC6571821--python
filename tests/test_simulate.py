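import numpy as np
import pytest

from timepls import (
    DEFAULT_CLASSES,
    SimulationConfig,
    draw_subject_terms,
    mean_curve,
    simulate_dataset,
    simulate_train_test,
    simulate_variable,
)


class TestMeanCurve:
    def test_baseline_at_zero(self):
        assert mean_curve(2.0, 3.0, 1.0, 0.5, [0.0])[0] == pytest.approx(2.0)

    def test_flat_profile_when_amplitude_zero(self):
        np.testing.assert_allclose(mean_curve(1.5, 0.0, 1.0, 1.0, [0, 2, 4, 24]), 1.5)

    def test_peak_location_is_alpha_over_beta(self):
        # calculus: d/dt [a t^alpha e^(-beta t)] = 0 at t = alpha/beta
        alpha, beta = 1.4, 0.7
        grid = np.linspace(0.01, 24, 20000)
        mu = mean_curve(0.0, 2.0, alpha, beta, grid)
        assert grid[np.argmax(mu)] == pytest.approx(alpha / beta, abs=0.01)

    def test_nonpositive_alpha_with_zero_time(self):
        with pytest.raises(ValueError):
            mean_curve(1.0, 2.0, -0.5, 0.5, [0.0, 2.0])


class TestSubjectTerms:
    def test_inter_individual_term_constant_over_time(self):
        cfg = SimulationConfig(n_variables=10, n_discriminating=2)
        b, w, e = draw_subject_terms(cfg, seed=0)
        assert np.ptp(b) == 0.0

    def test_b_covariance_is_all_ones_structure(self):
        cfg = SimulationConfig(n_variables=10, n_discriminating=2, sigma_b=0.3)
        rng = np.random.default_rng(1)
        draws = np.array([draw_subject_terms(cfg, rng)[0] for _ in range(10_000)])
        cov = np.cov(draws.T)
        se = 3 * 0.09 * np.sqrt(2 / 10_000) * 10  # generous 3-se band
        assert np.abs(cov - 0.09).max() < max(se, 0.01)

    def test_ar1_lag1_correlation(self):
        cfg = SimulationConfig(n_variables=10, n_discriminating=2, sigma_w=0.5, rho=0.6)
        rng = np.random.default_rng(2)
        draws = np.array([draw_subject_terms(cfg, rng)[1] for _ in range(10_000)])
        corr = np.corrcoef(draws[:, 0], draws[:, 1])[0, 1]
        assert corr == pytest.approx(0.6, abs=0.03)

    def test_rho_zero_uncorrelated(self):
        cfg = SimulationConfig(n_variables=10, n_discriminating=2, sigma_w=0.5, rho=0.0)
        rng = np.random.default_rng(3)
        draws = np.array([draw_subject_terms(cfg, rng)[1] for _ in range(10_000)])
        corr = np.corrcoef(draws[:, 0], draws[:, 1])[0, 1]
        assert abs(corr) < 0.04

    def test_rho_out_of_range(self):
        with pytest.raises(ValueError):
            SimulationConfig(rho=1.0)


class TestSimulateVariable:
    def _noise_free(self):
        return SimulationConfig(
            n_units_per_group=3, n_variables=10, n_discriminating=2,
            sigma_b=0.0, sigma_w=0.0, sigma_e=0.0,
        )

    def test_noise_free_limit_reproduces_mean_curves(self):
        cfg = self._noise_free()
        rng = np.random.default_rng(0)
        X, truth = simulate_variable(DEFAULT_CLASSES["a"], cfg, rng)
        mu_int = mean_curve(
            truth["c_intervention"], truth["a_intervention"],
            truth["alpha_intervention"], truth["beta_intervention"], cfg.times,
        )
        for s in range(3, 6):  # intervention units
            np.testing.assert_allclose(X[s], mu_int, atol=1e-12)

    def test_flat_class_constant_mean(self):
        cfg = self._noise_free()
        X, truth = simulate_variable(DEFAULT_CLASSES["h"], cfg, np.random.default_rng(1))
        assert np.ptp(X) == pytest.approx(0.0, abs=1e-12)

    def test_sample_mean_approaches_mean_curve(self):
        cfg = SimulationConfig(
            n_units_per_group=1000, n_variables=10, n_discriminating=2,
            sigma_b=0.3, sigma_w=0.2, sigma_e=0.1,
        )
        X, truth = simulate_variable(DEFAULT_CLASSES["b"], cfg, np.random.default_rng(2))
        mu_int = mean_curve(
            truth["c_intervention"], truth["a_intervention"],
            truth["alpha_intervention"], truth["beta_intervention"], cfg.times,
        )
        emp = X[1000:].mean(axis=0)
        tol = 3 * np.abs(mu_int) * np.sqrt(0.09 + 0.04 + 0.01) / np.sqrt(1000)
        assert np.all(np.abs(emp - mu_int) <= tol + 1e-9)


class TestSimulateDataset:
    def test_dimensions_and_truth_count(self):
        cfg = SimulationConfig(n_units_per_group=10, n_variables=300, n_discriminating=20)
        table, cube, truth = simulate_dataset(cfg, seed=0)
        assert cube.shape == (20, 300, 4)
        assert table.X.shape == (80, 300)
        assert truth.discriminating.sum() == 20

    def test_seed_determinism(self):
        cfg = SimulationConfig(n_units_per_group=3, n_variables=50, n_discriminating=10)
        t1, c1, tr1 = simulate_dataset(cfg, seed=7)
        t2, c2, tr2 = simulate_dataset(cfg, seed=7)
        np.testing.assert_array_equal(c1.X3, c2.X3)
        assert tr1.equals(tr2)

    def test_all_discriminating_boundary(self):
        cfg = SimulationConfig(n_units_per_group=3, n_variables=12, n_discriminating=12)
        _, _, truth = simulate_dataset(cfg, seed=0)
        assert truth.discriminating.all()
        assert set(truth.class_id) <= set("abcdef")

    def test_group_mean_identity_for_nondiscriminating(self):
        cfg = SimulationConfig(n_units_per_group=3, n_variables=40, n_discriminating=10)
        _, _, truth = simulate_dataset(cfg, seed=3)
        nond = truth[~truth.discriminating]
        for p in ("c", "a", "alpha", "beta"):
            np.testing.assert_allclose(nond[f"{p}_control"], nond[f"{p}_intervention"])

    def test_discriminating_group_means_differ(self):
        cfg = SimulationConfig(n_units_per_group=2, n_variables=30, n_discriminating=12)
        _, _, truth = simulate_dataset(cfg, seed=5)
        disc = truth[truth.discriminating]
        diff = (disc.a_control - disc.a_intervention).abs()
        assert (diff > 1e-12).all()

    def test_train_test_share_truth(self):
        cfg = SimulationConfig(n_units_per_group=3, n_variables=50, n_discriminating=10)
        train, test, truth = simulate_train_test(cfg, seed=11)
        assert train.shape == test.shape
        assert not np.allclose(train.X3, test.X3)

    def test_inconsistent_class_mix_rejected(self):
        cfg = SimulationConfig(
            n_units_per_group=2, n_variables=100, n_discriminating=10,
            class_mix={"a": 0.5, "h": 0.5},
        )
        with pytest.raises(ValueError, match="discriminating"):
            cfg.class_counts()

    def test_excess_discriminating_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_variables=10, n_discriminating=11)
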