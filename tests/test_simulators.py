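"""Tests for the synthetic-data generators and the Monte Carlo harness."""

import math

import numpy as np
import pytest

from timescales import (
    AcfTarget,
    Ar1Spec,
    Ar2Spec,
    FitConfig,
    NoisyAcfSpec,
    PositiveDefiniteError,
    SimulationSetting,
    StationarityError,
    ar2_acf,
    ar2_design,
    center_series,
    fit_lls,
    fit_nls,
    phi_to_tau,
    rrmse,
    run_monte_carlo,
    sample_acf,
    simulate_ar1,
    simulate_ar2,
    simulate_from_acf,
    simulate_noisy_acf,
)


class TestSimulateAr1:
    def test_reproducible(self):
        spec = Ar1Spec(phi=0.5, T=200, seed=42)
        np.testing.assert_array_equal(
            simulate_ar1(spec).values, simulate_ar1(spec).values
        )

    def test_phi_zero_is_white_noise(self):
        x = simulate_ar1(Ar1Spec(phi=0.0, T=20000, seed=1))
        assert np.var(x.values) == pytest.approx(1.0, rel=0.05)

    def test_stationary_variance(self):
        x = simulate_ar1(Ar1Spec(phi=0.8, T=20000, seed=2))
        assert np.var(x.values) == pytest.approx(1.0 / (1 - 0.64), rel=0.1)

    def test_lag1_autocorrelation_recovered(self):
        x = center_series(simulate_ar1(Ar1Spec(phi=0.8, T=4800, seed=3)))
        rho1 = sample_acf(x, 1).values[1]
        se = math.sqrt((1 - 0.64) / 4800)
        assert abs(rho1 - 0.8) < 4 * se

    def test_nonstationary_phi_rejected(self):
        with pytest.raises(StationarityError):
            Ar1Spec(phi=1.0, T=100)


class TestSimulateAr2:
    def test_reduces_to_ar1_at_phi2_zero(self):
        x2 = simulate_ar2(Ar2Spec(phi1=0.5, phi2=0.0, T=20000, seed=4))
        x1 = simulate_ar1(Ar1Spec(phi=0.5, T=20000, seed=4))
        for x in (x1, x2):
            xc = center_series(x)
            rho1 = sample_acf(xc, 1).values[1]
            assert rho1 == pytest.approx(0.5, abs=0.05)
        assert np.var(x2.values) == pytest.approx(np.var(x1.values), rel=0.1)

    def test_stationarity_triangle_enforced(self):
        with pytest.raises(StationarityError):
            Ar2Spec(phi1=0.5, phi2=0.6, T=100)  # phi1 + phi2 >= 1
        with pytest.raises(StationarityError):
            Ar2Spec(phi1=0.2, phi2=-1.2, T=100)  # phi2 <= -1
        with pytest.raises(StationarityError):
            Ar2Spec(phi1=0.4, phi2=-0.5, T=100)  # periodic region

    def test_sample_acf_matches_yule_walker(self):
        spec = Ar2Spec(phi1=0.5, phi2=0.25, T=4800, seed=5)
        x = center_series(simulate_ar2(spec))
        empirical = sample_acf(x, 5).values
        theoretical = ar2_acf(0.5, 0.25, 5)
        np.testing.assert_allclose(empirical, theoretical, atol=0.08)


class TestAr2Design:
    def test_reduction_at_phi2_zero(self):
        spec, rho = ar2_design(0.45, 0.0, T=100)
        assert spec.phi1 == pytest.approx(0.45)
        np.testing.assert_allclose(rho[:5], 0.45 ** np.arange(5))

    def test_lag1_autocorrelation_formula(self):
        # Yule-Walker: rho_1 = phi1/(1 - phi2) = 0.5/0.75 = 2/3
        rho = ar2_acf(0.5, 0.25, 3)
        assert rho[1] == pytest.approx(2.0 / 3.0)

    def test_projection_consistency(self):
        # the time-domain fit to long AR(2) data recovers the designed
        # AR(1) projection, not the AR(2) coefficients
        spec, _ = ar2_design(0.45, 0.2, T=40000, seed=6)
        x = center_series(simulate_ar2(spec))
        fit = fit_lls(x)
        assert fit.phi == pytest.approx(0.45, abs=0.02)

    def test_invalid_design_rejected(self):
        # phi_star=0.9, phi2=-0.5 gives phi1=1.35: complex roots
        with pytest.raises(StationarityError, match="periodic"):
            ar2_design(0.9, -0.5, T=100)


class TestSimulateFromAcf:
    def test_white_noise_target(self):
        rho = np.zeros(500)
        rho[0] = 1.0
        x = center_series(
            simulate_from_acf(AcfTarget(rho=rho), T=500, seed=7)
        )
        assert abs(sample_acf(x, 1).values[1]) < 4 / math.sqrt(500)

    def test_exponential_target_recovered(self):
        rho = 0.6 ** np.arange(1200)
        x = center_series(simulate_from_acf(AcfTarget(rho=rho), T=1200, seed=8))
        se = math.sqrt((1 - 0.36) / 1200)
        assert sample_acf(x, 1).values[1] == pytest.approx(0.6, abs=4 * se)

    def test_reproducible(self):
        rho = 0.4 ** np.arange(64)
        target = AcfTarget(rho=rho)
        np.testing.assert_array_equal(
            simulate_from_acf(target, 64, seed=9).values,
            simulate_from_acf(target, 64, seed=9).values,
        )

    def test_covariance_converges_to_target(self):
        rho = 0.5 ** np.arange(8)
        target = AcfTarget(rho=rho)
        draws = np.stack(
            [simulate_from_acf(target, 8, seed=s).values for s in range(3000)]
        )
        empirical = np.cov(draws.T, ddof=1)
        from scipy.linalg import toeplitz

        np.testing.assert_allclose(empirical, toeplitz(rho), atol=0.12)

    def test_non_positive_definite_target_fails_clearly(self):
        rho = np.array([1.0, 0.99, 0.0])  # far outside the PSD set
        with pytest.raises(PositiveDefiniteError):
            simulate_from_acf(AcfTarget(rho=rho), T=3, seed=0)


class TestSimulateNoisyAcf:
    def test_noiseless_ar1_is_exact_and_recoverable(self):
        acf = simulate_noisy_acf(
            NoisyAcfSpec(kind="ar1", phi=0.6, K=200, noise_sd=0.0)
        )
        np.testing.assert_allclose(acf.values, 0.6 ** np.arange(201))
        assert fit_nls(acf).phi == pytest.approx(0.6, abs=1e-8)

    def test_noise_applies_at_every_lag(self):
        acf = simulate_noisy_acf(
            NoisyAcfSpec(kind="ar1", phi=0.6, K=50, noise_sd=1.0, seed=11)
        )
        assert acf.values.size == 51
        assert acf.values[0] != 1.0  # rho_0 = 1 + e_0 as specified
        assert acf.source_length is None

    def test_ar2_kind_noiseless_matches_yule_walker(self):
        acf = simulate_noisy_acf(
            NoisyAcfSpec(kind="ar2", phi1=0.5, phi2=0.25, K=30, noise_sd=0.0)
        )
        np.testing.assert_allclose(acf.values, ar2_acf(0.5, 0.25, 30))

    def test_empirical_kind(self):
        base = 0.7 ** np.arange(40)
        acf = simulate_noisy_acf(
            NoisyAcfSpec(kind="empirical", rho=base, K=39, noise_sd=0.0)
        )
        np.testing.assert_allclose(acf.values, base)

    def test_estimator_unbiased_at_moderate_noise(self):
        # in the signal+noise regime (noise small relative to the unit-
        # bounded curve) the exponential fit is unbiased
        estimates = [
            fit_nls(
                simulate_noisy_acf(
                    NoisyAcfSpec(kind="ar1", phi=0.6, K=2000, noise_sd=0.05, seed=i)
                )
            ).phi
            for i in range(200)
        ]
        mc_se = np.std(estimates, ddof=1) / math.sqrt(len(estimates))
        assert abs(np.mean(estimates) - 0.6) < 3 * mc_se


class TestRrmse:
    def test_exact_estimates_give_zero(self):
        assert rrmse(np.full(10, 2.5), 2.5) == 0.0

    def test_single_estimate(self):
        assert rrmse(np.array([12.0]), 10.0) == pytest.approx(0.2)

    def test_constant_relative_bias(self):
        tau = 3.7
        assert rrmse(np.full(100, 1.1 * tau), tau) == pytest.approx(0.10)

    def test_scale_invariance(self, rng):
        estimates = rng.normal(loc=5.0, scale=0.5, size=50)
        assert rrmse(3.0 * estimates, 15.0) == pytest.approx(
            rrmse(estimates, 5.0)
        )

    def test_zero_truth_rejected(self):
        with pytest.raises(ValueError):
            rrmse(np.array([1.0]), 0.0)


class TestSimulationSetting:
    def test_phi_star_must_match_generator(self):
        with pytest.raises(ValueError, match="lag-1"):
            SimulationSetting(generator=Ar1Spec(phi=0.5, T=100), phi_star=0.6)

    def test_tau_star_derived(self):
        setting = SimulationSetting(generator=Ar1Spec(phi=0.5, T=100), phi_star=0.5)
        assert setting.tau_star == pytest.approx(phi_to_tau(0.5))


class TestRunMonteCarlo:
    def test_summary_layout_and_reproducibility(self):
        settings = [
            SimulationSetting(generator=Ar1Spec(phi=p, T=300), phi_star=p)
            for p in (0.3, 0.6)
        ]
        a = run_monte_carlo(settings, N=20, seed=1, estimators=("lls",))
        b = run_monte_carlo(settings, N=20, seed=1, estimators=("lls",))
        assert set(a["se_method"]) == {"naive", "newey_west"}
        assert len(a) == 4  # 2 settings x 2 SE variants
        assert (a["rrmse_tau"] >= 0).all() and (a["rrmse_se"] >= 0).all()
        assert (a["n_reps"] + a["n_failed"] == 20).all()
        np.testing.assert_array_equal(a["mean_tau"], b["mean_tau"])

    def test_noisy_acf_generator_path(self):
        setting = SimulationSetting(
            generator=NoisyAcfSpec(kind="ar1", phi=0.6, K=200, noise_sd=0.05),
            phi_star=0.6,
        )
        out = run_monte_carlo([setting], N=20, seed=2)
        assert set(out["estimator"]) == {"nls"}
        assert set(out["se_method"]) == {"naive", "newey_west"}

    def test_recovery_at_small_scale(self):
        setting = SimulationSetting(generator=Ar1Spec(phi=0.5, T=1200), phi_star=0.5)
        out = run_monte_carlo(
            [setting], N=50, seed=3, estimators=("lls",)
        )
        row = out[out.se_method == "newey_west"].iloc[0]
        assert row["mean_tau"] == pytest.approx(phi_to_tau(0.5), rel=0.15)
        assert row["rrmse_tau"] < 0.25
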