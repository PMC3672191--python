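"""Tests for the synthetic-data layer: noisy curves, Brownian photon traces,
the multi-tau correlator and the titration/trajectory generators."""

import numpy as np
import pytest
from scipy import stats

import fcs_hydroshape as fh
from fcs_hydroshape.errors import DomainError, NormalizationError, UsageError
from fcs_hydroshape.synthetic import titration_D_profile, titration_slow_fraction


class TestSimulateCurve:
    def test_zero_noise_is_exact_analytic(self, beam, single_species_model):
        curve = fh.simulate_curve(single_species_model, beam, noise_cv=0.0)
        expected = fh.autocorrelation(single_species_model, beam, curve.lags_s)
        np.testing.assert_array_equal(curve.g, expected)
        assert curve.sigma is None

    def test_seed_determinism_bitwise(self, beam, single_species_model):
        a = fh.simulate_curve(single_species_model, beam, noise_cv=0.02, seed=11)
        b = fh.simulate_curve(single_species_model, beam, noise_cv=0.02, seed=11)
        np.testing.assert_array_equal(a.g, b.g)
        np.testing.assert_array_equal(a.sigma, b.sigma)

    def test_noise_is_unbiased_clt(self, beam, single_species_model):
        lags = fh.default_lag_grid(32)
        truth = fh.autocorrelation(single_species_model, beam, lags)
        draws = np.stack([
            fh.simulate_curve(single_species_model, beam, 0.02, lags, seed=s).g
            for s in range(200)
        ])
        se = 0.02 * truth / np.sqrt(200)
        assert np.all(np.abs(draws.mean(axis=0) - truth) <= 3 * se + 1e-15)

    def test_sigma_is_cv_times_truth(self, beam, single_species_model):
        curve = fh.simulate_curve(single_species_model, beam, noise_cv=0.05, seed=1)
        truth = fh.autocorrelation(single_species_model, beam, curve.lags_s)
        np.testing.assert_allclose(curve.sigma, 0.05 * truth, rtol=1e-12)


class TestSimulatePhotonTrace:
    def test_zero_brightness_all_zero(self, beam):
        trace = fh.simulate_photon_trace(
            [fh.EmitterSpecies(84.0, 0.0, 5)], beam, 4.0, 1e-5, 0.05, seed=0
        )
        assert np.all(trace.counts == 0)

    def test_immobile_center_emitter_poisson_mean(self, beam):
        # one motionless emitter at the focus center: mean counts/bin = β·dt
        beta, dt, duration = 1e5, 1e-5, 0.5
        trace = fh.simulate_photon_trace(
            [fh.EmitterSpecies(0.0, beta, 1)], beam, 4.0, dt, duration, seed=4,
            initial_positions={0: np.zeros((1, 3))},
        )
        n_bins = len(trace.counts)
        expected_total = beta * dt * n_bins
        assert abs(trace.counts.sum() - expected_total) <= 3 * np.sqrt(expected_total)

    def test_mean_intensity_matches_profile_integral(self, beam):
        # ⟨I⟩ = C·β·∫exp(−4r²/ω0²−4z²/z0²) d³r, the squared-Gaussian volume
        box = 4.0
        n_em, beta, dt = 60, 1e5, 1e-5
        integral = (np.pi**1.5 / 8.0) * beam.omega0_um**2 * beam.z0_um
        expected_rate = n_em / box**3 * beta * integral
        rates = []
        for s in range(8):
            trace = fh.simulate_photon_trace(
                [fh.EmitterSpecies(84.0, beta, n_em)], beam, box, dt, 0.3, seed=s
            )
            rates.append(trace.counts.sum() / trace.duration_s)
        se = np.std(rates, ddof=1) / np.sqrt(len(rates))
        assert abs(np.mean(rates) - expected_rate) <= 3 * se

    def test_seed_determinism(self, beam):
        kw = dict(beam=beam, box_um=4.0, dt_s=1e-5, duration_s=0.05, seed=9)
        a = fh.simulate_photon_trace([fh.EmitterSpecies(84.0, 5e4, 10)], **kw)
        b = fh.simulate_photon_trace([fh.EmitterSpecies(84.0, 5e4, 10)], **kw)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_coarse_dt_rejected_with_named_constraint(self, beam):
        with pytest.raises(UsageError, match="tau_D/20"):
            fh.simulate_photon_trace([fh.EmitterSpecies(84.0, 1e4, 5)], beam, 4.0, 1e-3, 0.1)

    def test_small_box_rejected(self, beam):
        with pytest.raises(UsageError, match="10"):
            fh.simulate_photon_trace([fh.EmitterSpecies(84.0, 1e4, 5)], beam, 2.0, 1e-5, 0.1)


class TestMultitauCorrelate:
    def test_constant_trace_zero_correlation(self):
        trace = fh.PhotonTrace(1e-5, np.full(2048, 7))
        curve = fh.multitau_correlate(trace, m=16)
        np.testing.assert_allclose(curve.g, 0.0, atol=1e-12)

    def test_zero_trace_rejected(self):
        with pytest.raises(NormalizationError):
            fh.multitau_correlate(fh.PhotonTrace(1e-5, np.zeros(2048, dtype=int)))

    def test_poisson_white_noise_uncorrelated(self):
        rng = np.random.default_rng(17)
        trace = fh.PhotonTrace(1e-5, rng.poisson(2.0, size=200_000))
        curve = fh.multitau_correlate(trace, m=16, n_segments=10)
        z = np.abs(curve.g) / curve.sigma
        assert np.mean(z <= 3.0) >= 0.9
        assert np.max(z) <= 6.0

    def test_lag_grid_strictly_increasing_and_covers_quarter(self):
        trace = fh.PhotonTrace(1e-5, np.random.default_rng(0).poisson(1.0, 65_536))
        curve = fh.multitau_correlate(trace, m=16)
        assert np.all(np.diff(curve.lags_s) > 0)
        assert curve.lags_s[0] == pytest.approx(1e-5)
        assert curve.lags_s[-1] >= trace.duration_s / 4.0

    def test_matches_analytic_autocorrelation(self, beam):
        # simulator → correlator output consistent with the analytic model:
        # goodness-of-fit chi² test using segment-derived standard errors
        trace = fh.simulate_photon_trace(
            [fh.EmitterSpecies(84.0, 3e5, 150)], beam, (4, 4, 12), 1e-5, 3.0, seed=123
        )
        curve = fh.multitau_correlate(trace, m=16, n_segments=10)
        tau_d = fh.diffusion_time(84.0, beam)
        mask = curve.lags_s <= 30 * tau_d
        trimmed = fh.CorrelationCurve(curve.lags_s[mask], curve.g[mask], sigma=curve.sigma[mask])
        fit = fh.fit_correlation(trimmed, 1, beam, fit_baseline=True)
        dof = fit.n_points - fit.n_free
        p_value = stats.chi2.sf(fit.chi2, dof)
        assert p_value > 0.01
        assert fit.model.species[0].D_um2_s == pytest.approx(84.0, rel=0.15)

    def test_odd_m_rejected(self):
        with pytest.raises(UsageError):
            fh.multitau_correlate(fh.PhotonTrace(1e-5, np.ones(1000, dtype=int)), m=15)


class TestTitrationScenario:
    def test_neutral_ph_truth(self):
        scenario = fh.titration_scenario([7.0], seed=1)
        assert scenario.D_profile_um2_s[0] == pytest.approx(84.0)
        assert scenario.slow_fraction_profile[0] <= 0.01

    def test_acid_ph_truth(self):
        scenario = fh.titration_scenario([4.0], seed=1)
        assert scenario.D_profile_um2_s[0] == pytest.approx(45.0, abs=2.0)
        assert scenario.slow_fraction_profile[0] == pytest.approx(0.03, abs=0.01)

    def test_profile_shape(self):
        ph = np.array([2.0, 4.5, 6.0, 7.0, 10.0, 11.0])
        np.testing.assert_allclose(titration_D_profile(ph), [25, 50, 50, 84, 31, 31])
        fr = titration_slow_fraction(np.array([2.0, 7.0, 11.0]))
        assert fr[0] == pytest.approx(0.1, abs=0.005)
        assert fr[1] == pytest.approx(0.002)
        assert fr[2] >= 0.05

    def test_seed_determinism(self):
        a = fh.titration_scenario([3.0, 7.0], seed=5)
        b = fh.titration_scenario([3.0, 7.0], seed=5)
        for ph in a.curves:
            np.testing.assert_array_equal(a.curves[ph].g, b.curves[ph].g)

    def test_out_of_range_ph(self):
        with pytest.raises(UsageError):
            fh.titration_scenario([1.0])
        with pytest.raises(UsageError):
            fh.titration_scenario([12.0])


class TestToyTrajectory:
    def test_static_frames_identical(self):
        traj = fh.toy_trajectory(20, 4, "static", seed=2)
        assert np.all(traj.coords == traj.coords[0])

    def test_two_state_exact_counts(self):
        traj = fh.toy_trajectory(50, 5, "two-state", params={"weights": (0.8, 0.2)}, seed=3)
        assert traj.n_frames == 50

    def test_unknown_mode(self):
        with pytest.raises(UsageError):
            fh.toy_trajectory(10, 3, "ballistic")

    def test_unused_params_rejected(self):
        with pytest.raises(UsageError):
            fh.toy_trajectory(10, 3, "static", params={"D_um2_s": 80.0})

    def test_seed_determinism(self):
        a = fh.toy_trajectory(30, 4, "diffusive", seed=6)
        b = fh.toy_trajectory(30, 4, "diffusive", seed=6)
        np.testing.assert_array_equal(a.coords, b.coords)
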