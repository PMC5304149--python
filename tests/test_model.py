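"""Phasor transform: analytic formulas, discrete transform, thresholding,
calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from flimphasor import (
    AcquisitionSettings,
    DecayCube,
    PhasorCloud,
    PhasorSettings,
    calibrate_cloud,
    ideal_decay_curve,
    lifetime_from_point,
    mono_exponential_phasor,
    mono_exponential_phasor_sampled,
    pixel_phasor,
    transform_cube,
)
from flimphasor.errors import (
    CalibrationError,
    EmptyCloudError,
    EmptyPixelError,
    InvalidInputError,
)


class TestAnalyticPhasor:
    @pytest.mark.parametrize(
        "tau, omega, expected",
        [
            (0.0, 2 * math.pi / 12500, (1.0, 0.0)),
            (12500 / (2 * math.pi), 2 * math.pi / 12500, (0.5, 0.5)),
            # omega*tau = 2*pi*0.2: g = 1/(1+(wt)^2), s = wt/(1+(wt)^2)
            (2500.0, 2 * math.pi / 12500, (0.3877266367, 0.4872316614)),
        ],
    )
    def test_closed_form(self, tau, omega, expected):
        g, s = mono_exponential_phasor(tau, omega)
        assert g == pytest.approx(expected[0], abs=1e-9)
        assert s == pytest.approx(expected[1], abs=1e-9)

    @pytest.mark.parametrize("tau", [300.0, 750.0, 1000.0, 2500.0, 5000.0])
    @pytest.mark.parametrize("harmonic", [1, 2, 4])
    def test_on_circle_identity(self, tau, harmonic, acq):
        g, s = mono_exponential_phasor(tau, acq.omega(harmonic))
        assert math.hypot(g - 0.5, s) == pytest.approx(0.5, abs=1e-9)

    @pytest.mark.parametrize("tau", [1.0, 300.0, 2500.0, 9000.0])
    def test_lifetime_round_trip(self, tau, acq):
        omega = acq.omega(4)
        recovered = lifetime_from_point(mono_exponential_phasor(tau, omega), omega)
        assert recovered == pytest.approx(tau, rel=1e-9)

    def test_lifetime_examples(self, acq):
        omega = acq.omega(1)
        assert lifetime_from_point((0.5, 0.5), omega) == pytest.approx(
            1989.4367886, abs=1e-3
        )
        assert lifetime_from_point((1.0, 0.0), omega) == 0.0
        assert math.isinf(lifetime_from_point((0.0, 0.3), omega))
        assert math.isinf(lifetime_from_point((-0.1, 0.3), omega))

    def test_invalid_arguments(self):
        with pytest.raises(InvalidInputError):
            mono_exponential_phasor(-1.0, 1.0)
        with pytest.raises(InvalidInputError):
            mono_exponential_phasor(100.0, 0.0)


class TestPixelPhasor:
    def test_delta_decay_at_window_start(self, acq):
        """All photons in the first window channel sit at (1, 0) rotated by
        the half-channel phase of the channel-centre convention."""
        decay = np.zeros(acq.n_channels)
        decay[0] = 1000
        ps = PhasorSettings(harmonic=2, window_fraction=0.5, window_start=0,
                            threshold_fraction=0.0, baseline_subtraction=False)
        g, s = pixel_phasor(decay, acq, ps)
        half = acq.omega(2) * acq.channel_width / 2
        assert g == pytest.approx(math.cos(half), abs=1e-12)
        assert s == pytest.approx(math.sin(half), abs=1e-12)

    def test_uniform_over_full_cycle_is_origin(self, acq):
        """Constant intensity over exactly one harmonic cycle sums cosine and
        sine to zero."""
        decay = np.full(acq.n_channels, 7.0)
        ps = PhasorSettings(harmonic=2, window_fraction=0.5, window_start=0,
                            baseline_subtraction=False)
        g, s = pixel_phasor(decay, acq, ps)
        assert abs(g) < 1e-12 and abs(s) < 1e-12

    def test_dense_noiseless_exponential_matches_closed_form(self):
        dense = AcquisitionSettings(n_channels=50_000)
        curve = ideal_decay_curve([(2500.0, 1.0)], dense, photons=1e6, wrap=True)
        ps = PhasorSettings(harmonic=1, window_fraction=1.0, window_start=0,
                            baseline_subtraction=False)
        g, s = pixel_phasor(curve, dense, ps)
        assert g == pytest.approx(0.3877266367, abs=1e-3)
        assert s == pytest.approx(0.4872316614, abs=1e-3)

    @pytest.mark.parametrize("tau", [400.0, 2500.0])
    @pytest.mark.parametrize("harmonic,fraction", [(1, 1.0), (2, 0.5), (4, 0.25)])
    def test_sampled_closed_form(self, acq, tau, harmonic, fraction):
        """The 64-channel transform of a wrapped channel-integrated
        exponential equals its geometric-series closed form exactly."""
        curve = ideal_decay_curve([(tau, 1.0)], acq, photons=1e6, wrap=True)
        ps = PhasorSettings(harmonic=harmonic, window_fraction=fraction,
                            window_start=0, baseline_subtraction=False)
        g, s = pixel_phasor(curve, acq, ps)
        ge, se = mono_exponential_phasor_sampled(
            tau, acq.omega(harmonic), acq.channel_width
        )
        assert g == pytest.approx(ge, abs=1e-12)
        assert s == pytest.approx(se, abs=1e-12)

    def test_truncated_transform_near_circle(self, acq):
        """With 64 channels the sampled phasor of an exponential stays within
        the documented 0.02 of the universal circle."""
        for tau in (500.0, 1000.0, 2500.0, 4000.0):
            g, s = mono_exponential_phasor_sampled(
                tau, acq.omega(2), acq.channel_width
            )
            assert abs(math.hypot(g - 0.5, s) - 0.5) < 0.02

    @hyp_settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=10_000),
                    min_size=64, max_size=64),
           st.integers(min_value=1, max_value=4))
    def test_brute_force_fourier_oracle(self, counts, harmonic):
        """pixel_phasor agrees with a direct complex-exponential sum."""
        acq = AcquisitionSettings()
        decay = np.asarray(counts, dtype=float)
        if decay.sum() == 0:
            decay[0] = 1.0
        ps = PhasorSettings(harmonic=harmonic, window_fraction=1.0,
                            window_start=0, baseline_subtraction=False)
        g, s = pixel_phasor(decay, acq, ps)
        t = (np.arange(64) + 0.5) * acq.channel_width
        z = (decay * np.exp(1j * acq.omega(harmonic) * t)).sum() / decay.sum()
        assert g == pytest.approx(z.real, abs=1e-12)
        assert s == pytest.approx(z.imag, abs=1e-12)

    def test_linearity(self, acq, rng):
        """Phasor of a channel-wise sum is the intensity-weighted convex
        combination of the phasors — exact for the discrete transform."""
        ps = PhasorSettings(harmonic=2, window_fraction=1.0, window_start=0,
                            baseline_subtraction=False)
        a = rng.integers(0, 500, acq.n_channels).astype(float)
        b = rng.integers(0, 500, acq.n_channels).astype(float)
        ga, sa = pixel_phasor(a, acq, ps)
        gb, sb = pixel_phasor(b, acq, ps)
        gs, ss = pixel_phasor(a + b, acq, ps)
        wa, wb = a.sum(), b.sum()
        assert gs == pytest.approx((wa * ga + wb * gb) / (wa + wb), abs=1e-12)
        assert ss == pytest.approx((wa * sa + wb * sb) / (wa + wb), abs=1e-12)

    def test_error_conditions(self, acq):
        with pytest.raises(InvalidInputError):
            pixel_phasor(-np.ones(acq.n_channels), acq)
        with pytest.raises(EmptyPixelError):
            pixel_phasor(np.zeros(acq.n_channels), acq,
                         PhasorSettings(baseline_subtraction=False))
        with pytest.raises(InvalidInputError):
            pixel_phasor(np.ones(10), acq)

    def test_baseline_subtraction_removes_pre_rise_floor(self, acq):
        curve = ideal_decay_curve([(2500.0, 1.0)], acq, irf_fwhm=250.0,
                                  photons=1e5, wrap=True)
        noisy = curve + 50.0  # constant background
        ps_on = PhasorSettings(harmonic=2, baseline_subtraction=True)
        ps_off = PhasorSettings(harmonic=2, baseline_subtraction=False)
        g_on, s_on = pixel_phasor(np.round(noisy), acq, ps_on)
        g_ref, s_ref = pixel_phasor(np.round(curve), acq, ps_on)
        g_off, _ = pixel_phasor(np.round(noisy), acq, ps_off)
        # subtraction restores the clean phasor far better than leaving it
        assert abs(g_on - g_ref) < 0.01
        assert abs(g_off - g_ref) > abs(g_on - g_ref)


def _flat_cube(acq, totals):
    """Cube whose pixels all share one decay shape, scaled to given totals."""
    shape = ideal_decay_curve([(1500.0, 1.0)], acq, wrap=True)
    counts = np.zeros((1, len(totals), acq.n_channels))
    for j, total in enumerate(totals):
        counts[0, j] = np.round(shape * total)
    return DecayCube(counts=counts.astype(int), settings=acq)


class TestTransformCube:
    def test_threshold_excludes_dim_pixels(self, acq):
        cube = _flat_cube(acq, [1000, 500, 299, 100])
        cloud = transform_cube(cube, PhasorSettings(threshold_fraction=0.30,
                                                    baseline_subtraction=False))
        kept = set(map(tuple, cloud.pixels))
        assert (0, 0) in kept and (0, 1) in kept
        assert (0, 2) not in kept and (0, 3) not in kept

    def test_zero_threshold_keeps_all_nonzero(self, acq):
        cube = _flat_cube(acq, [1000, 50, 700])
        cloud = transform_cube(cube, PhasorSettings(threshold_fraction=0.0,
                                                    baseline_subtraction=False))
        assert len(cloud) == 3

    def test_uniform_cube_matches_pixel_phasor(self, acq):
        cube = _flat_cube(acq, [800, 800, 800])
        ps = PhasorSettings(threshold_fraction=0.0, baseline_subtraction=False)
        cloud = transform_cube(cube, ps)
        g, s = pixel_phasor(cube.counts[0, 0], acq, ps)
        np.testing.assert_allclose(cloud.g, g, atol=1e-12)
        np.testing.assert_allclose(cloud.s, s, atol=1e-12)

    def test_threshold_monotonicity(self, acq, rng):
        counts = rng.poisson(
            ideal_decay_curve([(2000.0, 1.0)], acq, wrap=True) * 500,
            size=(8, 8, acq.n_channels),
        )
        cube = DecayCube(counts=counts, settings=acq)
        sizes = []
        for thr in (0.0, 0.2, 0.5, 0.8):
            cloud = transform_cube(
                cube, PhasorSettings(threshold_fraction=thr,
                                     baseline_subtraction=False))
            sizes.append(len(cloud))
        assert sizes == sorted(sizes, reverse=True)

    def test_empty_result_names_threshold(self, acq):
        counts = np.zeros((2, 2, acq.n_channels), dtype=int)
        counts[0, 0, 5] = 10  # only bright pixel; others below any threshold
        cube = DecayCube(counts=counts, settings=acq)
        ps = PhasorSettings(threshold_fraction=0.9, baseline_subtraction=False)
        cloud = transform_cube(cube, ps)  # the bright pixel itself passes
        assert len(cloud) == 1
        with pytest.raises(EmptyCloudError, match="threshold"):
            transform_cube(
                DecayCube(counts=np.zeros((2, 2, acq.n_channels), dtype=int)
                          + 0, settings=acq),
                ps,
            )

    def test_shot_noise_spread_shrinks_with_budget(self, acq):
        curve = ideal_decay_curve([(2000.0, 1.0)], acq, wrap=True)
        spreads = []
        for photons in (100, 1000, 10_000):
            rng = np.random.default_rng(7)
            counts = rng.poisson(curve * photons, size=(64, 1, acq.n_channels))
            cube = DecayCube(counts=counts, settings=acq)
            cloud = transform_cube(
                cube, PhasorSettings(threshold_fraction=0.0,
                                     baseline_subtraction=False))
            spreads.append(float(np.std(cloud.g) + np.std(cloud.s)))
        assert spreads[0] > spreads[1] > spreads[2]


class TestCalibration:
    def _cloud_from_cube(self, cube, ps):
        return transform_cube(cube, ps)

    def test_identity_when_reference_already_on_target(self, acq):
        omega = acq.omega(1)
        g, s = mono_exponential_phasor(1800.0, omega)
        cloud = PhasorCloud.from_points([g, g + 0.01], [s, s - 0.01], omega)
        ref = PhasorCloud.from_points([g], [s], omega)
        out = calibrate_cloud(cloud, ref, 1800.0)
        np.testing.assert_allclose(out.g, cloud.g, atol=1e-12)
        np.testing.assert_allclose(out.s, cloud.s, atol=1e-12)

    def test_self_calibration_lands_on_circle(self, acq, rng):
        omega = acq.omega(2)
        cloud = PhasorCloud.from_points(
            0.4 + 0.01 * rng.standard_normal(50),
            0.3 + 0.01 * rng.standard_normal(50),
            omega,
        )
        out = calibrate_cloud(cloud, cloud, 2000.0)
        g, s = out.mean_phasor()
        expected = mono_exponential_phasor(2000.0, omega)
        assert (g, s) == pytest.approx(expected, abs=1e-12)

    def test_simulated_irf_decay_recovers_lifetime_within_1pct(self, acq):
        from flimphasor import reference_fixture, simulate_cube, SyntheticSpec

        ps = PhasorSettings(harmonic=2, window_fraction=0.5)
        spec = SyntheticSpec(components=((1800.0, 1.0),), irf_fwhm=250.0,
                             photons_per_pixel=2000.0, shape=(16, 16), seed=3)
        cube, _ = simulate_cube(spec, acq)
        ref = reference_fixture(2500.0, acq, photons_per_pixel=2000.0, seed=4)
        cloud = calibrate_cloud(
            self._cloud_from_cube(cube, ps),
            self._cloud_from_cube(ref, ps),
            2500.0,
        )
        tau = lifetime_from_point(cloud.mean_phasor(), cloud.omega)
        assert tau == pytest.approx(1800.0, rel=0.01)

    def test_origin_reference_rejected(self, acq):
        omega = acq.omega(1)
        cloud = PhasorCloud.from_points([0.5], [0.3], omega)
        ref = PhasorCloud.from_points([0.0], [0.0], omega)
        with pytest.raises(CalibrationError):
            calibrate_cloud(cloud, ref, 2500.0)


class TestSettingsTypes:
    def test_acquisition_invariants(self):
        with pytest.raises(InvalidInputError):
            AcquisitionSettings(repetition_period=1000.0, n_channels=64,
                                channel_width=100.0)  # window exceeds period
        with pytest.raises(InvalidInputError):
            AcquisitionSettings(repetition_period=-5.0)

    def test_phasor_settings_validation(self):
        with pytest.raises(InvalidInputError):
            PhasorSettings(window_fraction=0.0)
        with pytest.raises(InvalidInputError):
            PhasorSettings(threshold_fraction=1.0)
        with pytest.raises(InvalidInputError):
            PhasorSettings(harmonic=0)
        with pytest.raises(InvalidInputError):
            PhasorSettings(window_start="center")

    def test_config_round_trip(self):
        ps = PhasorSettings(harmonic=4, window_fraction=0.25, window_start=3,
                            threshold_fraction=0.1, baseline_subtraction=False)
        assert PhasorSettings.from_config(ps.to_config()) == ps
        assert PhasorSettings.from_config(
            PhasorSettings().to_config()) == PhasorSettings()

    def test_cube_validation(self, acq):
        with pytest.raises(InvalidInputError):
            DecayCube(counts=np.ones((4, 4), dtype=int), settings=acq)
        with pytest.raises(InvalidInputError):
            DecayCube(counts=-np.ones((2, 2, acq.n_channels), dtype=int),
                      settings=acq)
        with pytest.raises(InvalidInputError):
            DecayCube(counts=np.full((2, 2, acq.n_channels), 0.5),
                      settings=acq)

    def test_outside_semicircle_flagging(self, acq):
        cloud = PhasorCloud.from_points([0.5, 1.2], [0.25, 0.1], acq.omega(1))
        flags = cloud.outside_semicircle(tol=1e-9)
        assert list(flags) == [False, True]
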