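import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fsflim import (
    CorrectedCube,
    Fluorophore,
    PhantomScene,
    SimulationParams,
    SpectralAxis,
    ThresholdPolicy,
    TimeAxis,
    channel_intensity,
    fit_cube,
    fit_decays,
    fit_single_exponential,
    flatfield_spectral,
    lifetime_histogram,
    moving_spectral_mean,
    roi_difference,
    roi_mean_spectral_lifetime,
    simulate_cube,
    subtract_dark,
    threshold_mask,
    wavelength_to_channel,
)


@pytest.fixture(scope="module")
def fitted_phantom(chained_cube, sensor):
    """Corrected + fitted two-fluorophore phantom (no spectral smoothing)."""
    corr = flatfield_spectral(subtract_dark(chained_cube, sensor), sensor)
    bg = sensor.dark_rate_at(64) * chained_cube.dwell_time * 1e-6
    return fit_cube(corr, bg, ThresholdPolicy(smoothing_mode="off"))


class TestChannelIntensity:
    def test_zero_cube(self):
        assert not channel_intensity(np.zeros((2, 2, 4, 8))).any()

    def test_single_photon(self):
        cube = np.zeros((2, 2, 4, 8))
        cube[1, 0, 2, 5] = 1
        intensity = channel_intensity(cube)
        assert intensity[1, 0, 2] == 1
        assert intensity.sum() == 1

    def test_matches_triple_loop(self, rng):
        cube = rng.integers(0, 50, size=(4, 4, 8, 8)).astype(float)
        intensity = channel_intensity(cube)
        for y in range(4):
            for x in range(4):
                for k in range(8):
                    assert intensity[y, x, k] == sum(
                        cube[y, x, k, j] for j in range(8)
                    )


class TestMovingSpectralMean:
    def test_width_one_is_identity(self, rng):
        v = rng.normal(size=32)
        np.testing.assert_array_equal(moving_spectral_mean(v, 1), v)

    @pytest.mark.parametrize("width", [2, 5, 8])
    def test_constant_unchanged(self, width):
        v = np.full(40, 3.7)
        np.testing.assert_allclose(moving_spectral_mean(v, width), v)

    def test_ramp_matches_window_loop(self):
        """Oracle: exhaustive truncated-window mean over a 0..511 ramp."""
        v = np.arange(512, dtype=float)
        width = 8
        out = moving_spectral_mean(v, width)
        left, right = (width - 1) // 2, width // 2
        for k in range(512):
            window = v[max(k - left, 0) : min(k + right + 1, 512)]
            assert out[k] == pytest.approx(window.mean(), rel=1e-12)

    def test_width_exceeding_channels_rejected(self):
        with pytest.raises(ValueError):
            moving_spectral_mean(np.zeros(8), 9)


class TestThresholdMask:
    def test_degenerate_zero_thresholds(self):
        policy = ThresholdPolicy(background_multiple=1.0, absolute_min_counts=0.0)
        intensity = np.array([[0.0, 1.0], [5.0, 0.0]])
        mask = threshold_mask(intensity, 0.0, policy)
        assert mask.all()  # >= holds everywhere, including intensity 0

    def test_200_count_floor(self):
        policy = ThresholdPolicy(background_multiple=10.0, absolute_min_counts=200.0)
        intensity = np.array([199.0, 200.0, 201.0])
        mask = threshold_mask(intensity, 0.0, policy)
        np.testing.assert_array_equal(mask, [False, True, True])

    def test_matches_exhaustive_comparison(self, rng):
        intensity = rng.uniform(0, 500, size=(8, 8, 6))
        bg = rng.uniform(0, 30, size=6)
        policy = ThresholdPolicy(background_multiple=10.0, absolute_min_counts=200.0)
        mask = threshold_mask(intensity, bg, policy)
        for y in range(8):
            for x in range(8):
                for k in range(6):
                    expected = (
                        intensity[y, x, k] >= 10.0 * bg[k]
                        and intensity[y, x, k] >= 200.0
                    )
                    assert mask[y, x, k] == expected

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        mult_lo=st.floats(1.0, 20.0),
        mult_hi=st.floats(0.0, 20.0),
        floor_lo=st.floats(0.0, 400.0),
        floor_hi=st.floats(0.0, 400.0),
    )
    def test_monotone_under_tightening(self, seed, mult_lo, mult_hi, floor_lo, floor_hi):
        """mask(tighter policy) is a subset of mask(looser policy)."""
        r = np.random.default_rng(seed)
        intensity = r.uniform(0, 500, size=(6, 6))
        bg = r.uniform(0, 30)
        loose = ThresholdPolicy(
            background_multiple=mult_lo, absolute_min_counts=floor_lo
        )
        tight = ThresholdPolicy(
            background_multiple=mult_lo + mult_hi,
            absolute_min_counts=floor_lo + floor_hi,
        )
        m_loose = threshold_mask(intensity, bg, loose)
        m_tight = threshold_mask(intensity, bg, tight)
        assert not np.any(m_tight & ~m_loose)


def grid_search_sse(y: np.ndarray, t: np.ndarray) -> float:
    """Independent oracle: dense 3-D grid search over (A, tau, B), tail range."""
    peak = int(np.argmax(y))
    yt = y[peak:]
    tt = t[peak:] - t[peak]
    taus = np.geomspace(0.1, 50.0, 80)
    amps = np.linspace(0.0, 2.0 * y.max() + 1.0, 60)
    bgs = np.linspace(0.0, y.max() / 2 + 1.0, 25)
    model = (
        amps[:, None, None, None] * np.exp(-tt[None, None, None, :] / taus[None, :, None, None])
        + bgs[None, None, :, None]
    )
    return float(((model - yt) ** 2).sum(axis=-1).min())


class TestFitSingleExponential:
    def test_noiseless_exact_recovery(self, raw_time_axis):
        t = raw_time_axis.centers
        y = 1000.0 * np.exp(-t / 2.0)
        res = fit_single_exponential(y, raw_time_axis)
        assert res.valid
        assert res.tau == pytest.approx(2.0, rel=1e-6)
        assert res.background == pytest.approx(0.0, abs=1e-3)

    def test_noiseless_with_background(self, raw_time_axis):
        t = raw_time_axis.centers
        y = 500.0 * np.exp(-t / 3.0) + 25.0
        res = fit_single_exponential(y, raw_time_axis)
        assert res.valid
        assert res.tau == pytest.approx(3.0, rel=1e-6)
        assert res.background == pytest.approx(25.0, rel=1e-4)

    def test_constant_decay_flagged_invalid(self, raw_time_axis):
        res = fit_single_exponential(np.full(32, 40.0), raw_time_axis)
        assert not res.valid
        assert res.tau == 0.0

    def test_all_zero_returns_invalid_not_exception(self, raw_time_axis):
        res = fit_single_exponential(np.zeros(32), raw_time_axis)
        assert not res.valid
        assert res.tau == 0.0

    def test_poisson_decay_beats_grid_oracle(self, raw_time_axis):
        """Fixed-seed Poisson decay, 5,000 photons: the analytic fitter's
        residual must not exceed the dense grid-search minimum."""
        r = np.random.default_rng(99)
        t = raw_time_axis.centers
        p = np.exp(-t / 2.0)
        y = r.poisson(5000 * p / p.sum()).astype(float)
        res = fit_single_exponential(y, raw_time_axis)
        assert res.valid
        assert res.tau == pytest.approx(2.0, rel=0.1)
        peak = int(np.argmax(y))
        dof = max(len(y) - peak - 3, 1)
        assert res.chi_square * dof <= grid_search_sse(y, t) * (1 + 1e-9) + 1e-9

    def test_oracle_equivalence_on_random_decays(self, raw_time_axis):
        """On 100 random Poisson decays the fitter's residual sum is never
        worse than the grid-search oracle's (the fitter solves the same
        least-squares problem exactly in (A, B) and finer in tau)."""
        r = np.random.default_rng(2026)
        t = raw_time_axis.centers
        failures = 0
        for _ in range(100):
            tau = r.uniform(0.5, 8.0)
            photons = r.uniform(300, 20000)
            bg = r.uniform(0, 5)
            p = np.exp(-t / tau)
            y = r.poisson(photons * p / p.sum() + bg).astype(float)
            res = fit_single_exponential(y, raw_time_axis)
            if not res.valid:
                continue
            peak = int(np.argmax(y))
            dof = max(len(y) - peak - 3, 1)
            sse_fit = res.chi_square * dof
            sse_grid = grid_search_sse(y, t)
            if sse_fit > sse_grid * (1 + 1e-9) + 1e-9:
                failures += 1
        assert failures == 0

    def test_recovery_improves_with_photon_budget(self, raw_time_axis):
        """Bias shrinks toward 0 and spread tightens at 500 / 5,000 / 50,000
        photons (200 replicate decays per budget, fixed seed)."""
        r = np.random.default_rng(7)
        t = raw_time_axis.centers
        p = np.exp(-t / 2.0)
        p /= p.sum()
        spreads, biases = [], []
        for photons in (500, 5000, 50000):
            y = r.poisson(photons * p, size=(200, 32)).astype(float)
            res = fit_decays(y, raw_time_axis)
            taus = res["tau"][res["valid"]]
            assert taus.size > 190
            spreads.append(np.std(taus))
            biases.append(abs(np.median(taus) - 2.0))
        assert spreads[0] > spreads[1] > spreads[2]
        assert biases[2] < 0.02
        assert spreads[2] < 0.05

    def test_weighted_fit_available(self, raw_time_axis):
        r = np.random.default_rng(17)
        t = raw_time_axis.centers
        p = np.exp(-t / 2.5)
        y = r.poisson(8000 * p / p.sum()).astype(float)
        res = fit_single_exponential(y, raw_time_axis, weighted=True)
        assert res.valid
        assert res.tau == pytest.approx(2.5, rel=0.1)


class TestFitCube:
    def test_fully_subthreshold_cube(self, small_axis):
        taxis = TimeAxis(n_bins=16, bin_width=3.125)
        corr = CorrectedCube(
            np.full((4, 4, 64, 16), 0.5), small_axis, taxis, 500.0,
            corrections_applied=["dark"],
        )
        ltc = fit_cube(corr, 0.0, ThresholdPolicy(smoothing_mode="off"))
        assert ltc.n_attempted == 0
        assert not ltc.tau_map.any()

    def test_candidate_count_is_pixelwise_channel_product(self, fitted_phantom):
        assert fitted_phantom.n_candidates == 32 * 32 * 64

    def test_tau_support_subset_of_mask(self, fitted_phantom):
        assert not np.any((fitted_phantom.tau_map > 0) & ~fitted_phantom.mask)
        assert np.all(fitted_phantom.tau_map[~fitted_phantom.mask] == 0)

    def test_phantom_median_recovery_within_5pct(self, fitted_phantom):
        tau = fitted_phantom.tau_map
        short = tau[:, :16, :][tau[:, :16, :] > 0]
        long = tau[:, 16:, :][tau[:, 16:, :] > 0]
        assert np.median(short) == pytest.approx(1.5, rel=0.05)
        assert np.median(long) == pytest.approx(3.5, rel=0.05)

    def test_smoothing_mode_recorded(self, chained_cube, sensor):
        corr = subtract_dark(chained_cube, sensor)
        bg = sensor.dark_rate_at(64) * chained_cube.dwell_time * 1e-6
        ltc = fit_cube(corr, bg, ThresholdPolicy(smoothing_mode="full", smoothing_width=4))
        assert ltc.provenance["smoothing_mode"] == "full"
        assert (ltc.tau_map > 0).sum() > 0


class TestLifetimeHistogram:
    def test_all_invalid_channel_empty(self, fitted_phantom):
        # channel 0 (below 510 nm) has no emission above threshold
        counts = lifetime_histogram(fitted_phantom, 0, np.linspace(0, 5, 26))
        assert counts.sum() == 0

    def test_single_valid_pixel(self):
        from fsflim import LifetimeCube

        tau = np.zeros((4, 4, 2))
        tau[2, 1, 0] = 2.0
        ltc = LifetimeCube(tau, np.ones((4, 4, 2)), ThresholdPolicy())
        edges = np.linspace(0, 5, 11)
        counts = lifetime_histogram(ltc, 0, edges)
        assert counts.sum() == 1
        assert counts[4] == 1  # 2.0 ns falls in [2.0, 2.5)

    def test_mass_equals_valid_pixels(self, fitted_phantom, small_axis):
        k = wavelength_to_channel(small_axis, 560.0)
        counts = lifetime_histogram(fitted_phantom, k, np.linspace(0, 50, 501))
        assert counts.sum() == (fitted_phantom.tau_map[:, :, k] > 0).sum()

    def test_bimodal_phantom_two_peaks(self, sensor, small_axis, raw_time_axis):
        """Two lifetime populations at one wavelength produce a two-peaked
        histogram with peaks at the simulated lifetimes (± bin width)."""
        f1 = Fluorophore("a", 620.0, 20.0, 1.5, 40.0)
        f2 = Fluorophore("b", 620.0, 20.0, 3.5, 40.0)
        w1 = np.zeros((16, 16))
        w1[:8] = 1.0
        w2 = np.zeros((16, 16))
        w2[8:] = 1.0
        scene = PhantomScene(16, 16, [f1, f2], [w1, w2])
        cube = simulate_cube(
            scene, sensor, small_axis, raw_time_axis,
            SimulationParams(dwell_time=500.0, seed=21, chained=True),
        )
        corr = subtract_dark(cube, sensor)
        bg = sensor.dark_rate_at(64) * cube.dwell_time * 1e-6
        ltc = fit_cube(corr, bg, ThresholdPolicy(smoothing_mode="off"))
        k = wavelength_to_channel(small_axis, 620.0)
        width = 0.25
        edges = np.arange(0.0, 6.0 + width, width)
        counts = lifetime_histogram(ltc, k, edges)
        # local maxima of the histogram sit at the two simulated lifetimes
        top_two = np.sort(np.argsort(counts)[-2:])
        centers = edges[:-1] + width / 2
        assert abs(centers[top_two[0]] - 1.5) <= width
        assert abs(centers[top_two[1]] - 3.5) <= width


class TestRoiSummaries:
    def test_single_pixel_roi(self, fitted_phantom):
        roi = np.zeros((32, 32), dtype=bool)
        roi[5, 5] = True
        profile = roi_mean_spectral_lifetime(fitted_phantom, roi)
        taus = fitted_phantom.tau_map[5, 5]
        valid = taus > 0
        np.testing.assert_allclose(profile[valid], taus[valid])
        assert np.isnan(profile[~valid]).all()

    def test_identical_rois_zero_difference(self, fitted_phantom):
        roi = np.zeros((32, 32), dtype=bool)
        roi[:, :16] = True
        a = roi_mean_spectral_lifetime(fitted_phantom, roi)
        b = roi_mean_spectral_lifetime(fitted_phantom, roi)
        d = roi_difference(a, b)
        assert np.all((d == 0) | np.isnan(d))

    def test_empty_roi_rejected(self, fitted_phantom):
        with pytest.raises(ValueError, match="empty"):
            roi_mean_spectral_lifetime(fitted_phantom, np.zeros((32, 32), dtype=bool))

    def test_region_means_track_ground_truth(self, fitted_phantom):
        left = np.zeros((32, 32), dtype=bool)
        left[:, :16] = True
        right = ~left
        a = roi_mean_spectral_lifetime(fitted_phantom, left)
        b = roi_mean_spectral_lifetime(fitted_phantom, right)
        a_valid = a[~np.isnan(a)]
        b_valid = b[~np.isnan(b)]
        assert a_valid.size > 3 and b_valid.size > 3
        np.testing.assert_allclose(a_valid, 1.5, rtol=0.05)
        np.testing.assert_allclose(b_valid, 3.5, rtol=0.05)
        # spectrally disjoint emitters: no channel is valid in both regions,
        # so the difference profile is missing (NaN) everywhere, never 0
        d = roi_difference(a, b)
        assert np.isnan(d).all()
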