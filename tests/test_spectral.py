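"""Preprocessing operators: excision, rubber-band baseline, Savitzky-Golay
second derivative, vector normalization, and their composition."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ftirpath.spectral import (
    PreprocessConfig,
    Spectrum,
    WavenumberAxis,
    excise_region,
    preprocess_pipeline,
    rubber_band_baseline,
    second_derivative,
    vector_normalize,
)

from conftest import gaussian


def make_spectrum(wn, ab):
    return Spectrum(WavenumberAxis(wn), np.asarray(ab, float))


# ---------------------------------------------------------------------------
# axis model


class TestWavenumberAxis:
    def test_descending_input_stored_ascending(self):
        ax = WavenumberAxis(np.arange(3900.0, 949.0, -50.0))
        assert ax.values[0] == 950.0 and np.all(np.diff(ax.values) > 0)

    @pytest.mark.parametrize("bad", [
        [1000.0, 1000.0, 1010.0, 1020.0, 1030.0],   # not strictly monotonic
        [100.0, 200.0, 300.0, 400.0, 500.0],        # below 400 cm-1
        [1000.0, 1010.0, 1020.0, 1030.0],           # too short
        [1000.0, np.nan, 1020.0, 1030.0, 1040.0],   # non-finite
    ])
    def test_invalid_axes_rejected(self, bad):
        with pytest.raises(ValueError):
            WavenumberAxis(bad)

    def test_spectrum_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            make_spectrum(np.arange(1000.0, 1010.0), np.zeros(5))


# ---------------------------------------------------------------------------
# excision


class TestExcision:
    def test_co2_band_channel_count(self):
        # 950..3900 step 50: channels in [2250, 2400] are 2250,2300,2350,2400
        wn = np.arange(950.0, 3901.0, 50.0)
        s = make_spectrum(wn, np.ones_like(wn))
        out = excise_region(s, 2250.0, 2400.0)
        assert len(out.axis) == wn.size - 4
        assert not np.any((out.wavenumbers >= 2250) & (out.wavenumbers <= 2400))

    def test_window_outside_axis_is_noop(self):
        wn = np.arange(950.0, 3901.0, 50.0)
        s = make_spectrum(wn, np.sin(wn))
        out = excise_region(s, 5000.0, 6000.0)
        assert np.array_equal(out.wavenumbers, s.wavenumbers)
        assert np.array_equal(out.absorbance, s.absorbance)

    def test_idempotent(self):
        wn = np.arange(950.0, 3901.0, 50.0)
        s = make_spectrum(wn, np.cos(wn / 100))
        once = excise_region(s, 2250.0, 2400.0)
        twice = excise_region(once, 2250.0, 2400.0)
        assert np.array_equal(once.wavenumbers, twice.wavenumbers)
        assert np.array_equal(once.absorbance, twice.absorbance)
        assert once.segments == twice.segments

    def test_original_untouched_and_segments_split(self):
        wn = np.arange(950.0, 3901.0, 50.0)
        s = make_spectrum(wn, np.ones_like(wn))
        out = excise_region(s, 2250.0, 2400.0)
        assert len(s.axis) == wn.size  # untouched
        assert len(out.segments) == 2
        (a0, a1), (b0, b1) = out.segments
        assert a1 - a0 + (b1 - b0) == len(out.axis)

    def test_full_cover_errors(self):
        wn = np.arange(1000.0, 1050.0, 10.0)
        s = make_spectrum(wn, np.ones_like(wn))
        with pytest.raises(ValueError, match="empty"):
            excise_region(s, 900.0, 2000.0)


# ---------------------------------------------------------------------------
# rubber-band baseline


def brute_force_lower_hull_baseline(x, y):
    """O(n^2) oracle: a point is a hull vertex iff some chord through it and
    another point keeps all points on or above the line through them, built
    by walking chords left to right."""
    n = x.size
    verts = [0]
    while verts[-1] != n - 1:
        i = verts[-1]
        best = None
        for j in range(i + 1, n):
            slope = (y[j] - y[i]) / (x[j] - x[i])
            above = y[i + 1:] >= y[i] + slope * (x[i + 1:] - x[i]) - 1e-12
            if np.all(above):
                best = j  # furthest j whose chord stays below everything
        verts.append(best)
    return np.interp(x, x[verts], y[verts])


class TestRubberBand:
    def test_line_is_its_own_baseline(self):
        wn = np.arange(950.0, 3901.0, 2.0)
        s = make_spectrum(wn, 2.0 + 0.001 * wn)
        baseline, corrected = rubber_band_baseline(s)
        assert np.allclose(corrected.absorbance, 0.0, atol=1e-9)
        assert np.allclose(baseline.absorbance, s.absorbance, atol=1e-9)

    def test_single_band_on_zero_baseline_preserved(self):
        wn = np.arange(1500.0, 1801.0, 2.0)
        ab = gaussian(wn, 1650.0, 10.0, 0.8)
        baseline, corrected = rubber_band_baseline(make_spectrum(wn, ab))
        assert np.allclose(baseline.absorbance, 0.0, atol=1e-6)
        assert np.allclose(corrected.absorbance, ab, atol=1e-6)

    def test_gaussian_on_affine_baseline_vs_oracle(self):
        wn = np.arange(1500.0, 1801.0, 2.0)
        ab = gaussian(wn, 1652.0, 10.0, 0.8) + 0.5 + 3e-4 * wn
        _, corrected = rubber_band_baseline(make_spectrum(wn, ab))
        oracle = ab - brute_force_lower_hull_baseline(wn, ab)
        assert np.allclose(corrected.absorbance, oracle, atol=1e-9)

    def test_200_random_spectra_vs_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(5, 65))
            wn = np.sort(rng.uniform(950.0, 3900.0, n))
            while np.any(np.diff(wn) <= 0):
                wn = np.sort(rng.uniform(950.0, 3900.0, n))
            ab = rng.normal(0.0, 1.0, n).cumsum()  # rough random walk
            s = make_spectrum(wn, ab)
            _, corrected = rubber_band_baseline(s)
            oracle = ab - brute_force_lower_hull_baseline(wn, ab)
            np.testing.assert_allclose(corrected.absorbance, oracle, atol=1e-9)

    def test_corrected_nonnegative_and_zero_at_vertices(self):
        rng = np.random.default_rng(3)
        wn = np.arange(950.0, 2001.0, 5.0)
        ab = rng.normal(1.0, 0.3, wn.size) + 1e-3 * wn
        _, corrected = rubber_band_baseline(make_spectrum(wn, ab))
        assert corrected.absorbance.min() >= -1e-9
        # both endpoints anchor the hull
        assert abs(corrected.absorbance[0]) < 1e-12
        assert abs(corrected.absorbance[-1]) < 1e-12

    def test_idempotent(self):
        rng = np.random.default_rng(11)
        wn = np.arange(950.0, 2001.0, 5.0)
        ab = rng.normal(1.0, 0.3, wn.size)
        _, c1 = rubber_band_baseline(make_spectrum(wn, ab))
        _, c2 = rubber_band_baseline(c1)
        assert np.max(np.abs(c2.absorbance - c1.absorbance)) <= 1e-9

    def test_excised_segments_anchored_independently(self):
        wn = np.arange(950.0, 3901.0, 2.0)
        ab = gaussian(wn, 1652.0, 10.0, 0.5) + 0.2
        s = excise_region(make_spectrum(wn, ab), 2250.0, 2400.0)
        _, corrected = rubber_band_baseline(s)
        for a, b in s.segments:
            assert abs(corrected.absorbance[a]) < 1e-12
            assert abs(corrected.absorbance[b - 1]) < 1e-12


# ---------------------------------------------------------------------------
# second derivative


class TestSecondDerivative:
    def test_quadratic_maps_to_two(self):
        wn = np.arange(1000.0, 1100.0, 2.0)
        d2 = second_derivative(make_spectrum(wn, wn ** 2))
        assert np.allclose(d2.absorbance, 2.0, atol=1e-6)

    def test_affine_annihilated(self):
        wn = np.arange(1000.0, 1100.0, 2.0)
        d2 = second_derivative(make_spectrum(wn, 3.0 + 0.5 * wn))
        assert np.allclose(d2.absorbance, 0.0, atol=1e-9)

    def test_gaussian_minimum_at_center(self):
        wn = np.arange(1500.0, 1751.0, 1.0)
        d2 = second_derivative(make_spectrum(wn, gaussian(wn, 1625.0, 8.0)))
        assert wn[np.argmin(d2.absorbance)] == 1625.0

    def test_grid_independent_scaling(self):
        # same analytic curve on two grids -> same derivative values
        for h in (1.0, 2.0):
            wn = np.arange(1600.0, 1700.0 + h / 2, h)
            d2 = second_derivative(make_spectrum(wn, 0.01 * wn ** 2))
            assert np.allclose(d2.absorbance, 0.02, atol=1e-8)

    def test_non_uniform_axis_errors(self):
        wn = np.array([1000.0, 1002.0, 1005.0, 1007.0, 1010.0, 1012.0])
        with pytest.raises(ValueError, match="resample"):
            second_derivative(make_spectrum(wn, np.ones(6)))

    def test_window_longer_than_spectrum_errors(self):
        wn = np.arange(1000.0, 1012.0, 2.0)
        with pytest.raises(ValueError):
            second_derivative(make_spectrum(wn, np.ones(wn.size)), window=7)


# ---------------------------------------------------------------------------
# vector normalization


class TestVectorNormalize:
    def test_three_four_five(self):
        wn = np.arange(1000.0, 1010.0, 2.0)
        s = make_spectrum(wn, [3.0, 4.0, 0.0, 0.0, 0.0])
        out = vector_normalize(s)
        assert np.allclose(out.absorbance[:2], [0.6, 0.8])

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        wn = np.arange(950.0, 3901.0, 2.0)
        s = vector_normalize(make_spectrum(wn, rng.normal(size=wn.size)))
        out = vector_normalize(s)
        assert np.max(np.abs(out.absorbance - s.absorbance)) < 1e-12

    def test_norm_and_shape_preserved(self):
        rng = np.random.default_rng(6)
        wn = np.arange(950.0, 3901.0, 2.0)
        ab = rng.normal(size=wn.size)
        out = vector_normalize(make_spectrum(wn, ab))
        # independent norm computation
        assert abs(np.sqrt(np.sum(out.absorbance ** 2)) - 1.0) < 1e-12
        assert np.argmax(out.absorbance) == np.argmax(ab)
        assert np.array_equal(np.sign(out.absorbance), np.sign(ab))

    def test_null_spectrum_errors(self):
        wn = np.arange(1000.0, 1010.0, 2.0)
        with pytest.raises(ValueError, match="null"):
            vector_normalize(make_spectrum(wn, np.zeros(5)))

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(7)
        wn = np.arange(950.0, 1051.0, 2.0)
        ab = rng.normal(size=wn.size)
        a = vector_normalize(make_spectrum(wn, ab))
        b = vector_normalize(make_spectrum(wn, c * ab))
        assert np.allclose(a.absorbance, b.absorbance, atol=1e-9)


# ---------------------------------------------------------------------------
# composed pipeline


class TestPipeline:
    def test_identity_config_flat_input(self):
        wn = np.arange(950.0, 3901.0, 2.0)
        ab = gaussian(wn, 1652.0, 10.0)
        cfg = PreprocessConfig(excise_windows=())
        res = preprocess_pipeline(make_spectrum(wn, ab), cfg)
        assert np.allclose(res.corrected.absorbance, ab, atol=1e-6)

    def test_postconditions_on_synthetic_spectrum(self):
        from ftirpath.synthetic import case_template_spectrum, default_study_specs

        s = case_template_spectrum(default_study_specs()[0], "GM")
        res = preprocess_pipeline(s)
        assert res.corrected.absorbance.min() >= -1e-9
        assert abs(np.linalg.norm(res.derivative.absorbance) - 1.0) < 1e-12

    def test_equals_manual_composition(self):
        from ftirpath.synthetic import case_template_spectrum, default_study_specs

        s = case_template_spectrum(default_study_specs()[1], "WM")
        res = preprocess_pipeline(s)
        manual = excise_region(s, 2250.0, 2400.0)
        _, manual_corr = rubber_band_baseline(manual)
        manual_deriv = vector_normalize(second_derivative(manual_corr, 5, 2))
        assert np.array_equal(res.corrected.absorbance, manual_corr.absorbance)
        assert np.array_equal(res.derivative.absorbance, manual_deriv.absorbance)

    @given(
        center=st.floats(min_value=1200.0, max_value=1800.0),
        sigma=st.floats(min_value=4.0, max_value=30.0),
        amp=st.floats(min_value=0.1, max_value=2.0),
        offset=st.floats(min_value=0.0, max_value=1.0),
        slope=st.floats(min_value=-2e-4, max_value=5e-4),
    )
    def test_peak_location_preserved_through_full_chain(self, center, sigma,
                                                        amp, offset, slope):
        """A single Gaussian on any affine baseline keeps its argmin channel
        through excision -> hull -> SG second derivative -> normalization."""
        wn = np.arange(950.0, 3901.0, 2.0)
        center = 2.0 * round(center / 2.0)  # put the center on-grid
        ab = gaussian(wn, center, sigma, amp) + offset + slope * (wn - 950.0)
        res = preprocess_pipeline(make_spectrum(wn, ab))
        d = res.derivative
        assert d.wavenumbers[np.argmin(d.absorbance)] == center
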