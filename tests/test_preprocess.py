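"""Spectral preprocessing: smoothing, baseline, picking, alignment,
mass filtering and TIC normalisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zonemsi.preprocess import (
    FeatureMatrix,
    PreprocessConfig,
    Spectrum,
    align_features,
    baseline_correct,
    mass_range_filter,
    pick_peaks,
    preprocess_mode,
    smooth_spectrum,
    tic_normalize,
)


def spectrum(mz, intensity):
    return Spectrum(np.asarray(mz, float), np.asarray(intensity, float))


class TestSmoothing:
    def test_window_one_is_identity(self):
        s = spectrum([1, 2, 3], [5, 7, 9])
        out = smooth_spectrum(s, window=1)
        assert np.array_equal(out.intensity, s.intensity)

    def test_constant_spectrum_unchanged(self):
        s = spectrum(np.arange(10) + 100.0, np.full(10, 4.0))
        out = smooth_spectrum(s, window=5)
        assert np.allclose(out.intensity, 4.0)

    def test_impulse_spreads_to_thirds(self):
        y = np.zeros(9)
        y[4] = 9.0
        out = smooth_spectrum(spectrum(np.arange(9) + 100.0, y), window=3)
        assert np.allclose(out.intensity[3:6], 3.0)
        assert np.allclose(out.intensity[:3], 0.0)

    def test_mz_axis_untouched(self):
        s = spectrum([1, 2, 3, 4, 5], [1, 2, 3, 2, 1])
        assert np.array_equal(smooth_spectrum(s, 3).mz, s.mz)

    @pytest.mark.parametrize("window", [0, 2, -1])
    def test_even_or_nonpositive_window_rejected(self, window):
        with pytest.raises(ValueError):
            smooth_spectrum(spectrum([1, 2, 3], [1, 1, 1]), window)

    def test_window_exceeding_length_rejected(self):
        with pytest.raises(ValueError):
            smooth_spectrum(spectrum([1, 2, 3], [1, 1, 1]), 5)


class TestBaseline:
    def test_constant_offset_removed(self):
        rng = np.random.default_rng(0)
        y = rng.uniform(1, 5, 50)
        s = spectrum(np.arange(50) + 100.0, y)
        out = baseline_correct(s, half_window=10)
        assert out.intensity.min() == 0.0
        shifted = baseline_correct(
            spectrum(s.mz, y + 3.0), half_window=10)
        assert np.allclose(shifted.intensity, out.intensity)

    def test_all_zero_stays_zero(self):
        s = spectrum(np.arange(20) + 100.0, np.zeros(20))
        assert np.allclose(baseline_correct(s, 5).intensity, 0.0)

    def test_peak_on_linear_ramp_recovered(self):
        n = 201
        mz = np.linspace(100, 120, n)
        ramp = np.linspace(0, 10, n)
        peak = 50.0 * np.exp(-0.5 * ((mz - 110) / 0.05) ** 2)
        out = baseline_correct(spectrum(mz, ramp + peak), half_window=40)
        assert abs(out.intensity.max() - 50.0) / 50.0 < 0.05

    def test_result_nonnegative(self):
        rng = np.random.default_rng(1)
        s = spectrum(np.arange(100) + 100.0, rng.exponential(2.0, 100))
        assert baseline_correct(s, 7).intensity.min() >= 0


class TestPeakPicking:
    def test_flat_zero_spectrum_yields_nothing(self):
        s = spectrum(np.arange(10) + 100.0, np.zeros(10))
        assert pick_peaks(s) == []

    def test_empty_spectrum_yields_nothing(self):
        assert pick_peaks(spectrum([], [])) == []

    def test_symmetric_peak_centroid(self):
        mz = np.linspace(499.9, 500.1, 41)
        y = 100.0 * np.exp(-0.5 * ((mz - 500.0) / 0.02) ** 2)
        peaks = pick_peaks(spectrum(mz, y), snr=1.0)
        assert len(peaks) >= 1
        centroid = min(peaks, key=lambda p: abs(p[0] - 500.0))[0]
        assert abs(centroid - 500.0) / 500.0 * 1e6 < 1.0

    def test_two_resolved_peaks_ordered(self):
        mz = np.linspace(400, 401, 101)
        y = (80.0 * np.exp(-0.5 * ((mz - 400.3) / 0.02) ** 2)
             + 80.0 * np.exp(-0.5 * ((mz - 400.7) / 0.02) ** 2))
        peaks = pick_peaks(spectrum(mz, y), snr=1.0)
        tall = [p for p in peaks if p[1] > 50]
        assert len(tall) == 2
        assert tall[0][0] < tall[1][0]

    def test_nonpositive_snr_rejected(self):
        with pytest.raises(ValueError):
            pick_peaks(spectrum([1.0], [1.0]), snr=0)


def brute_force_single_linkage(mzs, intensities, tol_ppm):
    """Literal running-weighted-mean binning of sorted centroids."""
    labels = []
    label = -1
    wsum = msum = 0.0
    for mz, w in zip(mzs, intensities):
        if wsum > 0:
            mean = msum / wsum
            if (mz - mean) / mean * 1e6 > tol_ppm:
                wsum = msum = 0.0
        if wsum == 0:
            label += 1
        wsum += w
        msum += w * mz
        labels.append(label)
    return labels


class TestAlignment:
    def _one_pixel_matrix(self, centroids, tol_ppm):
        pixels = pd.DataFrame([{"row": 0, "col": 0, "mouse": "m1",
                                "mode": "positive", "zone": 1}])
        peaks = [[(mz, 1.0) for mz in centroids]]
        return align_features(peaks, pixels, tol_ppm=tol_ppm,
                              mode="positive")

    def test_six_ppm_apart_merges_at_ten(self):
        fm = self._one_pixel_matrix([500.000, 500.003], tol_ppm=10)
        assert fm.n_features == 1

    def test_twenty_ppm_apart_stays_split_at_ten(self):
        fm = self._one_pixel_matrix([500.000, 500.010], tol_ppm=10)
        assert fm.n_features == 2

    def test_single_pixel_features_verbatim(self):
        centroids = [150.0, 400.0, 900.0]
        fm = self._one_pixel_matrix(centroids, tol_ppm=10)
        assert np.allclose(fm.feature_mz, centroids)
        assert np.allclose(fm.values, 1.0)

    @given(st.lists(st.tuples(
        st.floats(min_value=100.0, max_value=1100.0),
        st.floats(min_value=0.1, max_value=100.0)),
        min_size=1, max_size=20))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_brute_force_single_linkage(self, peaks):
        peaks = sorted(peaks)
        mzs = [p[0] for p in peaks]
        ints = [p[1] for p in peaks]
        expected = brute_force_single_linkage(mzs, ints, tol_ppm=10)
        fm = self._one_pixel_matrix_with_int(mzs, ints)
        assert fm.n_features == max(expected) + 1

    def _one_pixel_matrix_with_int(self, mzs, ints):
        pixels = pd.DataFrame([{"row": 0, "col": 0, "mouse": "m1",
                                "mode": "positive", "zone": 1}])
        return align_features([list(zip(mzs, ints))], pixels, tol_ppm=10,
                              mode="positive")

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            self._one_pixel_matrix([500.0], tol_ppm=0)


class TestMassFilter:
    def _matrix(self, feature_mz):
        n = len(feature_mz)
        pixels = pd.DataFrame([{"row": 0, "col": 0, "mouse": "m1",
                                "mode": "positive", "zone": 1}])
        return FeatureMatrix(pixels=pixels,
                             feature_mz=np.asarray(feature_mz, float),
                             values=np.ones((1, n)), tic=np.array([float(n)]),
                             mode="positive")

    def test_inclusive_bounds(self):
        fm = mass_range_filter(self._matrix([99.5, 100.0, 1200.0, 1200.5]),
                               100.0, 1200.0)
        assert fm.n_features == 2
        assert np.allclose(fm.feature_mz, [100.0, 1200.0])

    def test_covering_range_is_identity(self):
        fm = self._matrix([150.0, 900.0])
        out = mass_range_filter(fm, 100, 1200)
        assert np.array_equal(out.feature_mz, fm.feature_mz)

    def test_empty_range_yields_zero_features(self):
        out = mass_range_filter(self._matrix([150.0, 900.0]), 2000, 3000)
        assert out.n_features == 0

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            mass_range_filter(self._matrix([150.0]), 1200, 100)


class TestTicNormalization:
    def _matrix(self, values):
        values = np.asarray(values, float)
        pixels = pd.DataFrame([{"row": 0, "col": i, "mouse": "m1",
                                "mode": "positive", "zone": 1}
                               for i in range(values.shape[0])])
        return FeatureMatrix(pixels=pixels,
                             feature_mz=np.arange(values.shape[1]) + 100.0,
                             values=values, tic=values.sum(axis=1),
                             mode="positive")

    def test_scaled_pixel_equals_reference_after_normalization(self):
        base = np.array([1.0, 2.0, 3.0])
        out = tic_normalize(self._matrix(np.stack([base, 2 * base])))
        assert np.allclose(out.values[0], out.values[1])

    def test_row_sums_equalised(self):
        rng = np.random.default_rng(2)
        out = tic_normalize(self._matrix(rng.uniform(0.1, 5, (20, 7))))
        sums = out.values.sum(axis=1)
        assert np.allclose(sums, sums[0], rtol=1e-9)

    def test_equal_tic_input_is_identity(self):
        base = np.array([[1.0, 2.0], [2.0, 1.0]])
        out = tic_normalize(self._matrix(base))
        assert np.allclose(out.values, base)

    def test_idempotence(self):
        rng = np.random.default_rng(3)
        once = tic_normalize(self._matrix(rng.uniform(0.1, 5, (10, 4))))
        twice = tic_normalize(once)
        assert np.allclose(once.values, twice.values)

    def test_zero_tic_pixels_dropped(self):
        values = np.array([[1.0, 1.0], [0.0, 0.0]])
        out = tic_normalize(self._matrix(values))
        assert len(out.pixels) == 1


class TestEndToEnd:
    def test_noiseless_recovery_is_proportional(self, noiseless_config,
                                                noiseless_data):
        """Recovered feature intensities on a noiseless simulation are
        proportional to the generated ones (r > 0.999)."""
        datasets, truth = noiseless_data
        mode_ds = [ds for (m, md), ds in sorted(datasets.items())
                   if md == "positive"]
        fm = preprocess_mode(mode_ds, PreprocessConfig())
        # generated: stack the in-lobule spectra in pixel order
        gen = np.concatenate([ds.intensity[i] for ds in mode_ds
                              for i in range(ds.n_pixels)
                              if len(ds.mz[i])])
        assert fm.values.shape[0] * fm.n_features == gen.size
        # noiseless, jitter-free: each pixel's spectrum maps 1:1 to features
        gen_matrix = gen.reshape(fm.values.shape[0], fm.n_features)
        r = np.corrcoef(gen_matrix.ravel(), fm.values.ravel())[0, 1]
        assert r > 0.999
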