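"""Spectral preprocessing: smoothing, baseline removal, peak picking,
cross-pixel alignment, mass-range filtering and TIC normalisation.

The output container is a :class:`FeatureMatrix`, pixels × aligned m/z
features, one per polarity mode.  Centroided input (the synthetic generator's
native output) goes straight to alignment; the profile-spectrum operations
(moving-average smoothing, rolling-minimum baseline, SNR peak picking) are
provided for profile-like input and follow common QTof practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import PixelDataset

logger = logging.getLogger(__name__)


@dataclass
class Spectrum:
    """One mass spectrum: strictly increasing m/z with intensities."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D and equal length")
        if len(self.mz) > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be nonnegative")

    def __len__(self) -> int:
        return len(self.mz)


def smooth_spectrum(s: Spectrum, window: int = 5) -> Spectrum:
    """Moving-average smoothing over ``window`` points (odd); m/z unchanged."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive point count")
    if window > len(s):
        raise ValueError("window larger than spectrum length")
    if window == 1:
        return Spectrum(s.mz.copy(), s.intensity.copy())
    kernel = np.ones(window) / window
    # reflect edges so constant spectra stay constant
    padded = np.pad(s.intensity, window // 2, mode="reflect")
    smoothed = np.convolve(padded, kernel, mode="valid")
    return Spectrum(s.mz.copy(), smoothed)


def baseline_correct(s: Spectrum, half_window: int = 50) -> Spectrum:
    """Subtract a rolling-minimum baseline; result is nonnegative."""
    if half_window < 1:
        raise ValueError("half_window must be >= 1")
    n = len(s)
    if n == 0:
        return Spectrum(s.mz.copy(), s.intensity.copy())
    baseline = np.empty(n)
    for i in range(n):
        lo = max(0, i - half_window)
        hi = min(n, i + half_window + 1)
        baseline[i] = s.intensity[lo:hi].min()
    return Spectrum(s.mz.copy(), s.intensity - baseline)


def pick_peaks(s: Spectrum, snr: float = 3.0) -> list[tuple[float, float]]:
    """Detect peaks as local maxima above ``snr`` × noise.

    The noise level is the median absolute deviation of the intensities.
    Each peak's centroid is the intensity-weighted mean m/z over the
    contiguous window above half its apex intensity; the reported magnitude
    is the summed intensity (area) over that window.  Isolated nonzero
    points (centroided input) count as their own local maxima.
    """
    if snr <= 0:
        raise ValueError("snr must be > 0")
    n = len(s)
    if n == 0:
        return []
    y = s.intensity
    noise = np.median(np.abs(y - np.median(y)))
    threshold = snr * noise
    peaks: list[tuple[float, float]] = []
    for i in range(n):
        if y[i] <= 0 or y[i] < threshold:
            continue
        if (i > 0 and y[i - 1] > y[i]) or (i < n - 1 and y[i + 1] > y[i]):
            continue
        # contiguous above-half-max window around the apex
        half = y[i] / 2.0
        lo = i
        while lo > 0 and y[lo - 1] >= half and y[lo - 1] <= y[lo]:
            lo -= 1
        hi = i
        while hi < n - 1 and y[hi + 1] >= half and y[hi + 1] <= y[hi]:
            hi += 1
        seg = slice(lo, hi + 1)
        area = float(y[seg].sum())
        centroid = float(np.average(s.mz[seg], weights=y[seg]))
        if peaks and abs(peaks[-1][0] - centroid) < 1e-12:
            continue  # merged with previous apex (plateau)
        peaks.append((centroid, area))
    return peaks


@dataclass
class FeatureMatrix:
    """Pixels × aligned m/z features for one polarity mode."""

    pixels: pd.DataFrame          # columns: row, col, mouse, mode, zone
    feature_mz: np.ndarray        # strictly increasing consensus m/z
    values: np.ndarray            # (n_pixels, n_features), nonnegative
    tic: np.ndarray               # per-pixel total ion count pre-normalisation
    mode: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.pixels), len(self.feature_mz)):
            raise ValueError("values shape inconsistent with pixels/features")
        if len(self.feature_mz) > 1 and \
                not np.all(np.diff(self.feature_mz) > 0):
            raise ValueError("consensus m/z must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def n_features(self) -> int:
        return len(self.feature_mz)

    def features_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature_id": [f"{self.mode[:3]}_{i:04d}"
                           for i in range(self.n_features)],
            "mz": self.feature_mz,
            "mode": self.mode,
        })


def _single_linkage_bins(mz: np.ndarray, intensity: np.ndarray,
                         tol_ppm: float) -> np.ndarray:
    """Bin labels for sorted centroids by the running weighted-mean rule.

    Scanning in ascending m/z, a centroid joins the current bin while it is
    within ``tol_ppm`` of the bin's running intensity-weighted mean m/z,
    otherwise it opens a new bin.  A gap larger than the tolerance between
    consecutive centroids always opens a new bin (the running mean never
    exceeds the previous centroid), which lets long tight stretches be
    labelled in vectorised blocks.
    """
    n = len(mz)
    labels = np.zeros(n, dtype=np.int64)
    if n == 0:
        return labels
    rel_gap = np.empty(n)
    rel_gap[0] = np.inf
    rel_gap[1:] = np.diff(mz) / mz[:-1] * 1e6
    block_starts = np.flatnonzero(rel_gap > tol_ppm)
    block_ends = np.append(block_starts[1:], n)
    label = -1
    for start, end in zip(block_starts, block_ends):
        span_ppm = (mz[end - 1] - mz[start]) / mz[start] * 1e6
        if span_ppm <= tol_ppm:
            label += 1
            labels[start:end] = label
            continue
        # wide block: apply the literal running-mean rule
        wsum = 0.0
        msum = 0.0
        for i in range(start, end):
            if wsum > 0 and (mz[i] - msum / wsum) / (msum / wsum) * 1e6 \
                    > tol_ppm:
                wsum = 0.0
                msum = 0.0
            if wsum == 0.0:
                label += 1
            w = max(intensity[i], 1e-300)
            wsum += w
            msum += w * mz[i]
            labels[i] = label
    return labels


def align_features(peaks_per_pixel: list,
                   pixels: pd.DataFrame, tol_ppm: float = 10.0,
                   mode: str = "") -> FeatureMatrix:
    """Align per-pixel peak centroids into a pixel × feature matrix.

    Peaks from all pixels are pooled, sorted by m/z and single-linkage
    binned at ``tol_ppm`` against the running intensity-weighted bin mean.
    Consensus feature m/z is the intensity-weighted mean of each bin; a
    pixel without a peak in a bin gets 0.  Intensities of multiple peaks
    of one pixel falling in one bin are summed.

    Each ``peaks_per_pixel`` entry is either a list of (centroid m/z, area)
    tuples (the :func:`pick_peaks` output) or a ``(mz_array, int_array)``
    pair for already-centroided input.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    n_pixels = len(pixels)
    if len(peaks_per_pixel) != n_pixels:
        raise ValueError("peaks_per_pixel length must match pixels")
    mz_arrays: list[np.ndarray] = []
    int_arrays: list[np.ndarray] = []
    px_arrays: list[np.ndarray] = []
    for px, peaks in enumerate(peaks_per_pixel):
        if isinstance(peaks, tuple) and len(peaks) == 2:
            mz_arr = np.asarray(peaks[0], dtype=float)
            int_arr = np.asarray(peaks[1], dtype=float)
        elif len(peaks) == 0:
            continue
        else:
            arr = np.asarray(peaks, dtype=float)
            mz_arr, int_arr = arr[:, 0], arr[:, 1]
        if len(mz_arr) == 0:
            continue
        mz_arrays.append(mz_arr)
        int_arrays.append(int_arr)
        px_arrays.append(np.full(len(mz_arr), px, dtype=np.int64))
    if not mz_arrays:
        return FeatureMatrix(pixels=pixels.reset_index(drop=True),
                             feature_mz=np.empty(0), tic=np.zeros(n_pixels),
                             values=np.zeros((n_pixels, 0)), mode=mode)
    all_mz = np.concatenate(mz_arrays)
    all_int = np.concatenate(int_arrays)
    all_px = np.concatenate(px_arrays)
    order = np.argsort(all_mz, kind="stable")
    all_mz, all_int, all_px = all_mz[order], all_int[order], all_px[order]
    labels = _single_linkage_bins(all_mz, all_int, tol_ppm)
    n_features = int(labels[-1]) + 1
    wsum = np.bincount(labels, weights=all_int, minlength=n_features)
    msum = np.bincount(labels, weights=all_int * all_mz,
                       minlength=n_features)
    csum = np.bincount(labels, weights=all_mz, minlength=n_features)
    cnt = np.bincount(labels, minlength=n_features)
    consensus = np.where(wsum > 0, msum / np.where(wsum > 0, wsum, 1.0),
                         csum / cnt)
    values = np.zeros((n_pixels, n_features))
    np.add.at(values, (all_px, labels), all_int)
    tic = values.sum(axis=1)
    return FeatureMatrix(pixels=pixels.reset_index(drop=True),
                         feature_mz=consensus, values=values, tic=tic,
                         mode=mode)


def mass_range_filter(fm: FeatureMatrix, lo: float = 100.0,
                      hi: float = 1200.0) -> FeatureMatrix:
    """Drop features with consensus m/z outside the inclusive [lo, hi]."""
    if lo >= hi:
        raise ValueError("lo must be < hi")
    keep = (fm.feature_mz >= lo) & (fm.feature_mz <= hi)
    if not keep.any():
        logger.warning("mass range [%g, %g] removes all features", lo, hi)
    return FeatureMatrix(pixels=fm.pixels, feature_mz=fm.feature_mz[keep],
                         values=fm.values[:, keep], tic=fm.tic.copy(),
                         mode=fm.mode, normalized=fm.normalized)


def tic_normalize(fm: FeatureMatrix) -> FeatureMatrix:
    """Scale each pixel so its feature sum equals the mean pre-normalisation
    TIC; zero-TIC pixels are dropped with a warning."""
    keep = fm.tic > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d zero-TIC pixels", n_dropped)
    values = fm.values[keep]
    tic = fm.tic[keep]
    row_sums = values.sum(axis=1)
    target = tic.mean()
    scale = np.where(row_sums > 0, target / np.where(row_sums > 0, row_sums,
                                                     1.0), 1.0)
    return FeatureMatrix(pixels=fm.pixels.loc[keep].reset_index(drop=True),
                         feature_mz=fm.feature_mz.copy(),
                         values=values * scale[:, None], tic=tic,
                         mode=fm.mode, normalized=True)


@dataclass
class PreprocessConfig:
    """Preprocessing defaults follow common QTof practice; all exposed."""

    smoothing_window: int = 5
    baseline_half_window: int = 50
    snr: float = 3.0
    alignment_tol_ppm: float = 10.0
    mz_range: tuple[float, float] = (100.0, 1200.0)
    profile_mode: bool = False   # apply smoothing/baseline/picking per pixel


def preprocess_mode(datasets: list[PixelDataset],
                    config: PreprocessConfig | None = None) -> FeatureMatrix:
    """Run the full preprocessing chain for one polarity mode.

    Pools all acquisitions (mice) of one mode, aligns peaks across every
    in-lobule pixel, applies the mass-range filter and TIC normalisation.
    Centroided input uses the stored centroids directly; with
    ``profile_mode=True`` each spectrum is smoothed, baseline-corrected and
    peak-picked first.
    """
    config = config or PreprocessConfig()
    if not datasets:
        raise ValueError("no datasets given")
    modes = {ds.mode for ds in datasets}
    if len(modes) > 1:
        raise ValueError(f"mixed polarity modes: {sorted(modes)}")
    mode = modes.pop()
    rows = []
    peaks_per_pixel: list[list[tuple[float, float]]] = []
    for ds in datasets:
        for i in range(ds.n_pixels):
            if ds.zone[i] == 0 and len(ds.mz[i]) == 0:
                continue  # background pixel
            rows.append({"row": int(ds.coords[i, 0]),
                         "col": int(ds.coords[i, 1]),
                         "mouse": ds.mouse, "mode": mode,
                         "zone": int(ds.zone[i])})
            if config.profile_mode:
                s = Spectrum(ds.mz[i], ds.intensity[i])
                s = smooth_spectrum(s, config.smoothing_window)
                s = baseline_correct(s, config.baseline_half_window)
                peaks_per_pixel.append(pick_peaks(s, config.snr))
            else:
                peaks_per_pixel.append((ds.mz[i], ds.intensity[i]))
    pixels = pd.DataFrame(rows)
    fm = align_features(peaks_per_pixel, pixels,
                        tol_ppm=config.alignment_tol_ppm, mode=mode)
    fm = mass_range_filter(fm, *config.mz_range)
    return tic_normalize(fm)


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    """Persist a FeatureMatrix as a compressed .npz plus a features TSV."""
    path = Path(path)
    np.savez_compressed(
        path.with_suffix(".npz"), values=fm.values, feature_mz=fm.feature_mz,
        tic=fm.tic, pixels=fm.pixels.to_records(index=False))
    fm.features_frame().to_csv(path.with_suffix(".features.tsv"), sep="\t",
                               index=False)
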