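"""Synthetic lobule MSI generator.

Emulates a DESI-style acquisition of one liver lobule per mouse in positive
and negative ionisation mode.  The generative model for the intensity of
lipid L in pixel p of mouse m is

    I(L, p, m) = base_L * zone_profile_L[zone(p)] * g_m * e(L, p) * t(p)

with ``g_m`` a per-mouse log-normal random intercept, ``e`` per-pixel
multiplicative log-normal measurement noise and ``t`` a per-pixel log-normal
total-ion-count scale.  The intensity is split across the mode's adducts by
the class adduct weights (the M+0 adduct intensities sum exactly to I); each
adduct additionally gets an M+1 isotopologue peak at 1.07% per carbon.  Peak
m/z values are jittered by a per-peak Gaussian ppm error and spectra are
truncated to the configured mass range.  Everything is deterministic under a
fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import C13_ABUNDANCE, C13_DELTA, ADDUCTS, theoretical_mz
from .geometry import BACKGROUND, ZONE_NAMES, LobuleGeometry, lobule_zone_map
from .library import (
    LipidLibraryEntry,
    adduct_weights_for,
    default_library,
)

logger = logging.getLogger(__name__)

MODES = ("positive", "negative")


@dataclass
class SyntheticConfig:
    """Study-design and noise parameters of the synthetic acquisition.

    Defaults emulate the study conditions: five mice, both polarity modes,
    m/z 100–1,200, 50 μm pixels, a 269-lipid library with 117 zonally
    differential species.
    """

    n_mice: int = 5
    library: list[LipidLibraryEntry] = field(default_factory=default_library)
    geometry: LobuleGeometry = field(default_factory=LobuleGeometry)
    mouse_sd: float = 0.15       # SD of the log-normal mouse intercept
    noise_sd: float = 0.15       # SD of per-pixel multiplicative noise
    tic_sd: float = 0.10         # SD of the per-pixel TIC scale
    mass_error_ppm: float = 2.0  # SD of per-peak m/z jitter
    adduct_weights: dict[str, float] | None = None  # override per-class rules
    mz_range: tuple[float, float] = (100.0, 1200.0)
    modes: tuple[str, ...] = MODES
    include_m1: bool = True      # simulate the M+1 isotopologue
    seed: int = 0

    def validate(self) -> None:
        if self.n_mice < 2:
            raise ValueError("n_mice must be >= 2")
        if not self.library:
            raise ValueError("lipid library must be nonempty")
        for name, val in (("mouse_sd", self.mouse_sd),
                          ("noise_sd", self.noise_sd),
                          ("tic_sd", self.tic_sd),
                          ("mass_error_ppm", self.mass_error_ppm)):
            if val < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.mz_range[0] < self.mz_range[1]:
            raise ValueError("mz_range must be increasing")
        for mode in self.modes:
            if mode not in MODES:
                raise ValueError(f"unknown polarity mode {mode!r}")


@dataclass
class PixelDataset:
    """Centroided spectra of one (mouse, mode) acquisition on a 2D grid."""

    mouse: str
    mode: str
    coords: np.ndarray            # (n_pixels, 2) int grid coordinates
    mz: list[np.ndarray]          # per-pixel sorted centroid m/z (Da)
    intensity: list[np.ndarray]   # per-pixel nonnegative intensities
    zone: np.ndarray              # per-pixel zone code (0 = background)
    grid_shape: tuple[int, int]
    pixel_size: float = 50.0

    @property
    def n_pixels(self) -> int:
        return len(self.coords)


@dataclass
class GroundTruth:
    """Planted truth of a synthetic dataset."""

    zone_mask: np.ndarray                 # grid int mask, 0 = background
    differential_lipids: set[str]
    true_dominant_zone: dict[str, str]    # lipid id -> Z1|Z2|Z3

    def to_frame(self) -> pd.DataFrame:
        rows = [{"lipid_id": lid, "differential": lid in self.differential_lipids,
                 "true_dominant_zone": self.true_dominant_zone.get(lid, "")}
                for lid in sorted(self.true_dominant_zone)]
        return pd.DataFrame(rows)


def _mode_peak_template(config: SyntheticConfig, mode: str,
                        ) -> tuple[list[LipidLibraryEntry], np.ndarray,
                                   np.ndarray, np.ndarray]:
    """Per-mode flattened peak table: (lipids, lipid_index, mz, fraction).

    ``fraction`` is the share of the lipid's pixel intensity carried by each
    peak: adduct weights for M+0 peaks, weight × 0.0107 nC for M+1.
    """
    lipids = [e for e in config.library if mode in e.polarity_modes]
    skipped = [e.id for e in config.library if mode not in e.polarity_modes]
    if skipped:
        logger.info("%d library entries absent from %s mode", len(skipped), mode)
    lip_idx, mzs, fracs = [], [], []
    lo, hi = config.mz_range
    for i, entry in enumerate(lipids):
        if config.adduct_weights is not None:
            weights = {k: v for k, v in config.adduct_weights.items()
                       if ADDUCTS[k].mode == mode}
            total = sum(weights.values())
            weights = {k: v / total for k, v in weights.items()}
        else:
            weights = adduct_weights_for(entry.lipid_class, mode)
        for adduct_name, w in weights.items():
            mz0 = theoretical_mz(entry.monoisotopic_mass, ADDUCTS[adduct_name])
            peak_list = [(mz0, w)]
            if config.include_m1:
                peak_list.append((mz0 + C13_DELTA,
                                  w * C13_ABUNDANCE * entry.n_carbon))
            for mz, frac in peak_list:
                if lo <= mz <= hi:
                    lip_idx.append(i)
                    mzs.append(mz)
                    fracs.append(frac)
    order = np.argsort(mzs, kind="stable")
    return (lipids, np.asarray(lip_idx)[order],
            np.asarray(mzs, dtype=float)[order],
            np.asarray(fracs, dtype=float)[order])


def simulate_dataset(config: SyntheticConfig,
                     ) -> tuple[dict[tuple[str, str], PixelDataset], GroundTruth]:
    """Simulate one lobule section per mouse and polarity mode.

    Returns a dict keyed by ``(mouse_id, mode)`` plus the planted ground
    truth (zone mask, differential lipid set, dominant zones).
    """
    config.validate()
    rows, cols = config.geometry.grid_shape
    zone_mask = lobule_zone_map(config.geometry)
    rr, cc = np.mgrid[0:rows, 0:cols]
    coords = np.stack([rr.ravel(), cc.ravel()], axis=1)
    zones_flat = zone_mask.ravel()
    in_lobule = zones_flat != BACKGROUND

    root = np.random.SeedSequence(config.seed)
    mouse_ss, *mode_ss = root.spawn(1 + config.n_mice * len(config.modes))
    mouse_factors = np.exp(
        np.random.default_rng(mouse_ss).normal(0.0, config.mouse_sd,
                                               config.n_mice))

    datasets: dict[tuple[str, str], PixelDataset] = {}
    stream = iter(mode_ss)
    for m in range(config.n_mice):
        mouse_id = f"mouse{m + 1}"
        for mode in config.modes:
            rng = np.random.default_rng(next(stream))
            lipids, lip_idx, tmz, tfrac = _mode_peak_template(config, mode)
            if len(tmz) == 0:
                raise ValueError(f"no library peaks in {mode} mode")
            base = np.array([e.base_abundance for e in lipids])
            profiles = np.array([e.zone_profile for e in lipids])  # (nlip, 3)
            npx = int(in_lobule.sum())
            zone_idx = zones_flat[in_lobule] - 1
            # lipid intensity per pixel: base x zonal profile x mouse x noise
            lip_int = (base[None, :] * profiles.T[zone_idx, :]
                       * mouse_factors[m])
            if config.noise_sd > 0:
                lip_int = lip_int * np.exp(
                    rng.normal(0.0, config.noise_sd, lip_int.shape))
            tic_factor = (np.exp(rng.normal(0.0, config.tic_sd, npx))
                          if config.tic_sd > 0 else np.ones(npx))
            peak_int = lip_int[:, lip_idx] * tfrac[None, :] \
                * tic_factor[:, None]
            peak_mz = np.broadcast_to(tmz[None, :], peak_int.shape)
            if config.mass_error_ppm > 0:
                jitter = rng.normal(0.0, config.mass_error_ppm,
                                    peak_int.shape)
                peak_mz = peak_mz * (1.0 + jitter * 1e-6)
                order = np.argsort(peak_mz, axis=1, kind="stable")
                peak_mz = np.take_along_axis(peak_mz, order, axis=1)
                peak_int = np.take_along_axis(peak_int, order, axis=1)
            mz_list: list[np.ndarray] = []
            int_list: list[np.ndarray] = []
            j = 0
            for flat_i in range(rows * cols):
                if in_lobule[flat_i]:
                    mz_list.append(np.ascontiguousarray(peak_mz[j]))
                    int_list.append(np.ascontiguousarray(peak_int[j]))
                    j += 1
                else:
                    mz_list.append(np.empty(0))
                    int_list.append(np.empty(0))
            datasets[(mouse_id, mode)] = PixelDataset(
                mouse=mouse_id, mode=mode, coords=coords, mz=mz_list,
                intensity=int_list, zone=zones_flat.copy(),
                grid_shape=(rows, cols),
                pixel_size=config.geometry.pixel_size)

    truth = GroundTruth(
        zone_mask=zone_mask,
        differential_lipids={e.id for e in config.library
                             if e.is_differential},
        true_dominant_zone={e.id: e.dominant_zone for e in config.library},
    )
    return datasets, truth


# --- persistence -------------------------------------------------------------

def write_datasets_hdf5(datasets: dict[tuple[str, str], PixelDataset],
                        truth: GroundTruth, path: str | Path) -> None:
    """Write all acquisitions plus the zone mask into one HDF5 container."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("zone_mask", data=truth.zone_mask)
        for (mouse, mode), ds in datasets.items():
            grp = fh.create_group(f"{mouse}/{mode}")
            grp.attrs["grid_shape"] = ds.grid_shape
            grp.attrs["pixel_size"] = ds.pixel_size
            grp.create_dataset("coords", data=ds.coords)
            grp.create_dataset("zone", data=ds.zone)
            lengths = np.array([len(a) for a in ds.mz])
            grp.create_dataset("lengths", data=lengths)
            grp.create_dataset("mz", data=np.concatenate(ds.mz))
            grp.create_dataset("intensity", data=np.concatenate(ds.intensity))


def read_datasets_hdf5(path: str | Path,
                       ) -> tuple[dict[tuple[str, str], PixelDataset],
                                  np.ndarray]:
    import h5py

    datasets: dict[tuple[str, str], PixelDataset] = {}
    with h5py.File(path, "r") as fh:
        zone_mask = fh["zone_mask"][()]
        for mouse in fh:
            if mouse == "zone_mask":
                continue
            for mode in fh[mouse]:
                grp = fh[mouse][mode]
                lengths = grp["lengths"][()]
                offsets = np.concatenate([[0], np.cumsum(lengths)])
                mz_all = grp["mz"][()]
                int_all = grp["intensity"][()]
                mz = [mz_all[offsets[i]:offsets[i + 1]]
                      for i in range(len(lengths))]
                inten = [int_all[offsets[i]:offsets[i + 1]]
                         for i in range(len(lengths))]
                datasets[(mouse, mode)] = PixelDataset(
                    mouse=mouse, mode=mode, coords=grp["coords"][()],
                    mz=mz, intensity=inten, zone=grp["zone"][()],
                    grid_shape=tuple(grp.attrs["grid_shape"]),
                    pixel_size=float(grp.attrs["pixel_size"]))
    return datasets, zone_mask


def write_ground_truth_tsv(truth: GroundTruth, path: str | Path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)


def export_imzml(ds: PixelDataset, path: str | Path) -> None:
    """Export one acquisition as centroided imzML (plus its .ibd file)."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    with ImzMLWriter(str(path), mode="processed") as writer:
        for (r, c), mz, inten in zip(ds.coords, ds.mz, ds.intensity):
            if len(mz):
                writer.addSpectrum(mz, inten, (int(c) + 1, int(r) + 1, 1))
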