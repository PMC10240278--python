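"""End-to-end orchestration: simulate → preprocess → annotate → zones →
stats → pathways, with deterministic per-stage seed substreams and a run
manifest recording the counts funnel."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import Annotation, annotations_frame, match_features, \
    rank1_lipid_features, write_annotations
from .geometry import LobuleGeometry
from .library import LipidLibraryEntry, packaged_library, read_library
from .pathways import load_pathways, rank_pathways, results_frame
from .preprocess import FeatureMatrix, PreprocessConfig, preprocess_mode, \
    write_feature_matrix
from .simulate import GroundTruth, PixelDataset, SyntheticConfig, \
    simulate_dataset, write_datasets_hdf5, write_ground_truth_tsv
from .stats import replicate_percent_cv, zonal_test, zonation_table
from .zonation import ROI, extract_roi_medians, rois_frame, sample_rois

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Single structured configuration governing every pipeline stage."""

    seed: int = 0
    n_mice: int = 5
    grid_shape: tuple[int, int] = (40, 40)
    pixel_size: float = 50.0
    zone_thresholds: tuple[float, float] = (1.0 / 3.0, 0.5)
    mouse_sd: float = 0.15
    noise_sd: float = 0.15
    tic_sd: float = 0.10
    mass_error_ppm: float = 2.0
    mz_range: tuple[float, float] = (100.0, 1200.0)
    library_path: str | None = None      # None -> packaged default library
    smoothing_window: int = 5
    baseline_half_window: int = 50
    snr: float = 3.0
    alignment_tol_ppm: float = 10.0
    annotation_tol_ppm: float = 10.0
    n_rois: int = 3
    roi_pixels: int = 10
    alpha: float = 0.05
    pathway_path: str | None = None      # None -> packaged fixture
    out_dir: str | None = None

    def validate(self) -> None:
        self.synthetic_config().validate()
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.n_rois < 1 or self.roi_pixels < 1:
            raise ValueError("n_rois and roi_pixels must be >= 1")
        if self.annotation_tol_ppm <= 0 or self.alignment_tol_ppm <= 0:
            raise ValueError("ppm tolerances must be > 0")

    def library(self) -> list[LipidLibraryEntry]:
        if self.library_path is None:
            return packaged_library()
        return read_library(self.library_path)

    def geometry(self) -> LobuleGeometry:
        return LobuleGeometry(grid_shape=tuple(self.grid_shape),
                              pixel_size=self.pixel_size,
                              zone_thresholds=tuple(self.zone_thresholds))

    def synthetic_config(self, seed: int | None = None) -> SyntheticConfig:
        return SyntheticConfig(
            n_mice=self.n_mice, library=self.library(),
            geometry=self.geometry(), mouse_sd=self.mouse_sd,
            noise_sd=self.noise_sd, tic_sd=self.tic_sd,
            mass_error_ppm=self.mass_error_ppm,
            mz_range=tuple(self.mz_range),
            seed=self.seed if seed is None else seed)

    def preprocess_config(self) -> PreprocessConfig:
        return PreprocessConfig(
            smoothing_window=self.smoothing_window,
            baseline_half_window=self.baseline_half_window, snr=self.snr,
            alignment_tol_ppm=self.alignment_tol_ppm,
            mz_range=tuple(self.mz_range))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self) -> str:
        data = asdict(self)
        for key in ("grid_shape", "zone_thresholds", "mz_range"):
            data[key] = list(data[key])
        return yaml.safe_dump(data, sort_keys=True)


def _roi_seed(seed: int, mouse_index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=seed,
                                  spawn_key=(101, mouse_index))


@dataclass
class RunResult:
    """All in-memory artifacts of one end-to-end run."""

    config: RunConfig
    truth: GroundTruth
    datasets: dict[tuple[str, str], PixelDataset]
    matrices: dict[str, FeatureMatrix]
    annotations: dict[str, list[Annotation]]
    rois_by_mouse: dict[str, list[ROI]]
    zonal_table: pd.DataFrame
    test_results: pd.DataFrame
    pathway_ranking: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    @property
    def annotated_lipids(self) -> set[str]:
        out: set[str] = set()
        for anns in self.annotations.values():
            out |= set(rank1_lipid_features(anns))
        return out

    @property
    def significant_lipids(self) -> list[str]:
        sig = self.test_results[self.test_results["significant"]]
        return sorted(sig["lipid_id"])


def run_pipeline(config: RunConfig | None = None,
                 write_outputs: bool | None = None) -> RunResult:
    """Execute every stage under one config; optionally write artifacts.

    Outputs are written when ``config.out_dir`` is set (or
    ``write_outputs=True`` with a default directory ``zonemsi_out``).
    """
    config = config or RunConfig()
    config.validate()
    library = config.library()
    lipid_classes = {e.id: e.lipid_class for e in library}
    lipid_compounds = {e.id: e.compound_id or e.lipid_class
                       for e in library}

    syn = config.synthetic_config()
    datasets, truth = simulate_dataset(syn)

    matrices: dict[str, FeatureMatrix] = {}
    annotations: dict[str, list[Annotation]] = {}
    modes = sorted({mode for (_, mode) in datasets})
    for mode in modes:
        mode_ds = [ds for (m, md), ds in sorted(datasets.items())
                   if md == mode]
        fm = preprocess_mode(mode_ds, config.preprocess_config())
        matrices[mode] = fm
        annotations[mode] = match_features(
            fm, library, tol_ppm=config.annotation_tol_ppm)

    rois_by_mouse: dict[str, list[ROI]] = {}
    for i in range(config.n_mice):
        mouse = f"mouse{i + 1}"
        rois_by_mouse[mouse] = sample_rois(
            truth.zone_mask, n_rois=config.n_rois,
            roi_pixels=config.roi_pixels, seed=_roi_seed(config.seed, i),
            mouse=mouse)

    zonal = extract_roi_medians(matrices, annotations, rois_by_mouse)
    results = zonal_test(zonal, alpha=config.alpha)
    report = zonation_table(results, lipid_classes)

    pset = load_pathways(config.pathway_path)
    sig = sorted(results.loc[results["significant"], "lipid_id"])
    ranking = results_frame(rank_pathways(pset, sig, lipid_compounds))

    n_features = sum(fm.n_features for fm in matrices.values())
    annotated = set()
    for anns in annotations.values():
        annotated |= set(rank1_lipid_features(anns))
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": yaml.safe_load(config.to_yaml()),
        "counts": {
            "features": int(n_features),
            "annotated_lipids": len(annotated),
            "tested_lipids": int(len(results)),
            "significant_lipids": int(results["significant"].sum()),
        },
    }
    result = RunResult(config=config, truth=truth, datasets=datasets,
                       matrices=matrices, annotations=annotations,
                       rois_by_mouse=rois_by_mouse, zonal_table=zonal,
                       test_results=report, pathway_ranking=ranking,
                       manifest=manifest)
    out_dir = config.out_dir
    if write_outputs and out_dir is None:
        out_dir = "zonemsi_out"
    if out_dir is not None and write_outputs is not False:
        _write_artifacts(result, Path(out_dir))
    return result


def _write_artifacts(result: RunResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_datasets_hdf5(result.datasets, result.truth,
                        out / "datasets.h5")
    write_ground_truth_tsv(result.truth, out / "ground_truth.tsv")
    for mode, fm in result.matrices.items():
        write_feature_matrix(fm, out / f"features_{mode}")
        write_annotations(result.annotations[mode],
                          out / f"annotations_{mode}.tsv")
    pd.concat([rois_frame(r) for r in result.rois_by_mouse.values()],
              ignore_index=True).to_csv(out / "rois.tsv", sep="\t",
                                        index=False)
    result.zonal_table.to_csv(out / "zonal_table.tsv", sep="\t", index=False)
    result.test_results.to_csv(out / "zonation_results.tsv", sep="\t",
                               index=False)
    result.pathway_ranking.to_csv(out / "pathway_ranking.tsv", sep="\t",
                                  index=False)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
    logger.info("artifacts written to %s", out)


def replicate_cv_study(config: RunConfig | None = None,
                       n_replicates: int = 3) -> pd.DataFrame:
    """Reproducibility assessment: replicate acquisitions of one section.

    Simulates ``n_replicates`` single-mouse acquisitions sharing the same
    ground truth (mouse effect off) but fresh measurement noise, runs
    preprocessing and zonal ROI extraction on each, and returns per-lipid
    %CV of the zone-median intensities across replicates together with
    mean abundance.
    """
    config = config or RunConfig()
    tables = []
    for rep in range(n_replicates):
        rep_cfg = RunConfig(**{**asdict(config),
                               "n_mice": 2, "mouse_sd": 0.0,
                               "seed": config.seed,
                               "out_dir": None})
        syn = rep_cfg.synthetic_config(
            seed=np.random.SeedSequence(
                entropy=config.seed, spawn_key=(202, rep)
            ).generate_state(1)[0] % (2 ** 31))
        datasets, truth = simulate_dataset(syn)
        library = rep_cfg.library()
        matrices, annotations = {}, {}
        keep_mouse = "mouse1"
        for mode in sorted({mode for (_, mode) in datasets}):
            fm = preprocess_mode([datasets[(keep_mouse, mode)]],
                                 rep_cfg.preprocess_config())
            matrices[mode] = fm
            annotations[mode] = match_features(
                fm, library, tol_ppm=rep_cfg.annotation_tol_ppm)
        rois = {keep_mouse: sample_rois(
            truth.zone_mask, n_rois=rep_cfg.n_rois,
            roi_pixels=rep_cfg.roi_pixels,
            seed=_roi_seed(config.seed, 0), mouse=keep_mouse)}
        tables.append(extract_roi_medians(matrices, annotations, rois))
    return replicate_percent_cv(tables)
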