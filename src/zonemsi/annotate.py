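"""Accurate-mass lipid annotation with adduct rules and an isotope check.

Each aligned feature is matched against the lipid library: for every
mode-compatible (lipid, adduct) pair whose theoretical m/z lies within the
ppm tolerance an :class:`Annotation` candidate is created.  Candidates per
feature are ranked by absolute ppm error, ties broken by the M+1
isotope-pattern score and then lexically by lipid id.  Sum-composition
identities are reported; chain-resolved names are synonyms of the same sum
composition at this level of evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import (
    ADDUCTS,
    C13_ABUNDANCE,
    C13_DELTA,
    AdductRule,
    ppm_error,
    theoretical_mz,
)
from .library import LipidLibraryEntry
from .preprocess import FeatureMatrix

logger = logging.getLogger(__name__)

#: Adducts searched per polarity mode during annotation.
MODE_ADDUCTS = {
    "positive": ["[M+H]+", "[M+Na]+", "[M+NH4]+", "[M+K]+"],
    "negative": ["[M-H]-"],
}


@dataclass
class Annotation:
    """One candidate (lipid, adduct) assignment of an aligned feature."""

    feature_index: int
    feature_mz: float
    lipid_id: str
    lipid_class: str
    adduct: AdductRule
    theoretical_mz: float
    ppm_error: float
    isotope_score: float
    isotope_found: bool
    rank: int = 0


def isotope_score(observed_ratio: float | None, formula: dict[str, int],
                  ) -> tuple[float, bool]:
    """Score the observed M+1/M intensity ratio against the carbon count.

    Expected ratio is 0.0107 × nC (one 13C substitution); the score is
    ``max(0, 1 − |observed − expected| / expected)``.  A missing M+1
    observation scores 0 and is flagged.
    """
    n_carbon = formula.get("C", 0)
    if n_carbon < 1:
        raise ValueError("formula must contain at least one carbon")
    if observed_ratio is None:
        return 0.0, False
    expected = C13_ABUNDANCE * n_carbon
    return max(0.0, 1.0 - abs(observed_ratio - expected) / expected), True


def observed_m1_ratios(fm: FeatureMatrix, tol_ppm: float = 10.0,
                       ) -> np.ndarray:
    """Per-feature observed M+1/M intensity ratio (NaN when no M+1 feature).

    The M+1 partner of feature i is the feature nearest to
    ``mz_i + 1.00335`` within ``tol_ppm``; intensities are totalled over
    pixels before forming the ratio.
    """
    mz = fm.feature_mz
    totals = fm.values.sum(axis=0)
    ratios = np.full(len(mz), np.nan)
    if len(mz) == 0:
        return ratios
    targets = mz + C13_DELTA
    idx = np.searchsorted(mz, targets)
    for i, target in enumerate(targets):
        best, best_err = -1, tol_ppm
        for j in (idx[i] - 1, idx[i]):
            if 0 <= j < len(mz):
                err = abs(mz[j] - target) / target * 1e6
                if err <= best_err:
                    best, best_err = j, err
        if best >= 0 and totals[i] > 0:
            ratios[i] = totals[best] / totals[i]
    return ratios


def match_features(fm: FeatureMatrix, library: list[LipidLibraryEntry],
                   adducts: list[str] | None = None,
                   tol_ppm: float = 10.0) -> list[Annotation]:
    """Annotate the features of one mode's matrix against the library.

    Returns all candidates (every mode-compatible (lipid, adduct) pair
    within ``tol_ppm``), ranked per feature by |ppm error|, ties broken by
    larger isotope score then lexical lipid id.  Features without any
    candidate are simply absent from the result (the caller can count them).
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    if not library:
        raise ValueError("library must be nonempty")
    mode = fm.mode
    if mode not in MODE_ADDUCTS:
        raise ValueError(f"feature matrix has unknown mode {mode!r}")
    adduct_names = adducts if adducts is not None else MODE_ADDUCTS[mode]
    candidates = [(e, ADDUCTS[a]) for e in library
                  if mode in e.polarity_modes
                  for a in adduct_names]
    if not candidates:
        return []
    theo = np.array([theoretical_mz(e.monoisotopic_mass, ad)
                     for e, ad in candidates])
    order = np.argsort(theo)
    theo_sorted = theo[order]
    ratios = observed_m1_ratios(fm, tol_ppm)
    annotations: list[Annotation] = []
    for i, feat_mz in enumerate(fm.feature_mz):
        tol_da = feat_mz * tol_ppm * 1e-6
        lo = np.searchsorted(theo_sorted, feat_mz - tol_da, side="left")
        hi = np.searchsorted(theo_sorted, feat_mz + tol_da, side="right")
        cands = []
        for k in range(lo, hi):
            entry, adduct = candidates[order[k]]
            err = ppm_error(feat_mz, theo_sorted[k])
            if abs(err) > tol_ppm:
                continue
            obs = None if np.isnan(ratios[i]) else float(ratios[i])
            score, found = isotope_score(obs, entry.formula)
            cands.append(Annotation(
                feature_index=i, feature_mz=float(feat_mz),
                lipid_id=entry.id, lipid_class=entry.lipid_class,
                adduct=adduct, theoretical_mz=float(theo_sorted[k]),
                ppm_error=float(err), isotope_score=score,
                isotope_found=found))
        cands.sort(key=lambda a: (abs(a.ppm_error), -a.isotope_score,
                                  a.lipid_id))
        for rank, ann in enumerate(cands, start=1):
            ann.rank = rank
        annotations.extend(cands)
    return annotations


def annotations_frame(annotations: list[Annotation]) -> pd.DataFrame:
    return pd.DataFrame([{
        "feature_index": a.feature_index, "feature_mz": a.feature_mz,
        "lipid_id": a.lipid_id, "lipid_class": a.lipid_class,
        "adduct": a.adduct.name, "theoretical_mz": a.theoretical_mz,
        "ppm_error": a.ppm_error, "isotope_score": a.isotope_score,
        "isotope_found": a.isotope_found, "rank": a.rank,
    } for a in annotations])


def write_annotations(annotations: list[Annotation], path: str | Path,
                      ) -> None:
    annotations_frame(annotations).to_csv(path, sep="\t", index=False)


def rank1_lipid_features(annotations: list[Annotation],
                         ) -> dict[str, list[int]]:
    """Map lipid id -> feature indices whose rank-1 annotation is the lipid."""
    out: dict[str, list[int]] = {}
    for a in annotations:
        if a.rank == 1:
            out.setdefault(a.lipid_id, []).append(a.feature_index)
    return out
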