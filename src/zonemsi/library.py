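"""The lipid library: sum-composition chemistry and the default synthetic set.

Lipids are represented at sum-composition level, ``CLASS(C:DB)`` with C total
acyl carbons and DB total double bonds.  Molecular formulas follow the
standard constitution of each class (diacyl glycerophospholipids, monoacyl
lyso-species, di-/tri-acylglycerols, ceramide and sphingomyelin backbones),
so the monoisotopic mass is always recomputable from the formula.

The default library holds 269 species over 12 classes, 117 of which carry a
non-flat zonal profile (periportal Z1 / midzone Z2 / pericentral Z3).  The
zonal assignments follow the known lobule biology: polyunsaturated fatty
acids and most phospholipids periportal, a phosphatidylinositol subset
midzone, di-/tri-acylglycerols and most sphingolipids pericentral, and
phosphatidylglycerols flat.  Species are admitted greedily only if every
adduct peak (and its M+1 isotopologue) is at least 25 ppm away from all
previously admitted peaks of the same polarity mode, so accurate-mass
annotation of the synthetic data is unambiguous.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .chem import (
    ADDUCTS,
    C13_ABUNDANCE,
    C13_DELTA,
    format_formula,
    monoisotopic_mass,
    parse_formula,
    theoretical_mz,
)

ZONES = ("Z1", "Z2", "Z3")

#: Minimum theoretical peak separation (ppm) enforced within a polarity mode.
MIN_PEAK_SEPARATION_PPM = 25.0


@dataclass(frozen=True)
class LipidLibraryEntry:
    """One sum-composition lipid species of the simulation library."""

    id: str
    name: str
    formula: dict[str, int]
    monoisotopic_mass: float
    lipid_class: str  # FA, LPL, PA, PC, PE, PG, PI, PS, DG, TG, Cer, SL
    polarity_modes: tuple[str, ...]
    zone_profile: tuple[float, float, float]
    base_abundance: float
    compound_id: str = ""  # class-level pathway compound (e.g. LPC -> "LPC")

    def __post_init__(self) -> None:
        if self.base_abundance <= 0:
            raise ValueError(f"{self.id}: base_abundance must be > 0")
        if min(self.zone_profile) < 0 or max(self.zone_profile) <= 0:
            raise ValueError(f"{self.id}: zone_profile must be nonnegative "
                             "with at least one positive entry")
        recomputed = monoisotopic_mass(self.formula)
        if abs(recomputed - self.monoisotopic_mass) > 1e-3:
            raise ValueError(f"{self.id}: mass {self.monoisotopic_mass} "
                             f"inconsistent with formula ({recomputed:.4f})")

    @property
    def is_differential(self) -> bool:
        return max(self.zone_profile) - min(self.zone_profile) > 1e-12

    @property
    def dominant_zone(self) -> str:
        return ZONES[max(range(3), key=lambda i: self.zone_profile[i])]

    @property
    def n_carbon(self) -> int:
        return self.formula.get("C", 0)


# --- sum-composition formulas ------------------------------------------------
# (extra C, extra H as function of c, d; O count; N count; P count)

def _gpl(c: int, d: int, dc: int, dh: int, o: int, n: int, p: int) -> dict[str, int]:
    counts = {"C": c + dc, "H": 2 * c - 2 * d + dh, "O": o}
    if n:
        counts["N"] = n
    if p:
        counts["P"] = p
    return counts


_FORMULA_BUILDERS = {
    "FA": lambda c, d: _gpl(c, d, 0, 0, 2, 0, 0),
    "LPA": lambda c, d: _gpl(c, d, 3, 7, 7, 0, 1),
    "LPC": lambda c, d: _gpl(c, d, 8, 18, 7, 1, 1),
    "LPE": lambda c, d: _gpl(c, d, 5, 12, 7, 1, 1),
    "PA": lambda c, d: _gpl(c, d, 3, 5, 8, 0, 1),
    "PC": lambda c, d: _gpl(c, d, 8, 16, 8, 1, 1),
    "PE": lambda c, d: _gpl(c, d, 5, 10, 8, 1, 1),
    "PG": lambda c, d: _gpl(c, d, 6, 11, 10, 0, 1),
    "PI": lambda c, d: _gpl(c, d, 9, 15, 13, 0, 1),
    "PS": lambda c, d: _gpl(c, d, 6, 10, 10, 1, 1),
    "DG": lambda c, d: _gpl(c, d, 3, 4, 5, 0, 0),
    "TG": lambda c, d: _gpl(c, d, 3, 2, 6, 0, 0),
    "Cer": lambda c, d: _gpl(c, d, 0, 1, 3, 1, 0),
    "SM": lambda c, d: {"C": c + 5, "H": 2 * c - 2 * d + 13, "N": 2, "O": 6, "P": 1},
}

#: subclass -> spec lipid class
_LIPID_CLASS = {"LPA": "LPL", "LPC": "LPL", "LPE": "LPL", "SM": "SL"}


def species_formula(subclass: str, c: int, d: int) -> dict[str, int]:
    """Molecular formula of the sum-composition species ``subclass(c:d)``."""
    try:
        return _FORMULA_BUILDERS[subclass](c, d)
    except KeyError:
        raise ValueError(f"unknown lipid subclass {subclass!r}") from None


def make_entry(subclass: str, c: int, d: int, mode: str,
               zone_profile: tuple[float, float, float],
               base_abundance: float) -> LipidLibraryEntry:
    formula = species_formula(subclass, c, d)
    name = f"{subclass}({c}:{d})"
    return LipidLibraryEntry(
        id=name, name=name, formula=formula,
        monoisotopic_mass=monoisotopic_mass(formula),
        lipid_class=_LIPID_CLASS.get(subclass, subclass),
        polarity_modes=(mode,),
        zone_profile=zone_profile,
        base_abundance=base_abundance,
        compound_id=subclass,
    )


# --- adduct assignment -------------------------------------------------------

#: Relative adduct intensity weights by polarity mode; neutral-lipid classes
#: (TG, DG) cationise mainly with sodium/ammonium, protonation is minor.
POSITIVE_ADDUCT_WEIGHTS = {"[M+H]+": 0.60, "[M+Na]+": 0.25, "[M+NH4]+": 0.15}
NEUTRAL_LIPID_ADDUCT_WEIGHTS = {"[M+Na]+": 0.50, "[M+NH4]+": 0.45,
                                "[M+H]+": 0.03, "[M+K]+": 0.02}
NEGATIVE_ADDUCT_WEIGHTS = {"[M-H]-": 1.0}


def adduct_weights_for(entry_class: str, mode: str) -> dict[str, float]:
    """Adduct split (weights summing to 1) for a lipid class in a mode."""
    if mode == "negative":
        return dict(NEGATIVE_ADDUCT_WEIGHTS)
    if entry_class in ("TG", "DG"):
        return dict(NEUTRAL_LIPID_ADDUCT_WEIGHTS)
    return dict(POSITIVE_ADDUCT_WEIGHTS)


#: All adducts searched during annotation, per mode; the separation guard
#: must cover these as well, or a simulated peak of one lipid could fall
#: within matching tolerance of another lipid's never-simulated adduct mass.
SEARCH_ADDUCTS = {
    "positive": ("[M+H]+", "[M+Na]+", "[M+NH4]+", "[M+K]+"),
    "negative": ("[M-H]-",),
}


def entry_peak_mzs(entry: LipidLibraryEntry, mode: str,
                   include_m1: bool = True,
                   include_search_space: bool = True) -> list[float]:
    """Theoretical peak m/z values of an entry in one mode.

    Returns the simulated adduct peaks (class adduct set, with M+1
    isotopologues when ``include_m1``) plus, when
    ``include_search_space``, the monoisotopic masses of every adduct the
    annotation stage searches in this mode.
    """
    names = set(adduct_weights_for(entry.lipid_class, mode))
    mzs = []
    for adduct_name in names:
        mz = theoretical_mz(entry.monoisotopic_mass, ADDUCTS[adduct_name])
        mzs.append(mz)
        if include_m1:
            mzs.append(mz + C13_DELTA)
    if include_search_space:
        for adduct_name in SEARCH_ADDUCTS[mode]:
            if adduct_name not in names:
                mzs.append(theoretical_mz(entry.monoisotopic_mass,
                                          ADDUCTS[adduct_name]))
    return mzs


# --- default library construction -------------------------------------------

def _profile(dominant: str | None, fold: float) -> tuple[float, float, float]:
    """Zone profile normalised to mean 1; flat when dominant is None."""
    if dominant is None:
        return (1.0, 1.0, 1.0)
    lo = 3.0 / (fold + 2.0)
    hi = fold * lo
    prof = [lo, lo, lo]
    prof[ZONES.index(dominant)] = hi
    return tuple(prof)


@dataclass
class _ClassPlan:
    subclass: str
    mode: str
    n_total: int
    base: float            # class-level abundance scale
    fold: float            # dominant/other fold for differential species
    curated: list[tuple[int, int, str | None]]   # (c, d, zone or None)
    c_range: tuple[int, int] = (0, 0)            # fallback chain-length pool
    d_max: int = 0

    def fallback_pool(self) -> list[tuple[int, int]]:
        seen = {(c, d) for c, d, _ in self.curated}
        pool = []
        for d in range(self.d_max + 1):
            for c in range(self.c_range[0], self.c_range[1] + 1):
                if (c, d) not in seen:
                    pool.append((c, d))
        return pool


def _class_plans() -> list[_ClassPlan]:
    # Curated species reproduce the printed zonal biology; fillers extend
    # each class to its quota with plausible chain lengths.
    plans = [
        _ClassPlan(
            "FA", "negative", 20, base=60.0, fold=4.0,
            curated=[(18, 2, "Z1"), (20, 2, "Z1"), (20, 3, "Z1"),
                     (20, 4, "Z1"), (22, 4, "Z1"), (22, 6, "Z1"),
                     (16, 1, "Z1"), (18, 1, "Z1"), (18, 3, "Z1"),
                     (20, 5, "Z1"), (22, 5, "Z1"), (24, 1, "Z1"),
                     (16, 0, None), (18, 0, None), (14, 0, None),
                     (17, 0, None), (17, 1, None), (19, 1, None),
                     (20, 0, None), (24, 0, None)],
            c_range=(13, 26), d_max=6,
        ),
        _ClassPlan(
            "LPA", "negative", 5, base=18.0, fold=3.0,
            curated=[(18, 0, "Z1"), (18, 1, "Z1"),
                     (16, 0, None), (18, 2, None), (20, 4, None)],
            c_range=(14, 22), d_max=6,
        ),
        _ClassPlan(
            "LPC", "positive", 8, base=30.0, fold=3.0,
            curated=[(18, 1, "Z1"), (16, 0, "Z1"), (18, 2, "Z1"),
                     (18, 0, "Z3"),
                     (16, 1, None), (20, 4, None), (22, 6, None),
                     (17, 0, None)],
            c_range=(14, 22), d_max=6,
        ),
        _ClassPlan(
            "LPE", "negative", 5, base=18.0, fold=3.0,
            curated=[(16, 0, "Z1"), (18, 1, "Z1"),
                     (18, 0, None), (18, 2, None), (20, 4, None)],
            c_range=(14, 22), d_max=6,
        ),
        _ClassPlan(
            "PA", "negative", 15, base=25.0, fold=3.0,
            curated=[(40, 6, "Z1"), (40, 7, "Z1"), (36, 2, "Z1"),
                     (38, 4, "Z1"), (34, 1, "Z1"), (36, 4, "Z1"),
                     (32, 0, None), (32, 1, None), (34, 2, None),
                     (36, 1, None), (36, 3, None), (38, 3, None),
                     (38, 5, None), (40, 4, None), (42, 7, None)],
            c_range=(30, 44), d_max=10,
        ),
        _ClassPlan(
            "PC", "positive", 60, base=100.0, fold=3.0,
            curated=[
                # the most abundant liver PCs first, then the periportal,
                # midzone and pericentral subsets
                (34, 2, "Z1"), (36, 4, "Z3"), (38, 6, "Z1"),
                (32, 1, "Z1"), (34, 1, "Z1"), (34, 3, "Z1"),
                (34, 4, "Z1"), (36, 3, "Z1"), (36, 6, "Z1"), (37, 6, "Z1"),
                (32, 2, "Z1"), (33, 1, "Z1"), (36, 5, "Z1"),
                (30, 0, "Z2"), (30, 1, "Z2"), (31, 0, "Z2"), (32, 0, "Z2"),
                (33, 2, "Z2"), (35, 4, "Z2"),
                (35, 2, "Z3"), (36, 2, "Z3"), (37, 1, "Z3"),
                (37, 2, "Z3"), (37, 3, "Z3"), (38, 0, "Z3"), (39, 5, "Z3"),
                (40, 4, "Z3"), (38, 2, "Z3"), (38, 3, "Z3"), (40, 6, "Z3"),
                # flat remainder
                (34, 0, None), (35, 1, None), (36, 0, None), (36, 1, None),
                (38, 1, None), (38, 4, None), (38, 5, None), (39, 6, None),
                (40, 5, None), (40, 7, None), (40, 8, None), (41, 6, None),
                (42, 6, None), (42, 8, None), (42, 10, None), (44, 12, None),
                (31, 1, None), (33, 0, None), (35, 5, None), (37, 4, None),
                (39, 4, None), (41, 7, None), (30, 2, None), (42, 9, None),
                (44, 11, None), (29, 0, None), (43, 6, None), (41, 1, None),
            ],
            c_range=(26, 48), d_max=14,
        ),
        _ClassPlan(
            "PE", "negative", 30, base=45.0, fold=3.0,
            curated=[(36, 4, "Z1"), (36, 5, "Z1"), (38, 5, "Z1"),
                     (38, 6, "Z1"), (40, 6, "Z1"), (34, 1, "Z1"),
                     (34, 2, "Z1"), (36, 1, "Z1"), (36, 2, "Z1"),
                     (36, 3, "Z1"), (38, 3, "Z1"), (38, 4, "Z1"),
                     (40, 5, "Z1"), (40, 7, "Z1"),
                     (32, 0, None), (32, 1, None), (33, 1, None),
                     (34, 0, None), (35, 1, None), (35, 2, None),
                     (37, 4, None), (37, 6, None), (38, 1, None),
                     (38, 2, None), (39, 5, None), (40, 4, None),
                     (40, 8, None), (42, 9, None), (42, 10, None),
                     (44, 12, None)],
            c_range=(30, 44), d_max=12,
        ),
        _ClassPlan(
            "PG", "negative", 12, base=20.0, fold=1.0,
            curated=[(32, 0, None), (32, 1, None), (34, 1, None),
                     (34, 2, None), (36, 1, None), (36, 2, None),
                     (36, 3, None), (36, 4, None), (38, 4, None),
                     (38, 5, None), (38, 6, None), (40, 6, None)],
            c_range=(30, 42), d_max=8,
        ),
        _ClassPlan(
            "PI", "negative", 20, base=55.0, fold=3.0,
            curated=[
                # midzone subset
                (34, 2, "Z2"), (36, 2, "Z2"), (36, 3, "Z2"), (36, 4, "Z2"),
                (38, 5, "Z2"), (38, 6, "Z2"), (40, 5, "Z2"), (40, 6, "Z2"),
                # pericentral subset
                (38, 3, "Z3"), (38, 4, "Z3"), (39, 4, "Z3"), (42, 8, "Z3"),
                (42, 9, "Z3"),
                # flat remainder
                (32, 0, None), (32, 1, None), (34, 1, None), (36, 1, None),
                (38, 2, None), (40, 4, None), (42, 10, None)],
            c_range=(30, 44), d_max=12,
        ),
        _ClassPlan(
            "PS", "negative", 14, base=30.0, fold=3.0,
            curated=[(42, 8, "Z1"), (40, 6, "Z1"), (38, 4, "Z1"),
                     (36, 1, "Z1"), (36, 2, "Z1"), (40, 7, "Z1"),
                     (34, 1, None), (34, 2, None), (36, 3, None),
                     (36, 4, None), (38, 3, None), (38, 5, None),
                     (40, 5, None), (42, 10, None)],
            c_range=(32, 44), d_max=12,
        ),
        _ClassPlan(
            "DG", "positive", 18, base=50.0, fold=4.0,
            curated=[(36, 2, "Z3"), (36, 3, "Z3"), (38, 2, "Z3"),
                     (38, 4, "Z3"), (38, 5, "Z3"), (34, 1, "Z3"),
                     (34, 2, "Z3"), (36, 1, "Z3"), (36, 4, "Z3"),
                     (30, 0, None), (32, 0, None), (32, 1, None),
                     (34, 0, None), (34, 3, None), (38, 6, None),
                     (40, 6, None), (40, 7, None), (42, 10, None)],
            c_range=(26, 46), d_max=12,
        ),
        _ClassPlan(
            "TG", "positive", 36, base=80.0, fold=4.0,
            curated=[(50, 4, "Z3"), (50, 5, "Z3"), (51, 1, "Z3"),
                     (52, 2, "Z3"), (52, 3, "Z3"), (52, 4, "Z3"),
                     (54, 3, "Z3"), (54, 4, "Z3"), (54, 5, "Z3"),
                     (50, 1, "Z3"), (50, 2, "Z3"), (48, 1, "Z3"),
                     (46, 0, None), (46, 1, None), (46, 2, None),
                     (48, 0, None), (48, 2, None), (48, 3, None),
                     (50, 0, None), (50, 3, None), (51, 2, None),
                     (51, 3, None), (52, 1, None), (52, 5, None),
                     (52, 6, None), (53, 2, None), (53, 3, None),
                     (54, 2, None), (54, 6, None), (54, 7, None),
                     (56, 6, None), (56, 7, None), (56, 8, None),
                     (58, 8, None), (58, 9, None), (58, 10, None)],
            c_range=(42, 62), d_max=14,
        ),
        _ClassPlan(
            "Cer", "negative", 12, base=15.0, fold=4.0,
            curated=[(37, 0, "Z3"), (42, 1, "Z3"), (42, 2, "Z3"),
                     (34, 1, None), (36, 1, None), (38, 1, None),
                     (40, 1, None), (40, 2, None), (41, 1, None),
                     (43, 1, None), (44, 1, None), (44, 2, None)],
            c_range=(30, 46), d_max=3,
        ),
        _ClassPlan(
            "SM", "positive", 14, base=35.0, fold=3.0,
            curated=[(36, 0, "Z1"),
                     (40, 1, "Z3"), (42, 1, "Z3"), (42, 2, "Z3"),
                     (32, 1, None), (33, 1, None), (34, 0, None),
                     (34, 1, None), (34, 2, None), (36, 1, None),
                     (36, 2, None), (38, 1, None), (39, 1, None),
                     (41, 1, None)],
            c_range=(26, 52), d_max=8,
        ),
    ]
    return plans


def _separated(mzs: list[float], accepted: list[float]) -> bool:
    for mz in mzs:
        for other in accepted:
            if abs(mz - other) / other * 1e6 < MIN_PEAK_SEPARATION_PPM:
                return False
    return True


def default_library(mz_range: tuple[float, float] = (100.0, 1200.0),
                    ) -> list[LipidLibraryEntry]:
    """Build the default 269-species library (117 zonally differential).

    Species are admitted in curated order per class, skipping any whose
    theoretical adduct peaks (M and M+1) would fall within 25 ppm of an
    already admitted peak of the same polarity mode; skipped slots are
    refilled from per-class filler species carrying the same zonal role.
    Finally base abundances of the three dominant-zone groups are rescaled
    per mode so the expected per-pixel total ion current is zone-independent
    (which keeps TIC normalisation free of compositional artefacts).
    """
    accepted_peaks: dict[str, list[float]] = {"positive": [], "negative": []}
    entries: list[LipidLibraryEntry] = []
    for plan in _class_plans():
        n_kept = 0
        # within-class abundance spread: geometric ladder around plan.base
        spread = [plan.base * (1.25 ** (i % 7 - 3)) for i in range(plan.n_total)]
        candidates = list(plan.curated)
        filler_iter = iter(plan.fallback_pool())
        missing_zones: list[str | None] = []
        while n_kept < plan.n_total:
            if candidates:
                c, d, zone = candidates.pop(0)
            else:
                if missing_zones:
                    zone = missing_zones.pop(0)
                else:
                    zone = None
                try:
                    c, d = next(filler_iter)
                except StopIteration:
                    raise RuntimeError(
                        f"cannot fill class {plan.subclass}: filler pool "
                        "exhausted under peak-separation constraint") from None
            entry = make_entry(plan.subclass, c, d, plan.mode,
                               _profile(zone, plan.fold), spread[n_kept])
            mzs = entry_peak_mzs(entry, plan.mode)
            if not all(mz_range[0] <= mz <= mz_range[1] for mz in mzs):
                if zone is not None:
                    missing_zones.append(zone)
                continue
            if not _separated(mzs, accepted_peaks[plan.mode]):
                if zone is not None:
                    missing_zones.append(zone)
                continue
            accepted_peaks[plan.mode].extend(mzs)
            entries.append(entry)
            n_kept += 1
    return balance_zone_totals(entries)


def balance_zone_totals(entries: list[LipidLibraryEntry],
                        include_m1: bool = True) -> list[LipidLibraryEntry]:
    """Rescale dominant-zone group abundances so per-zone TIC is equal.

    Within each polarity mode, the expected pixel TIC in zone z is
    ``sum_i w_i * profile_i[z]`` with ``w_i = base_i * (1 + 0.0107 nC_i)``
    (the isotopologue contribution).  For single-dominant-zone profiles the
    zone dependence reduces to the per-group masses ``M_z``; scaling each
    group's base abundances by ``mean(M)/M_z`` equalises them exactly.
    """
    iso = (lambda e: 1.0 + C13_ABUNDANCE * e.n_carbon) if include_m1 \
        else (lambda e: 1.0)
    scale: dict[str, float] = {}
    for mode in ("positive", "negative"):
        group_mass = {z: 0.0 for z in ZONES}
        for e in entries:
            if mode not in e.polarity_modes or not e.is_differential:
                continue
            hi = max(e.zone_profile)
            lo = min(e.zone_profile)
            group_mass[e.dominant_zone] += e.base_abundance * iso(e) * (hi - lo)
        masses = [m for m in group_mass.values() if m > 0]
        if len(masses) < 3:
            continue  # cannot balance: fewer than three dominant groups
        target = sum(masses) / 3.0
        for z in ZONES:
            scale[(mode, z)] = target / group_mass[z]
    out = []
    for e in entries:
        key = (e.polarity_modes[0], e.dominant_zone)
        if e.is_differential and key in scale:
            e = LipidLibraryEntry(
                id=e.id, name=e.name, formula=e.formula,
                monoisotopic_mass=e.monoisotopic_mass,
                lipid_class=e.lipid_class, polarity_modes=e.polarity_modes,
                zone_profile=e.zone_profile,
                base_abundance=e.base_abundance * scale[key],
                compound_id=e.compound_id)
        out.append(e)
    return out


# --- TSV round-trip ----------------------------------------------------------

_TSV_COLUMNS = ["id", "name", "formula", "monoisotopic_mass", "class",
                "modes", "zone_profile", "base_abundance", "compound_id"]


def library_to_frame(entries: list[LipidLibraryEntry]) -> pd.DataFrame:
    rows = [{
        "id": e.id, "name": e.name, "formula": format_formula(e.formula),
        "monoisotopic_mass": round(e.monoisotopic_mass, 6),
        "class": e.lipid_class, "modes": ";".join(e.polarity_modes),
        "zone_profile": ",".join(f"{v:.8g}" for v in e.zone_profile),
        "base_abundance": round(e.base_abundance, 6),
        "compound_id": e.compound_id,
    } for e in entries]
    return pd.DataFrame(rows, columns=_TSV_COLUMNS)


def write_library(entries: list[LipidLibraryEntry], path: str | Path) -> None:
    library_to_frame(entries).to_csv(path, sep="\t", index=False)


def _frame_to_library(df: pd.DataFrame) -> list[LipidLibraryEntry]:
    entries = []
    for row in df.to_dict("records"):
        entries.append(LipidLibraryEntry(
            id=row["id"], name=row["name"],
            formula=parse_formula(row["formula"]),
            monoisotopic_mass=float(row["monoisotopic_mass"]),
            lipid_class=row["class"],
            polarity_modes=tuple(row["modes"].split(";")),
            zone_profile=tuple(float(v)
                               for v in row["zone_profile"].split(",")),
            base_abundance=float(row["base_abundance"]),
            compound_id="" if pd.isna(row["compound_id"])
            else str(row["compound_id"]),
        ))
    return entries


def read_library(path: str | Path | io.IOBase) -> list[LipidLibraryEntry]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "name": str})
    missing = set(_TSV_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise ValueError(f"library table missing columns: {sorted(missing)}")
    if "compound_id" not in df.columns:
        df["compound_id"] = ""
    return _frame_to_library(df)


def packaged_library() -> list[LipidLibraryEntry]:
    """The library shipped with the package (TSV fixture)."""
    ref = resources.files("zonemsi.data").joinpath("lipid_library.tsv")
    with ref.open("r") as fh:
        return read_library(fh)
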