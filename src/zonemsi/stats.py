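"""Zonal differential testing with a mouse random intercept.

For each lipid the log median intensity is modelled as

    log y = mu + beta_2 [zone = Z2] + beta_3 [zone = Z3] + b_mouse + eps,
    b_mouse ~ N(0, var_mouse),  eps ~ N(0, var_resid),

fitted by maximum likelihood with the variance ratio profiled out on a 1-D
grid plus local refinement (ML rather than REML, because the zone term is
tested by a likelihood-ratio test between nested fixed-effect structures).
The zone effect is tested with a chi-square LRT on 2 degrees of freedom and
multiplicity is controlled by the Benjamini–Hochberg step-up adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2

from .zonation import dominant_zones

logger = logging.getLogger(__name__)


@dataclass
class LmmFit:
    """ML fit of the random-intercept model for one lipid."""

    fixed_effects: dict[str, float]   # intercept (+ zone contrasts vs Z1)
    var_mouse: float
    var_resid: float
    loglik_ml: float
    n_obs: int
    include_zone: bool

    def __post_init__(self) -> None:
        if self.var_mouse < 0 or self.var_resid < 0:
            raise ValueError("variances must be nonnegative")
        if not np.isfinite(self.loglik_ml):
            raise ValueError("log-likelihood must be finite")


def _design(zones: np.ndarray, include_zone: bool) -> np.ndarray:
    n = len(zones)
    if not include_zone:
        return np.ones((n, 1))
    X = np.ones((n, 3))
    X[:, 1] = (zones == "Z2").astype(float)
    X[:, 2] = (zones == "Z3").astype(float)
    return X


def _profile_loglik(lam: float, y: np.ndarray, X: np.ndarray,
                    groups: np.ndarray) -> tuple[float, np.ndarray, float]:
    """Concentrated ML log-likelihood at variance ratio lam.

    With V = sigma^2 (I + lam Z Z'), the per-group transform
    ``v - theta_g * mean_g(v)``, theta_g = 1 - (1 + n_g lam)^{-1/2},
    whitens both y and X, after which beta and sigma^2 have closed forms.
    Returns (loglik, beta_hat, sigma2_hat).
    """
    n = len(y)
    yw = y.copy()
    Xw = X.copy()
    logdet = 0.0
    for g in np.unique(groups):
        sel = groups == g
        n_g = int(sel.sum())
        theta = 1.0 - 1.0 / np.sqrt(1.0 + n_g * lam)
        yw[sel] -= theta * yw[sel].mean()
        Xw[sel] -= theta * Xw[sel].mean(axis=0)
        logdet += np.log1p(n_g * lam)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    rss = float(np.sum((yw - Xw @ beta) ** 2))
    sigma2 = max(rss / n, 1e-300)
    ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + n + logdet)
    return ll, beta, sigma2


def fit_random_intercept(table: pd.DataFrame,
                         include_zone: bool = True) -> LmmFit:
    """Fit the mouse-random-intercept model to one lipid's zonal rows.

    ``table`` needs columns ``mouse``, ``zone`` and ``median_intensity``
    (positive; log-transformed internally).  The variance ratio
    var_mouse/var_resid is profiled on a log-spaced grid with local
    refinement of the best grid point.
    """
    y_raw = np.asarray(table["median_intensity"], dtype=float)
    if np.any(y_raw <= 0):
        raise ValueError(
            "non-positive intensities: apply the pseudo-count policy "
            "(e.g. zonal_test's half-minimum offset) before fitting")
    mice = np.asarray(table["mouse"])
    zones = np.asarray(table["zone"])
    if len(np.unique(mice)) < 2:
        raise ValueError("need at least 2 mice")
    if include_zone and len(np.unique(zones)) < 2:
        raise ValueError("need at least 2 zones to fit zone effects")
    y = np.log(y_raw)
    X = _design(zones, include_zone)

    grid = np.concatenate([[0.0], np.logspace(-4, 3, 40)])
    lls = [_profile_loglik(lam, y, X, mice)[0] for lam in grid]
    k = int(np.argmax(lls))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda lam: -_profile_loglik(lam, y, X, mice)[0],
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8})
        lam_hat = float(res.x) if -res.fun >= lls[k] else grid[k]
    else:
        lam_hat = grid[k]
    ll, beta, sigma2 = _profile_loglik(lam_hat, y, X, mice)
    names = ["intercept"] + (["Z2-Z1", "Z3-Z1"] if include_zone else [])
    return LmmFit(fixed_effects=dict(zip(names, beta.tolist())),
                  var_mouse=lam_hat * sigma2, var_resid=sigma2,
                  loglik_ml=ll, n_obs=len(y), include_zone=include_zone)


def lrt_zone(full: LmmFit, null: LmmFit) -> tuple[float, float]:
    """Likelihood-ratio chi-square test of the zone term (df = 2)."""
    if not full.include_zone or null.include_zone:
        raise ValueError("expected full fit with zone, null fit without")
    if full.n_obs != null.n_obs:
        raise ValueError("full and null fits use different data")
    chisq = max(0.0, 2.0 * (full.loglik_ml - null.loglik_ml))
    return chisq, float(chi2.sf(chisq, df=2))


def bh_adjust(pvalues: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} (p_(j) * m / j), capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def percent_cv(replicates: np.ndarray | list[float]) -> float:
    """Percent coefficient of variation, 100 × sample SD / mean."""
    x = np.asarray(replicates, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 replicates")
    mean = x.mean()
    if mean == 0:
        raise ValueError("%CV undefined for zero mean")
    return float(100.0 * x.std(ddof=1) / mean)


@dataclass
class TestResult:
    """Zonal LRT outcome for one lipid."""

    lipid_id: str
    chisq: float
    df: int
    p: float
    q: float = np.nan
    significant: bool = False
    dominant_zone: str = ""


def zonal_test(table: pd.DataFrame, alpha: float = 0.05,
               ) -> pd.DataFrame:
    """Per-lipid zone LRT over a zonal long table, with BH adjustment.

    Zero medians are offset by half the lipid's smallest positive median
    (logged) before the log transform.  Returns one row per lipid with
    chisq, p, BH q, significance at ``alpha`` and the dominant zone.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    results: list[TestResult] = []
    for lipid_id, sub in table.groupby("lipid_id", sort=True):
        sub = sub.copy()
        vals = sub["median_intensity"].to_numpy(dtype=float)
        if np.any(vals <= 0):
            positive = vals[vals > 0]
            if positive.size == 0:
                logger.warning("lipid %s all-zero; skipped", lipid_id)
                continue
            offset = 0.5 * positive.min()
            logger.info("lipid %s: %d non-positive medians offset by %g",
                        lipid_id, int((vals <= 0).sum()), offset)
            sub["median_intensity"] = vals + offset
        full = fit_random_intercept(sub, include_zone=True)
        null = fit_random_intercept(sub, include_zone=False)
        chisq, p = lrt_zone(full, null)
        results.append(TestResult(lipid_id=lipid_id, chisq=chisq, df=2, p=p))
    if not results:
        return pd.DataFrame(columns=["lipid_id", "chisq", "df", "p", "q",
                                     "significant", "dominant_zone"])
    q = bh_adjust([r.p for r in results])
    dz = dominant_zones(table).set_index("lipid_id")
    rows = []
    for r, qv in zip(results, q):
        rows.append({"lipid_id": r.lipid_id, "chisq": r.chisq, "df": r.df,
                     "p": r.p, "q": qv, "significant": bool(qv <= alpha),
                     "dominant_zone": dz.loc[r.lipid_id, "dominant_zone"]})
    return pd.DataFrame(rows)


def zonation_table(results: pd.DataFrame,
                   lipid_classes: dict[str, str] | None = None,
                   ) -> pd.DataFrame:
    """Final significant-lipid report (adds lipid class when available)."""
    out = results.copy()
    if lipid_classes:
        out["lipid_class"] = out["lipid_id"].map(lipid_classes).fillna("")
    return out.sort_values(["q", "p", "lipid_id"], ignore_index=True)


def replicate_percent_cv(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Reproducibility across replicate acquisitions.

    Each input is one replicate's zonal long table.  For every (lipid,
    zone) the zone median intensity (median of ROI medians) is computed per
    replicate; the %CV across replicates is averaged over zones, giving one
    row per lipid with its mean abundance and %CV.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 replicate tables")
    per_rep = []
    for i, tab in enumerate(tables):
        zm = tab.groupby(["lipid_id", "zone"])["median_intensity"].median()
        per_rep.append(zm.rename(f"rep{i}"))
    wide = pd.concat(per_rep, axis=1).dropna()
    cv = wide.apply(lambda row: percent_cv(row.to_numpy()), axis=1)
    abundance = wide.mean(axis=1)
    out = pd.DataFrame({"cv_percent": cv, "abundance": abundance})
    out = out.groupby(level="lipid_id").mean()
    return out.reset_index()
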