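"""Correlation and enrichment of recombination rates with sequence features.

Joins the per-bin rate table with the per-bin feature table and
provides: Pearson and Spearman correlations with two-sided p-values,
recombination jungle/desert definitions (top and bottom rate quantiles)
with J/D enrichment ratios, GC-stratified sex-specific mean rates, and
the correlation of rate with distance to the closest chromosome end.
Bins with an undefined rate or feature value are excluded pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import RecmapError


@dataclass
class CorrelationResult:
    feature: str
    scope: str
    r: float
    p_value: float
    n_bins: int


@dataclass
class JungleDesertResult:
    feature: str
    scope: str
    mean_in_jungles: float
    mean_in_deserts: float
    ratio: float  # J/D; NaN when D == 0
    n_jungle_bins: int
    n_desert_bins: int


def _paired(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise RecmapError("need at least 3 paired finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise RecmapError("correlation undefined: zero variance")
    return x, y


def pearson_with_p(x, y, feature: str = "", scope: str = "sex_averaged") -> CorrelationResult:
    """Product-moment correlation with a two-sided p-value from the
    t transform with n - 2 degrees of freedom."""
    x, y = _paired(x, y)
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(feature, scope, float(r), float(p), len(x))


def spearman(x, y, feature: str = "", scope: str = "sex_averaged") -> CorrelationResult:
    """Pearson correlation on mid-ranks."""
    x, y = _paired(x, y)
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(feature, scope, float(rho), float(p), len(x))


def define_jungles_deserts(
    bins: pd.DataFrame, q: float = 0.10, rate_column: str = "rate_cM_per_Mb"
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of recombination jungles (top ``q`` of rates) and deserts
    (bottom ``q``); each set holds floor(q * usable bins) bins, ties broken
    deterministically by (chrom, start)."""
    if not 0 < q < 0.5:
        raise RecmapError("quantile must be in (0, 0.5)")
    usable = bins[np.isfinite(bins[rate_column])]
    n = int(np.floor(q * len(usable)))
    if n < 1:
        raise RecmapError("fewer than 1/q usable bins")
    order = usable.sort_values(
        [rate_column, "chrom", "start_bp"], kind="stable"
    ).index.to_numpy()
    deserts = order[:n]
    jungles = order[::-1][:n]
    rates = bins[rate_column]
    if rates.loc[jungles].min() <= rates.loc[deserts].max():
        raise RecmapError("degenerate rate distribution: quantiles overlap")
    return np.sort(jungles), np.sort(deserts)


def jd_ratio(
    feature_values: pd.Series,
    jungles: np.ndarray,
    deserts: np.ndarray,
    feature: str = "",
    scope: str = "sex_averaged",
) -> JungleDesertResult:
    """Mean feature abundance in jungles, in deserts, and their ratio."""
    j = float(feature_values.loc[jungles].mean())
    d = float(feature_values.loc[deserts].mean())
    return JungleDesertResult(
        feature, scope, j, d, j / d if d != 0 else float("nan"), len(jungles), len(deserts)
    )


def gc_stratified_rates(
    bins: pd.DataFrame,
    gc: np.ndarray,
    male_column: str = "rate_male",
    female_column: str = "rate_female",
    class_width: float = 0.01,
) -> pd.DataFrame:
    """Mean male and female rate per fixed-width GC class.

    Adds a ``female_exceeds_male`` flag per class; the lowest class where
    the female mean exceeds the male mean is the sex crossover point.
    """
    gc = np.asarray(gc, dtype=float)
    ok = np.isfinite(gc)
    lo = np.floor(gc[ok].min() / class_width) * class_width
    cls = np.floor((gc - lo) / class_width).astype(int)
    rows = []
    for c in sorted(set(cls[ok])):
        m = ok & (cls == c)
        rows.append(
            (
                lo + (c + 0.5) * class_width,
                float(bins.loc[m, male_column].mean()),
                float(bins.loc[m, female_column].mean()),
                int(m.sum()),
            )
        )
    out = pd.DataFrame(rows, columns=["gc_mid", "male_rate", "female_rate", "n_bins"])
    out["female_exceeds_male"] = out["female_rate"] > out["male_rate"]
    return out


def sex_crossover_gc(strata: pd.DataFrame) -> float:
    """Lowest GC-class midpoint where the female mean rate exceeds the
    male mean rate; NaN if it never does."""
    above = strata[strata["female_exceeds_male"]]
    return float(above["gc_mid"].iloc[0]) if len(above) else float("nan")


def end_distance_correlation(
    bins: pd.DataFrame,
    distance_mb: np.ndarray,
    rate_column: str = "rate_cM_per_Mb",
    scope: str = "sex_averaged",
) -> CorrelationResult:
    """Pearson correlation of recombination rate with the distance (Mb)
    to the closest chromosome end."""
    return pearson_with_p(
        bins[rate_column].to_numpy(), distance_mb, "distance_to_end_Mb", scope
    )


def correlation_table(
    bins: pd.DataFrame,
    features: pd.DataFrame,
    feature_columns: list[str],
    rate_columns: dict[str, str],
    q: float = 0.10,
    with_bh: bool = True,
) -> pd.DataFrame:
    """Per-feature, per-scope Pearson r, p, jungle/desert means and J/D.

    ``rate_columns`` maps scope name -> column of ``bins``.  A
    Benjamini-Hochberg adjusted p-value column is appended for
    convenience.
    """
    rows = []
    for scope, rcol in rate_columns.items():
        jungles, deserts = define_jungles_deserts(bins, q, rcol)
        for feat in feature_columns:
            cr = pearson_with_p(bins[rcol], features[feat], feat, scope)
            jd = jd_ratio(features[feat], jungles, deserts, feat, scope)
            rows.append(
                (
                    feat,
                    scope,
                    cr.r,
                    cr.p_value,
                    cr.n_bins,
                    jd.mean_in_jungles,
                    jd.mean_in_deserts,
                    jd.ratio,
                )
            )
    out = pd.DataFrame(
        rows, columns=["feature", "scope", "r", "p", "n_bins", "J", "D", "J_D"]
    )
    if with_bh:
        out["p_bh"] = _benjamini_hochberg(out["p"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj
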