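"""Genetic-map construction from detected crossover events.

Per adjacent-marker interval the recombination fraction r is the number
of crossover events falling in the interval divided by the number of
informative meioses covering it; an event localised to a multi-interval
span contributes fractionally, in proportion to interval bp length.
Distances are obtained with the Haldane mapping function
d = -50 ln(1 - 2r) cM (no interference), cumulated into chromosome maps
(sex-averaged or sex-specific), and summarised as recombination rates in
SNP-delimited bins of approximately 1 Mb.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import FEMALE, MALE, MarkerMap, RecmapError
from .xover import CrossoverEvent, OriginMatrix

SCOPES = ("sex_averaged", "male", "female")


def haldane(r) -> np.ndarray | float:
    """Haldane map distance in cM: d = -50 ln(1 - 2r), for 0 <= r < 0.5."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise RecmapError("recombination fraction must be in [0, 0.5)")
    d = -50.0 * np.log1p(-2.0 * r)
    return float(d) if d.ndim == 0 else d


def haldane_inv(d) -> np.ndarray | float:
    """Inverse Haldane function: r = (1 - exp(-d/50)) / 2, for d >= 0."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise RecmapError("map distance must be non-negative")
    r = 0.5 * -np.expm1(-d / 50.0)
    return float(r) if r.ndim == 0 else r


@dataclass
class IntervalEstimate:
    chromosome: str
    left_marker: str
    right_marker: str
    left_bp: int
    right_bp: int
    n_events: float
    n_informative_meioses: int
    r: float
    d_cM: float


@dataclass
class GeneticMap:
    """Ordered markers with cumulative cM positions."""

    df: pd.DataFrame  # marker_id, chrom, pos_bp, cM
    scope: str

    @property
    def total_cM(self) -> float:
        return float(
            sum(sub["cM"].iloc[-1] for _, sub in self.df.groupby("chrom", sort=False))
        )

    def chrom_total_cM(self) -> dict[str, float]:
        return {
            str(c): float(sub["cM"].iloc[-1])
            for c, sub in self.df.groupby("chrom", sort=False)
        }

    def write_tsv(self, path) -> None:
        out = self.df.copy()
        out["cM"] = out["cM"].round(2)
        out.to_csv(path, sep="\t", index=False)


def _sex_filter(scope: str):
    if scope == "male":
        return {MALE}
    if scope == "female":
        return {FEMALE}
    if scope == "sex_averaged":
        return {MALE, FEMALE}
    raise RecmapError(f"unknown scope {scope!r}")


def meiosis_coverage(
    origins: list[OriginMatrix], markers: MarkerMap, scope: str = "sex_averaged"
) -> np.ndarray:
    """Number of informative meioses covering each adjacent-marker interval.

    A meiosis covers interval (k, k+1) when its assigned origin span
    reaches both flanking markers.
    """
    sexes = _sex_filter(scope)
    cov = np.zeros(markers.n_markers, dtype=np.int64)  # interval k = (k, k+1)
    for om in origins:
        if om.parent_sex not in sexes:
            continue
        assigned = om.matrix != -1
        for chrom in markers.chromosomes():
            cols = markers.chrom_slice(chrom)
            sub = assigned[:, cols]
            any_row = sub.any(axis=1)
            if not any_row.any():
                continue
            first = np.argmax(sub, axis=1)
            last = sub.shape[1] - 1 - np.argmax(sub[:, ::-1], axis=1)
            for f, l, ok in zip(first, last, any_row):
                if ok and l > f:
                    cov[cols[f] : cols[l]] += 1
    return cov


def interval_recombination(
    events: list[CrossoverEvent],
    origins: list[OriginMatrix],
    markers: MarkerMap,
    scope: str = "sex_averaged",
) -> list[IntervalEstimate]:
    """Per adjacent-marker interval recombination fraction and Haldane cM."""
    sexes = _sex_filter(scope)
    cov = meiosis_coverage(origins, markers, scope)
    pos = markers.df["pos_bp"].to_numpy()
    mass = np.zeros(markers.n_markers, dtype=float)
    for e in events:
        if e.parent_sex not in sexes:
            continue
        k = np.arange(e.left_index, e.right_index)
        w = (pos[k + 1] - pos[k]).astype(float)
        mass[k] += w / w.sum()
    mids = markers.df["marker_id"].to_numpy()
    chroms = markers.df["chrom"].to_numpy()
    out = []
    for chrom in markers.chromosomes():
        cols = markers.chrom_slice(chrom)
        for k in cols[:-1]:
            n_cov = int(cov[k])
            r = mass[k] / n_cov if n_cov > 0 else 0.0
            if r >= 0.5:
                raise RecmapError(
                    f"interval {mids[k]}..{mids[k + 1]} has r = {r:.3f} >= 0.5; "
                    "check the marker order"
                )
            out.append(
                IntervalEstimate(
                    chromosome=str(chroms[k]),
                    left_marker=str(mids[k]),
                    right_marker=str(mids[k + 1]),
                    left_bp=int(pos[k]),
                    right_bp=int(pos[k + 1]),
                    n_events=float(mass[k]),
                    n_informative_meioses=n_cov,
                    r=float(r),
                    d_cM=float(haldane(r)),
                )
            )
    return out


def build_map(intervals: list[IntervalEstimate], scope: str = "sex_averaged") -> GeneticMap:
    """Cumulate interval distances into a genetic map."""
    rows = []
    cm = 0.0
    last_chrom = None
    for iv in intervals:
        if iv.chromosome != last_chrom:
            cm = 0.0
            rows.append((iv.left_marker, iv.chromosome, iv.left_bp, 0.0))
            last_chrom = iv.chromosome
        cm += iv.d_cM
        rows.append((iv.right_marker, iv.chromosome, iv.right_bp, cm))
    return GeneticMap(
        pd.DataFrame(rows, columns=["marker_id", "chrom", "pos_bp", "cM"]), scope
    )


def build_maps(
    events: list[CrossoverEvent], origins: list[OriginMatrix], markers: MarkerMap
) -> dict[str, GeneticMap]:
    """Sex-averaged, male and female maps from one event set."""
    return {
        scope: build_map(interval_recombination(events, origins, markers, scope), scope)
        for scope in SCOPES
    }


def bin_rates(gmap: GeneticMap, target_bp: int = 1_000_000) -> pd.DataFrame:
    """SNP-delimited ~1 Mb bins with cM content and cM/Mb rates.

    Bin boundaries are the first marker at or beyond each multiple of
    ``target_bp`` from the previous boundary, so bins tile exactly the
    marker-covered span of each chromosome.  Half-open [start, end) bp
    intervals; a chromosome with fewer than two markers yields no bins.
    """
    rows = []
    for chrom, sub in gmap.df.groupby("chrom", sort=False):
        pos = sub["pos_bp"].to_numpy()
        cm = sub["cM"].to_numpy()
        if len(pos) < 2:
            continue
        i = 0
        while i < len(pos) - 1:
            j = int(np.searchsorted(pos, pos[i] + target_bp, side="left"))
            if j >= len(pos):
                j = len(pos) - 1
            if j <= i:
                j = i + 1
            rows.append(
                (
                    chrom,
                    int(pos[i]),
                    int(pos[j]),
                    cm[j] - cm[i],
                    (cm[j] - cm[i]) / ((pos[j] - pos[i]) / 1e6),
                    j - i,
                )
            )
            i = j
    return pd.DataFrame(
        rows, columns=["chrom", "start_bp", "end_bp", "cM", "rate_cM_per_Mb", "n_markers"]
    )


def moving_average(bins: pd.DataFrame, window_bins: int = 5, column: str = "rate_cM_per_Mb") -> np.ndarray:
    """Centered moving average per chromosome, shrinking at the ends."""
    if window_bins < 1 or window_bins % 2 == 0:
        raise RecmapError("window must be odd and >= 1")
    half = window_bins // 2
    out = np.empty(len(bins), dtype=float)
    k = 0
    for _, sub in bins.groupby("chrom", sort=False):
        v = sub[column].to_numpy()
        for i in range(len(v)):
            lo, hi = max(0, i - half), min(len(v), i + half + 1)
            out[k + i] = v[lo:hi].mean()
        k += len(v)
    return out


def write_bins_tsv(bins: pd.DataFrame, path) -> None:
    out = bins.copy()
    out["cM"] = out["cM"].round(2)
    out["rate_cM_per_Mb"] = out["rate_cM_per_Mb"].round(4)
    out.to_csv(path, sep="\t", index=False)
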