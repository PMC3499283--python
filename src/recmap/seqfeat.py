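"""Per-bin sequence features: GC content, degenerate motif counts,
repeat-class coverage and distance to the closest chromosome end.

Motifs are given over the alphabet {A, C, G, T, N} where N matches any
base.  Occurrences are counted by match start position, overlapping
matches included, on both strands by default: the forward pattern and
the reverse complement of the motif are both scanned against the
forward sequence.  When a motif equals its own reverse complement the
two scans would find identical positions, so the pattern is scanned
once (no palindromic double-counting).  Soft-masked (lowercase) bases
are uppercased before matching.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ParseError, RecmapError

#: GC-rich motifs associated with elevated recombination, including the
#: CTCF consensus (CCNCCNGGNGG) and the PRDM9 consensus binding sequence
#: (CCNCCNTNNCCNC).
DEFAULT_MOTIFS = (
    "CCTCCT",
    "CCTCCCT",
    "CTCTCCC",
    "CCCCCCC",
    "CCCCACCCC",
    "CCNCCNGGNGG",
    "CCNCCNTNNCCNC",
)

REPEAT_CLASSES = ("LINE", "SINE", "LTR", "simple_repeat", "low_complexity")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(motif: str) -> str:
    return motif.translate(_COMPLEMENT)[::-1]


def _check_motif(motif: str) -> None:
    if not motif or set(motif) - set("ACGTN"):
        raise RecmapError(f"illegal motif {motif!r}: alphabet is ACGTN")


def _bin_index(starts: np.ndarray, bins: pd.DataFrame, chrom: str) -> np.ndarray:
    """Index of the half-open bin containing each position; -1 if none."""
    sub = bins[bins["chrom"] == chrom]
    if not len(sub) or not len(starts):
        return sub.index.to_numpy(), np.full(len(starts), -1, dtype=np.int64)
    lo = sub["start_bp"].to_numpy()
    hi = sub["end_bp"].to_numpy()
    idx = np.searchsorted(lo, starts, side="right") - 1
    ok = (idx >= 0) & (starts < hi[np.clip(idx, 0, len(hi) - 1)])
    out = np.where(ok, idx, -1)
    return sub.index.to_numpy(), out


def gc_content(sequences: dict[str, str], bins: pd.DataFrame) -> np.ndarray:
    """Per-bin GC fraction: (G+C)/(A+C+G+T); ambiguous bases are excluded
    from the denominator and a bin with no unambiguous base is NaN."""
    out = np.full(len(bins), np.nan)
    for i, row in bins.reset_index(drop=True).iterrows():
        seq = sequences[row["chrom"]][row["start_bp"] : row["end_bp"]].upper()
        gc = seq.count("G") + seq.count("C")
        at = seq.count("A") + seq.count("T")
        if gc + at > 0:
            out[i] = gc / (gc + at)
    return out


def scan_motif(seq: str, motif: str, both_strands: bool = True) -> np.ndarray:
    """Start positions (0-based) of all overlapping matches of ``motif``.

    With ``both_strands`` the reverse-complement pattern is also scanned
    against the forward sequence; a self-reverse-complementary motif is
    scanned only once.
    """
    _check_motif(motif)
    seq = seq.upper()
    patterns = [motif]
    rc = reverse_complement(motif)
    if both_strands and rc != motif:
        patterns.append(rc)
    starts: list[int] = []
    for pat in patterns:
        rx = re.compile("(?=" + pat.replace("N", "[ACGT]") + ")")
        starts.extend(m.start() for m in rx.finditer(seq))
    return np.array(sorted(starts), dtype=np.int64)


def count_motif(
    sequences: dict[str, str],
    motif: str,
    bins: pd.DataFrame,
    both_strands: bool = True,
) -> np.ndarray:
    """Per-bin overlapping occurrence counts, tallied by match start."""
    out = np.zeros(len(bins), dtype=np.int64)
    bins = bins.reset_index(drop=True)
    for chrom in bins["chrom"].unique():
        starts = scan_motif(sequences[chrom], motif, both_strands)
        rows, idx = _bin_index(starts, bins, str(chrom))
        for b in idx[idx >= 0]:
            out[rows[b]] += 1
    return out


def read_repeat_bed(path: str | Path) -> pd.DataFrame:
    """RepeatMasker-style BED: chrom, start, end, class (half-open)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path} line {ln}: expected 4+ tab-separated fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(f"{path} line {ln}: non-integer coordinates") from None
            if end < start:
                raise ParseError(f"{path} line {ln}: end < start")
            rows.append((parts[0], start, end, parts[3]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "repeat_class"])


def repeat_coverage(
    annotation: pd.DataFrame, bins: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Per-bin repeat counts (feature start in bin) and clipped bp coverage.

    Returns {'count': DataFrame, 'coverage': DataFrame} with one column
    per repeat class, rows aligned with ``bins``.
    """
    bins = bins.reset_index(drop=True)
    classes = sorted(annotation["repeat_class"].unique()) if len(annotation) else []
    count = pd.DataFrame(0, index=bins.index, columns=classes, dtype=np.int64)
    cover = pd.DataFrame(0, index=bins.index, columns=classes, dtype=np.int64)
    for bi, brow in bins.iterrows():
        sub = annotation[annotation["chrom"] == brow["chrom"]]
        if not len(sub):
            continue
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        in_bin = (s >= brow["start_bp"]) & (s < brow["end_bp"])
        ov = np.maximum(
            0,
            np.minimum(e, brow["end_bp"]) - np.maximum(s, brow["start_bp"]),
        )
        for cls in classes:
            m = (sub["repeat_class"] == cls).to_numpy()
            count.loc[bi, cls] = int(in_bin[m].sum())
            cover.loc[bi, cls] = int(ov[m].sum())
    return {"count": count, "coverage": cover}


def distance_to_end(bins: pd.DataFrame, chrom_lengths: dict[str, int]) -> np.ndarray:
    """min(midpoint, length - midpoint) in Mb for each bin."""
    out = np.empty(len(bins))
    for i, row in bins.reset_index(drop=True).iterrows():
        L = chrom_lengths[row["chrom"]]
        if row["start_bp"] < 0 or row["end_bp"] > L:
            raise RecmapError(
                f"bin {row['chrom']}:{row['start_bp']}-{row['end_bp']} outside chromosome"
            )
        mid = 0.5 * (row["start_bp"] + row["end_bp"])
        out[i] = min(mid, L - mid) / 1e6
    return out


def feature_table(
    sequences: dict[str, str],
    bins: pd.DataFrame,
    chrom_lengths: dict[str, int] | None = None,
    motifs=DEFAULT_MOTIFS,
    repeats: pd.DataFrame | None = None,
    both_strands: bool = True,
) -> pd.DataFrame:
    """Assemble the per-bin feature table keyed like the bin table."""
    out = bins.reset_index(drop=True)[["chrom", "start_bp", "end_bp"]].copy()
    out["GC"] = gc_content(sequences, bins)
    for motif in motifs:
        out[motif] = count_motif(sequences, motif, bins, both_strands)
    if repeats is not None:
        rc = repeat_coverage(repeats, bins)
        for cls in rc["count"].columns:
            out[f"{cls}_count"] = rc["count"][cls].to_numpy()
            out[f"{cls}_bp"] = rc["coverage"][cls].to_numpy()
    if chrom_lengths is None:
        chrom_lengths = {c: len(s) for c, s in sequences.items()}
    out["distance_to_end_Mb"] = distance_to_end(bins, chrom_lengths)
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA into {name: sequence} via indexed access."""
    from pyfaidx import Fasta

    with Fasta(str(path)) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
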