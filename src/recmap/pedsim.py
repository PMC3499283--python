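"""Synthetic F2 pedigrees, meioses with known crossovers, and genomes.

The generator emulates the experimental designs used for SNP-chip
linkage mapping in livestock: two divergent founder lines are crossed,
their F1s are intercrossed, and full-sib F2 families of configurable
size are genotyped on a dense marker panel.  Crossovers are placed
interference-free (counts are Poisson with mean ``map_cM / 100`` per
meiosis), consistent with the Haldane mapping function used downstream.
Every simulated crossover is recorded as ground truth so detection,
map construction and feature-enrichment stages can be validated by
parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    FEMALE,
    MALE,
    MISSING,
    ConfigError,
    GenotypeMatrix,
    MarkerMap,
    Pedigree,
    marker_map_from_positions,
)

import pandas as pd


@dataclass
class SimConfig:
    """Design of a simulated mapping experiment.

    ``male_map_cM`` / ``female_map_cM`` are per-chromosome genetic
    lengths in centimorgans.  ``founder_maf`` is the within-line minor
    allele frequency of chip SNPs.  At 0 the two lines carry fixed
    alternate alleles, which maximises segregation but makes both F1
    parents heterozygous at every marker — then no marker is informative
    for one parent only and crossovers cannot be attributed to a sex at
    all.  Real line crosses segregate within lines; the default 0.15
    yields roughly 20 % of markers that are informative for exactly one
    parent, which is what anchors the sex attribution.
    """

    chrom_lengths_bp: list[int]
    n_markers_per_chrom: int
    male_map_cM: list[float]
    female_map_cM: list[float]
    n_families: int = 5
    offspring_per_family: int = 8
    founder_maf: float = 0.15
    genotype_error_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_lengths_bp)

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ConfigError("need at least one chromosome")
        if len(self.male_map_cM) != self.n_chromosomes or len(
            self.female_map_cM
        ) != self.n_chromosomes:
            raise ConfigError("map length lists must match chrom_lengths_bp")
        if self.n_families < 1 or self.offspring_per_family < 1:
            raise ConfigError("need at least one family with one offspring")
        if self.n_markers_per_chrom < 2:
            raise ConfigError("need at least two markers per chromosome")
        for rate, name in (
            (self.founder_maf, "founder_maf"),
            (self.genotype_error_rate, "genotype_error_rate"),
            (self.missing_rate, "missing_rate"),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {rate}")
        if self.founder_maf > 0.5:
            raise ConfigError("founder_maf must be at most 0.5")
        if min(self.male_map_cM) < 0 or min(self.female_map_cM) < 0:
            raise ConfigError("map lengths must be non-negative")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass
class CrossoverTruth:
    """Ground truth for one meiosis on one chromosome."""

    meiosis_id: str
    parent_id: str
    parent_sex: int
    chromosome: str
    crossover_positions_bp: list[float]


@dataclass
class GenomeTruth:
    """Synthetic genome with known per-bin feature/recombination structure."""

    sequences: dict[str, str]
    bin_size: int
    bin_gc: dict[str, np.ndarray]
    planted_counts: dict[str, dict[str, np.ndarray]]  # chrom -> motif -> counts
    latent_intensity: dict[str, np.ndarray]

    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Build an F2 pedigree: per family, four F0 founders (two per line),
    an F1 sire and dam, and ``offspring_per_family`` F2 full sibs."""
    rows = []
    for f in range(1, config.n_families + 1):
        fam = f"fam{f}"
        a_m, a_f = f"{fam}_F0_A_m", f"{fam}_F0_A_f"
        b_m, b_f = f"{fam}_F0_B_m", f"{fam}_F0_B_f"
        rows += [
            (a_m, "0", "0", MALE, fam, "A", 0),
            (a_f, "0", "0", FEMALE, fam, "A", 0),
            (b_m, "0", "0", MALE, fam, "B", 0),
            (b_f, "0", "0", FEMALE, fam, "B", 0),
        ]
        f1_sire, f1_dam = f"{fam}_F1_m", f"{fam}_F1_f"
        rows.append((f1_sire, a_m, b_f, MALE, fam, "", 1))
        rows.append((f1_dam, b_m, a_f, FEMALE, fam, "", 1))
        for k in range(1, config.offspring_per_family + 1):
            rows.append((f"{fam}_F2_{k}", f1_sire, f1_dam, 1 + (k % 2), fam, "", 2))
    df = pd.DataFrame(
        rows, columns=["id", "sire", "dam", "sex", "family", "line", "generation"]
    )
    return Pedigree(df)


def uniform_markers(config: SimConfig) -> MarkerMap:
    """Markers evenly spaced in bp, leaving a half-spacing margin at ends."""
    pos = {}
    for chrom, length in zip(config.chrom_names(), config.chrom_lengths_bp):
        n = config.n_markers_per_chrom
        step = length / (n + 1)
        pos[chrom] = np.round(step * np.arange(1, n + 1)).astype(int)
    return marker_map_from_positions(pos)


def _inverse_map_positions(u: np.ndarray, length_bp: int, intensity=None) -> np.ndarray:
    """Map uniform draws on the genetic scale to bp via the inverse
    cumulative genetic map.  ``intensity`` is an optional per-bin array of
    relative recombination weights over equal-width bp bins; None means a
    uniform genetic map."""
    if intensity is None or len(intensity) == 0:
        return u * length_bp
    w = np.asarray(intensity, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ConfigError("latent intensity must be non-negative and not all zero")
    edges = np.linspace(0.0, length_bp, len(w) + 1)
    cum = np.concatenate([[0.0], np.cumsum(w)]) / w.sum()
    return np.interp(u, cum, edges)


def simulate_meioses(
    ped: Pedigree,
    markers: MarkerMap,
    config: SimConfig,
    intensity: dict[str, np.ndarray] | None = None,
) -> tuple[GenotypeMatrix, list[CrossoverTruth]]:
    """Gene-drop through the pedigree with sex-specific crossover processes.

    Founder haplotypes are drawn per line from ``founder_maf``; each
    meiosis draws Poisson(map_cM/100) crossovers per chromosome for the
    transmitting parent's sex and copies the parental haplotypes with
    switches at the crossover positions.  ``intensity`` optionally
    modulates where crossovers fall: either ``{chrom: per-bin weights}``
    applied to both sexes, or ``{MALE: {...}, FEMALE: {...}}`` for
    sex-specific landscapes.  Returns the genotype matrix (before any
    error injection) and the full crossover truth.
    """
    if markers.n_markers == 0:
        raise ConfigError("marker map is empty")
    rng = np.random.default_rng(config.seed)
    chroms = config.chrom_names()
    chrom_cols = {c: markers.chrom_slice(c) for c in chroms}
    chrom_pos = {c: markers.df["pos_bp"].to_numpy()[chrom_cols[c]] for c in chroms}
    map_len = {
        MALE: dict(zip(chroms, config.male_map_cM)),
        FEMALE: dict(zip(chroms, config.female_map_cM)),
    }
    chrom_len = dict(zip(chroms, config.chrom_lengths_bp))

    n_markers = markers.n_markers
    haplo: dict[str, np.ndarray] = {}
    truth: list[CrossoverTruth] = []

    df = ped.df
    sex_of = dict(zip(df["id"], df["sex"].astype(int)))

    def founder_haplotypes(line: str) -> np.ndarray:
        base = 0 if line == "A" else 1
        h = np.full((2, n_markers), base, dtype=np.int8)
        if config.founder_maf > 0:
            flip = rng.random((2, n_markers)) < config.founder_maf
            h[flip] = 1 - base
        return h

    def gamete(parent: str) -> np.ndarray:
        """One recombinant haplotype from ``parent``; records truth."""
        sex = sex_of[parent]
        out = np.empty(n_markers, dtype=np.int8)
        xo_by_chrom = {}
        per_sex = intensity.get(sex, intensity) if intensity else None
        for chrom in chroms:
            L = map_len[sex][chrom]
            n_xo = rng.poisson(L / 100.0)
            inten = per_sex.get(chrom) if per_sex else None
            pos = np.sort(
                _inverse_map_positions(rng.random(n_xo), chrom_len[chrom], inten)
            )
            start = int(rng.integers(2))
            cols = chrom_cols[chrom]
            hap_idx = (start + np.searchsorted(pos, chrom_pos[chrom], side="left")) % 2
            out[cols] = haplo[parent][hap_idx, cols]
            xo_by_chrom[chrom] = pos
        return out, xo_by_chrom

    # parents before children: generation order if present, else topological
    if "generation" in df.columns:
        order = df.sort_values("generation", kind="stable")
    else:
        order = _topological(df)
    for _, row in order.iterrows():
        iid, sire, dam = row["id"], row["sire"], row["dam"]
        if sire == "0" and dam == "0":
            haplo[iid] = founder_haplotypes(row.get("line", "A") or "A")
            continue
        if sire == "0" or dam == "0":
            raise ConfigError(f"individual {iid} has a single known parent")
        h = np.empty((2, n_markers), dtype=np.int8)
        for j, parent in enumerate((sire, dam)):
            h[j], xo = gamete(parent)
            for chrom, pos in xo.items():
                truth.append(
                    CrossoverTruth(
                        meiosis_id=f"{iid}:{parent}",
                        parent_id=parent,
                        parent_sex=sex_of[parent],
                        chromosome=chrom,
                        crossover_positions_bp=pos.tolist(),
                    )
                )
        haplo[iid] = h

    ids = df["id"].tolist()
    calls = np.array([haplo[i][0] + haplo[i][1] for i in ids], dtype=np.int8)
    return GenotypeMatrix(ids, markers, calls), truth


def _topological(df: pd.DataFrame) -> pd.DataFrame:
    placed: dict[str, int] = {}
    rows = {r["id"]: r for _, r in df.iterrows()}
    order = []
    def visit(iid: str) -> None:
        if iid in placed or iid == "0":
            return
        placed[iid] = 1
        r = rows[iid]
        visit(r["sire"])
        visit(r["dam"])
        order.append(iid)
    for iid in rows:
        visit(iid)
    return df.set_index("id").loc[order].reset_index()


def inject_errors(
    gm: GenotypeMatrix, error_rate: float, missing_rate: float, seed: int
) -> GenotypeMatrix:
    """Flip calls to a different legal genotype with probability
    ``error_rate``, then set calls missing with probability
    ``missing_rate``.  The input matrix is not modified."""
    for rate, name in ((error_rate, "error_rate"), (missing_rate, "missing_rate")):
        if not 0.0 <= rate <= 1.0:
            raise ConfigError(f"{name} must be in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    calls = gm.calls.copy()
    called = calls != MISSING
    if error_rate > 0:
        flip = called & (rng.random(calls.shape) < error_rate)
        # shift by 1 or 2 (mod 3) -> always a different legal genotype
        shift = rng.integers(1, 3, size=calls.shape, dtype=np.int8)
        calls[flip] = (calls[flip] + shift[flip]) % 3
    if missing_rate > 0:
        calls[called & (rng.random(calls.shape) < missing_rate)] = MISSING
    return GenotypeMatrix(list(gm.individuals), gm.markers, calls)


def save_dataset(out_dir, ped, gm, truth, config=None) -> None:
    """Write a simulated dataset: PED/MAP + TSV genotypes, pedigree,
    crossover truth and (optionally) the YAML config."""
    from pathlib import Path

    from . import gtio_qc

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gtio_qc.write_ped_map(gm, ped, out / "dataset")
    gtio_qc.write_tsv(gm, ped, out / "dataset")
    rows = [
        (t.meiosis_id, t.chromosome, int(round(p)))
        for t in truth
        for p in t.crossover_positions_bp
    ]
    pd.DataFrame(rows, columns=["meiosis_id", "chrom", "pos_bp"]).to_csv(
        out / "crossover_truth.tsv", sep="\t", index=False
    )
    if config is not None:
        gtio_qc.write_config_yaml(config, out / "config.yaml")


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def simulate_genome(
    chrom_lengths_bp: dict[str, int],
    bin_gc_targets: dict[str, np.ndarray],
    motif_rates: dict[str, float] | None = None,
    latent_intensity: dict[str, np.ndarray] | None = None,
    bin_size: int = 1_000_000,
    seed: int = 0,
) -> GenomeTruth:
    """Random genome with controlled per-bin GC and planted motifs.

    Per bin, bases are i.i.d. with P(G)+P(C) equal to the bin's GC
    target.  Each requested motif is planted Poisson-many times per bin
    with rate ``motif_rates[motif] * latent_intensity[bin]``, so motif
    density and the latent recombination intensity are positively
    correlated by construction.  Planting overwrites the background
    sequence; N positions in a motif are filled with random bases.
    """
    rng = np.random.default_rng(seed)
    motif_rates = motif_rates or {}
    for motif in motif_rates:
        if set(motif) - set("ACGTN"):
            raise ConfigError(f"motif {motif!r} has characters outside ACGTN")
        if motif_rates[motif] < 0:
            raise ConfigError("motif rates must be non-negative")
    sequences: dict[str, str] = {}
    planted: dict[str, dict[str, np.ndarray]] = {}
    intensity_out: dict[str, np.ndarray] = {}
    for chrom, length in chrom_lengths_bp.items():
        gc = np.asarray(bin_gc_targets[chrom], dtype=float)
        if np.any((gc < 0) | (gc > 1)):
            raise ConfigError("GC targets must be in [0, 1]")
        n_bins = int(np.ceil(length / bin_size))
        if len(gc) != n_bins:
            raise ConfigError(
                f"{chrom}: {len(gc)} GC targets for {n_bins} bins of {bin_size} bp"
            )
        inten = (
            np.ones(n_bins)
            if latent_intensity is None
            else np.asarray(latent_intensity[chrom], dtype=float)
        )
        if len(inten) != n_bins:
            raise ConfigError(f"{chrom}: intensity length != {n_bins}")
        u = rng.random(length)
        idx = np.empty(length, dtype=np.int8)
        # per bin: C and G with prob gc/2 each, A and T with (1-gc)/2 each
        base_order = np.frombuffer(b"CGAT", dtype="S1")
        for b in range(n_bins):
            lo, hi = b * bin_size, min((b + 1) * bin_size, length)
            cuts = np.array([gc[b] / 2, gc[b], gc[b] + (1 - gc[b]) / 2])
            idx[lo:hi] = np.searchsorted(cuts, u[lo:hi], side="right")
        seq = base_order[idx]
        planted[chrom] = {}
        for motif, rate in motif_rates.items():
            counts = rng.poisson(rate * inten)
            planted[chrom][motif] = counts
            m = len(motif)
            for b in range(n_bins):
                lo = b * bin_size
                hi = min((b + 1) * bin_size, length) - m
                if hi <= lo:
                    counts[b] = 0
                    continue
                for _ in range(counts[b]):
                    start = int(rng.integers(lo, hi))
                    inst = [
                        c if c != "N" else str(_BASES[rng.integers(4)], "ascii")
                        for c in motif
                    ]
                    seq[start : start + m] = np.frombuffer(
                        "".join(inst).encode(), dtype="S1"
                    )
        sequences[chrom] = seq.tobytes().decode("ascii")
        intensity_out[chrom] = inten
    return GenomeTruth(
        sequences=sequences,
        bin_size=bin_size,
        bin_gc={c: np.asarray(bin_gc_targets[c], dtype=float) for c in chrom_lengths_bp},
        planted_counts=planted,
        latent_intensity=intensity_out,
    )
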