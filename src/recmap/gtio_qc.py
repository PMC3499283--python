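"""Genotype/pedigree IO, a priori marker-order reconciliation, and QC.

Two genotype dialects are supported: PLINK-style PED/MAP (whitespace
separated, alleles as single letters, ``0 0`` missing) and a simple TSV
(one row per individual, one column per marker, calls 0/1/2/NA).  The
QC cascade mirrors standard SNP-chip practice for pedigree linkage
mapping: strict per-marker call-rate filtering, Mendelian-inheritance
checks against the pedigree, family-limited masking versus outright
removal of inconsistent markers, removal of individuals with a high
inconsistency fraction, and retention of sufficiently large full-sib
families.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    MISSING,
    ConfigError,
    GenotypeMatrix,
    MarkerMap,
    ParseError,
    Pedigree,
    MARKER_COLUMNS,
)

_ALLELES = ("A", "B")
_CODE_FROM_PAIR = {("A", "A"): 0, ("A", "B"): 1, ("B", "A"): 1, ("B", "B"): 2}


# ---------------------------------------------------------------------------
# readers / writers


def write_ped_map(gm: GenotypeMatrix, ped: Pedigree, prefix: str | Path) -> None:
    prefix = Path(prefix)
    md = gm.markers.df
    with open(prefix.with_suffix(".map"), "w") as fh:
        for _, r in md.iterrows():
            fh.write(f"{r['chrom']}\t{r['marker_id']}\t0\t{int(r['pos_bp'])}\n")
    fam_of = dict(zip(ped.df["id"], ped.df["family"]))
    meta = ped.df.set_index("id")
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for iid in gm.individuals:
            row = meta.loc[iid]
            fields = [str(fam_of[iid]), iid, row["sire"], row["dam"], str(int(row["sex"])), "-9"]
            for c in gm.genotypes_of(iid):
                if c == MISSING:
                    fields += ["0", "0"]
                else:
                    fields += ["A" if c <= 1 else "B", "B" if c >= 1 else "A"]
            fh.write(" ".join(fields) + "\n")


def write_tsv(gm: GenotypeMatrix, ped: Pedigree, prefix: str | Path) -> None:
    prefix = Path(prefix)
    codes = gm.calls.astype(object)
    codes[gm.calls == MISSING] = "NA"
    pd.DataFrame(codes, index=gm.individuals, columns=gm.markers.marker_ids).to_csv(
        Path(str(prefix) + ".geno.tsv"), sep="\t", index_label="id"
    )
    gm.markers.df[MARKER_COLUMNS].to_csv(
        Path(str(prefix) + ".markers.tsv"), sep="\t", index=False
    )
    write_pedigree_tsv(ped, Path(str(prefix) + ".ped.tsv"))


def write_pedigree_tsv(ped: Pedigree, path: str | Path) -> None:
    ped.df[["id", "sire", "dam", "sex", "family"]].to_csv(path, sep="\t", index=False)


def read_pedigree_tsv(path: str | Path) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "sire": str, "dam": str})
    return Pedigree(df)


def read_genotypes(
    prefix: str | Path, dialect: str = "ped_map"
) -> tuple[GenotypeMatrix, MarkerMap, Pedigree]:
    """Read a genotype set written by :func:`write_ped_map` / :func:`write_tsv`.

    ``prefix`` is the path without extension; ``dialect`` is ``ped_map``
    (``<prefix>.ped`` + ``<prefix>.map``) or ``tsv`` (``<prefix>.geno.tsv``
    + ``<prefix>.markers.tsv`` + ``<prefix>.ped.tsv``).
    """
    if dialect == "ped_map":
        return _read_ped_map(Path(prefix))
    if dialect == "tsv":
        return _read_tsv(Path(prefix))
    raise ConfigError(f"unknown dialect {dialect!r}")


def _read_ped_map(prefix: Path):
    rows = []
    seen = set()
    with open(prefix.with_suffix(".map")) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(f"{prefix}.map line {ln}: expected 4 fields")
            chrom, mid, _, bp = parts
            if mid in seen:
                raise ParseError(f"{prefix}.map line {ln}: duplicated marker id {mid!r}")
            seen.add(mid)
            rows.append((mid, chrom, int(bp), len(rows), "both"))
    mdf = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    # order_index restarts per chromosome
    mdf["order_index"] = mdf.groupby("chrom", sort=False).cumcount()
    markers = MarkerMap(mdf)
    n_mark = markers.n_markers

    ids, ped_rows, calls = [], [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6 + 2 * n_mark:
                raise ParseError(
                    f"{prefix}.ped line {ln}: expected {6 + 2 * n_mark} fields, got {len(parts)}"
                )
            fam, iid, sire, dam, sex = parts[:5]
            ped_rows.append((iid, sire, dam, int(sex), fam))
            ids.append(iid)
            row = np.empty(n_mark, dtype=np.int8)
            al = parts[6:]
            for m in range(n_mark):
                a, b = al[2 * m], al[2 * m + 1]
                if a == "0" or b == "0":
                    row[m] = MISSING
                else:
                    try:
                        row[m] = _CODE_FROM_PAIR[(a, b)]
                    except KeyError:
                        raise ParseError(
                            f"{prefix}.ped line {ln}: unknown allele code {a!r}/{b!r}"
                        ) from None
            calls.append(row)
    ped = Pedigree(pd.DataFrame(ped_rows, columns=["id", "sire", "dam", "sex", "family"]))
    return GenotypeMatrix(ids, markers, np.array(calls)), markers, ped


def _read_tsv(prefix: Path):
    mdf = pd.read_csv(Path(str(prefix) + ".markers.tsv"), sep="\t")
    markers = MarkerMap(mdf)
    g = pd.read_csv(
        Path(str(prefix) + ".geno.tsv"),
        sep="\t",
        index_col="id",
        dtype=str,
        keep_default_na=False,  # "NA" is a literal missing-call token
    )
    if list(g.columns) != markers.marker_ids:
        raise ParseError(f"{prefix}.geno.tsv columns do not match marker file order")
    calls = np.full(g.shape, MISSING, dtype=np.int8)
    vals = g.to_numpy()
    for code in ("0", "1", "2"):
        calls[vals == code] = int(code)
    bad = ~np.isin(vals, ["0", "1", "2", "NA"])
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"{prefix}.geno.tsv row {i + 2}: unknown call {vals[i, j]!r} at {g.columns[j]}"
        )
    ped = read_pedigree_tsv(Path(str(prefix) + ".ped.tsv"))
    return GenotypeMatrix([str(i) for i in g.index], markers, calls), markers, ped


def write_config_yaml(config, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)


def read_config_yaml(path: str | Path, cls):
    with open(path) as fh:
        return cls(**yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# a priori order reconciliation


def reconcile_orders(rh: MarkerMap, asm: MarkerMap) -> tuple[MarkerMap, list[str]]:
    """Merge an RH (radiation hybrid) marker order with a sequence-assembly
    order.  The RH order is the basic order; assembly-only markers are
    inserted between their two nearest shared flanking markers when those
    flanks agree in relative order (and adjacency) between the inputs.
    Markers in disagreeing neighbourhoods, or with conflicting chromosome
    assignments, are excluded and reported.
    """
    excluded: list[str] = []
    rh_chrom = dict(zip(rh.df["marker_id"], rh.df["chrom"]))
    out_rows = []
    for chrom in rh.chromosomes():
        rh_sub = rh.df[rh.df["chrom"] == chrom].sort_values("order_index")
        asm_sub = asm.df[asm.df["chrom"] == chrom].sort_values("order_index")
        rh_ids = rh_sub["marker_id"].tolist()
        asm_ids = asm_sub["marker_id"].tolist()
        asm_pos = dict(zip(asm_sub["marker_id"], asm_sub["pos_bp"]))
        shared = [m for m in asm_ids if m in set(rh_ids)]
        # chromosome-conflicting assembly markers
        conflicts = {
            m for m in asm_ids if m in rh_chrom and rh_chrom[m] != chrom
        }
        excluded.extend(sorted(conflicts))
        rh_rank = {m: i for i, m in enumerate(rh_ids)}
        shared_rank_rh = {m: i for i, m in enumerate(m for m in rh_ids if m in set(shared))}
        inserts: dict[str, list[str]] = {m: [] for m in rh_ids}
        for m in asm_ids:
            if m in rh_rank or m in conflicts:
                continue
            k = asm_ids.index(m)
            left = next((x for x in reversed(asm_ids[:k]) if x in shared_rank_rh), None)
            right = next((x for x in asm_ids[k + 1 :] if x in shared_rank_rh), None)
            if left is None or right is None:
                excluded.append(m)
                continue
            # consistent neighbourhood: flanks in the same relative order and
            # adjacent among shared markers in the RH order
            if shared_rank_rh[right] - shared_rank_rh[left] != 1:
                excluded.append(m)
                continue
            inserts[left].append(m)
        for m in rh_ids:
            rh_row = rh_sub[rh_sub["marker_id"] == m].iloc[0]
            pos = asm_pos.get(m, rh_row["pos_bp"])
            src = "both" if m in asm_pos else "rh"
            out_rows.append((m, chrom, int(pos), None, src))
            for ins in inserts[m]:
                out_rows.append((ins, chrom, int(asm_pos[ins]), None, "assembly"))
    df = pd.DataFrame(out_rows, columns=MARKER_COLUMNS)
    df["order_index"] = df.groupby("chrom", sort=False).cumcount()
    return MarkerMap(df), excluded


# ---------------------------------------------------------------------------
# QC cascade


@dataclass
class QcReport:
    markers_dropped_callrate: int = 0
    markers_dropped_mendel: int = 0
    genotypes_set_missing: int = 0
    individuals_removed: int = 0
    families_retained: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(self)])


def filter_call_rate(
    gm: GenotypeMatrix, threshold: float = 0.97
) -> tuple[GenotypeMatrix, list[str]]:
    """Retain markers whose call rate is strictly higher than ``threshold``."""
    if not 0.0 <= threshold <= 1.0:
        raise ConfigError("call-rate threshold must be in [0, 1]")
    rate = gm.call_rate()
    keep = np.flatnonzero(rate > threshold)
    dropped = [gm.markers.marker_ids[i] for i in np.flatnonzero(rate <= threshold)]
    return gm.subset_markers(keep), dropped


def _mendel_table() -> np.ndarray:
    """consistent[sire+1, dam+1, child+1] over codes {-1,0,1,2}.

    A child call is consistent iff some choice of one transmitted allele
    per available parent can produce it; a missing parent places no
    constraint, a missing child is always consistent.
    """
    alleles = {MISSING: (0, 1), 0: (0,), 1: (0, 1), 2: (1,)}
    table = np.zeros((4, 4, 4), dtype=bool)
    for s in (-1, 0, 1, 2):
        for d in (-1, 0, 1, 2):
            for c in (-1, 0, 1, 2):
                if c == MISSING:
                    ok = True
                else:
                    ok = any(
                        a + b == c for a in alleles[s] for b in alleles[d]
                    )
                table[s + 1, d + 1, c + 1] = ok
    return table


_MENDEL_OK = _mendel_table()


def check_mendelian(
    gm: GenotypeMatrix, ped: Pedigree
) -> list[tuple[str, str, str]]:
    """All (marker_id, family_id, individual_id) trio inconsistencies.

    A call is inconsistent iff no assignment of transmitted alleles from
    the available parents can produce it; a missing parent simply drops
    that constraint.
    """
    out = []
    mids = gm.markers.marker_ids
    ids_in_gm = set(gm.individuals)
    for fam in ped.families(min_offspring=1):
        sire_g = (
            gm.genotypes_of(fam.sire) if fam.sire in ids_in_gm
            else np.full(len(mids), MISSING, dtype=np.int8)
        )
        dam_g = (
            gm.genotypes_of(fam.dam) if fam.dam in ids_in_gm
            else np.full(len(mids), MISSING, dtype=np.int8)
        )
        for child in fam.offspring:
            if child not in ids_in_gm:
                continue
            ok = _MENDEL_OK[sire_g + 1, dam_g + 1, gm.genotypes_of(child) + 1]
            for j in np.flatnonzero(~ok):
                out.append((mids[j], fam.family_id, child))
    return out


def apply_qc_policy(
    gm: GenotypeMatrix,
    ped: Pedigree,
    inconsistencies: list[tuple[str, str, str]],
    marker_family_limit: int = 1,
    individual_error_limit: float = 0.05,
) -> tuple[GenotypeMatrix, Pedigree, QcReport]:
    """Resolve Mendelian inconsistencies.

    Markers inconsistent in more than ``marker_family_limit`` families are
    dropped outright; otherwise the marker is set missing within each
    affected family.  Individuals whose inconsistency fraction (over their
    called genotypes) exceeds ``individual_error_limit`` are removed.
    """
    report = QcReport()
    gm = gm.copy()
    mid_col = {m: j for j, m in enumerate(gm.markers.marker_ids)}
    fam_members: dict[str, list[str]] = {}
    for fam in ped.families(min_offspring=1):
        fam_members.setdefault(fam.family_id, [])
        fam_members[fam.family_id].extend([fam.sire, fam.dam] + fam.offspring)

    by_marker: dict[str, set[str]] = {}
    by_indiv: dict[str, int] = {}
    for mid, fam_id, iid in inconsistencies:
        by_marker.setdefault(mid, set()).add(fam_id)
        by_indiv[iid] = by_indiv.get(iid, 0) + 1

    n_called = (gm.calls != MISSING).sum(axis=1)
    drop_ids = {
        iid
        for iid, n in by_indiv.items()
        if n_called[gm.row(iid)] > 0
        and n / n_called[gm.row(iid)] > individual_error_limit
    }

    drop_marker_cols = []
    for mid, fams in by_marker.items():
        j = mid_col.get(mid)
        if j is None:
            continue
        if len(fams) > marker_family_limit:
            drop_marker_cols.append(j)
        else:
            for fam_id in fams:
                for iid in fam_members.get(fam_id, []):
                    if iid in gm._row and gm.calls[gm.row(iid), j] != MISSING:
                        gm.calls[gm.row(iid), j] = MISSING
                        report.genotypes_set_missing += 1
    if drop_marker_cols:
        keep = np.setdiff1d(np.arange(gm.markers.n_markers), drop_marker_cols)
        gm = gm.subset_markers(keep)
        report.markers_dropped_mendel = len(drop_marker_cols)

    if drop_ids:
        keep_ids = [i for i in gm.individuals if i not in drop_ids]
        gm = gm.subset_individuals(keep_ids)
        ped = ped.subset(keep_ids)
        report.individuals_removed = len(drop_ids)
    report.families_retained = len(ped.families(min_offspring=2))
    return gm, ped, report


def select_families(ped: Pedigree, min_fullsibs: int = 5) -> Pedigree:
    """Retain nuclear families with at least ``min_fullsibs`` full-sib
    offspring (the default keeps families of more than four)."""
    is_parent = set(ped.df["sire"]) | set(ped.df["dam"])
    drop = set()
    for fam in ped.families(min_offspring=1):
        if fam.n_fullsibs < min_fullsibs:
            # undersized sibships leave the analysis, but individuals who
            # are themselves parents stay so the pedigree remains linked
            drop.update(o for o in fam.offspring if o not in is_parent)
    keep = [i for i in ped.individuals if i not in drop]
    return ped.subset(keep)


def run_qc(
    gm: GenotypeMatrix,
    ped: Pedigree,
    call_rate_threshold: float = 0.97,
    marker_family_limit: int = 1,
    individual_error_limit: float = 0.05,
    min_fullsibs: int = 5,
) -> tuple[GenotypeMatrix, Pedigree, QcReport]:
    """Full QC cascade: call-rate filter, Mendelian check + policy,
    family-size selection.

    The cascade is iterated to a fixpoint: masking Mendelian errors can
    push a marker below the call-rate threshold, so a single pass is not
    idempotent.
    """
    report = QcReport()
    for _ in range(10):
        gm2, dropped = filter_call_rate(gm, call_rate_threshold)
        inconsistencies = check_mendelian(gm2, ped)
        gm2, ped2, rep = apply_qc_policy(
            gm2, ped, inconsistencies, marker_family_limit, individual_error_limit
        )
        report.markers_dropped_callrate += len(dropped)
        report.markers_dropped_mendel += rep.markers_dropped_mendel
        report.genotypes_set_missing += rep.genotypes_set_missing
        report.individuals_removed += rep.individuals_removed
        stable = (
            not dropped
            and rep.markers_dropped_mendel == 0
            and rep.genotypes_set_missing == 0
            and rep.individuals_removed == 0
        )
        gm, ped = gm2, ped2
        if stable:
            break
    ped = select_families(ped, min_fullsibs)
    gm = gm.subset_individuals(ped.individuals)
    report.families_retained = len(ped.families(min_offspring=min_fullsibs))
    return gm, ped, report
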