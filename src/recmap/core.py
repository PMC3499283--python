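"""Core containers shared across the package.

Genotypes are held as a dense ``int8`` matrix of individuals x ordered
markers with calls coded ``0`` (AA), ``1`` (AB), ``2`` (BB) and ``-1``
(missing).  Marker metadata lives in a :class:`MarkerMap`, pedigree
structure in a :class:`Pedigree`.  Physical positions are 1-based
inclusive base pairs; all bin intervals elsewhere in the package are
half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: Sex codes follow the PLINK convention.
MALE = 1
FEMALE = 2

MARKER_COLUMNS = ["marker_id", "chrom", "pos_bp", "order_index", "source"]
PED_COLUMNS = ["id", "sire", "dam", "sex", "family"]


class RecmapError(Exception):
    """Base class for errors raised by this package."""


class ParseError(RecmapError):
    """A file did not conform to the declared dialect."""


class ConfigError(RecmapError):
    """An impossible or inconsistent configuration."""


@dataclass
class MarkerMap:
    """Ordered marker metadata (the a priori physical order).

    ``df`` columns: ``marker_id``, ``chrom``, ``pos_bp``, ``order_index``,
    ``source`` (one of ``rh``, ``assembly``, ``both``, ``unplaced``).
    Rows are kept sorted by (chrom, order_index); order_index is unique
    within a chromosome.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MARKER_COLUMNS if c not in self.df.columns]
        if missing:
            raise ConfigError(f"marker map missing columns: {missing}")
        self.df = self.df.sort_values(["chrom", "order_index"], kind="stable")
        self.df = self.df.reset_index(drop=True)
        for chrom, sub in self.df.groupby("chrom", sort=False):
            if sub["order_index"].duplicated().any():
                raise ConfigError(f"duplicate order_index on chromosome {chrom}")
        if self.df["marker_id"].duplicated().any():
            dup = self.df.loc[self.df["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise ConfigError(f"duplicated marker id: {dup}")

    @property
    def n_markers(self) -> int:
        return len(self.df)

    @property
    def marker_ids(self) -> list[str]:
        return self.df["marker_id"].tolist()

    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.df["chrom"].tolist()))

    def chrom_slice(self, chrom) -> np.ndarray:
        """Column indices (into the genotype matrix) of one chromosome."""
        return np.flatnonzero((self.df["chrom"] == chrom).to_numpy())

    def subset(self, keep: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.df.iloc[keep].reset_index(drop=True))


def marker_map_from_positions(chrom_positions: dict, source: str = "both") -> MarkerMap:
    """Build a MarkerMap from ``{chrom: array of bp positions}``."""
    rows = []
    for chrom, pos in chrom_positions.items():
        pos = np.asarray(pos)
        if np.any(np.diff(pos) <= 0):
            raise ConfigError(f"positions not strictly increasing on {chrom}")
        for i, p in enumerate(pos):
            rows.append((f"{chrom}_m{i + 1}", chrom, int(p), i, source))
    return MarkerMap(pd.DataFrame(rows, columns=MARKER_COLUMNS))


@dataclass
class NuclearFamily:
    family_id: str
    sire: str
    dam: str
    offspring: list[str]

    @property
    def n_fullsibs(self) -> int:
        return len(self.offspring)


@dataclass
class Pedigree:
    """Individuals with sire/dam/sex links.

    ``df`` columns: ``id``, ``sire``, ``dam``, ``sex``, ``family`` (and
    optionally ``line`` for simulated founders).  Founders carry sire and
    dam ``"0"``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ConfigError(f"pedigree missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)
        known = set(self.df["id"]) | {"0"}
        for col in ("sire", "dam"):
            bad = self.df.loc[~self.df[col].isin(known)]
            if len(bad):
                raise ParseError(
                    f"pedigree references unknown {col} "
                    f"{bad[col].iloc[0]!r} (individual {bad['id'].iloc[0]!r})"
                )

    @property
    def individuals(self) -> list[str]:
        return self.df["id"].tolist()

    def sex_of(self, iid: str) -> int:
        return int(self.df.set_index("id").loc[iid, "sex"])

    def families(self, min_offspring: int = 2) -> list[NuclearFamily]:
        """Nuclear families: offspring grouped by (sire, dam) pairs."""
        off = self.df[(self.df["sire"] != "0") & (self.df["dam"] != "0")]
        fams = []
        for (sire, dam), sub in off.groupby(["sire", "dam"], sort=False):
            if len(sub) < min_offspring:
                continue
            fam_id = str(sub["family"].iloc[0])
            fams.append(NuclearFamily(fam_id, sire, dam, sub["id"].tolist()))
        return fams

    def subset(self, keep_ids) -> "Pedigree":
        keep = set(keep_ids)
        sub = self.df[self.df["id"].isin(keep)].copy()
        # sever links to removed parents rather than dropping ancestors
        for col in ("sire", "dam"):
            sub.loc[~sub[col].isin(keep | {"0"}), col] = "0"
        return Pedigree(sub.reset_index(drop=True))


@dataclass
class GenotypeMatrix:
    """Individuals x ordered markers, calls in {0, 1, 2, -1}."""

    individuals: list[str]
    markers: MarkerMap
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), self.markers.n_markers):
            raise ConfigError(
                f"genotype matrix shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {self.markers.n_markers} markers"
            )
        self._row = {iid: i for i, iid in enumerate(self.individuals)}

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def row(self, iid: str) -> int:
        return self._row[iid]

    def genotypes_of(self, iid: str) -> np.ndarray:
        return self.calls[self._row[iid]]

    def call_rate(self) -> np.ndarray:
        """Per-marker fraction of non-missing calls."""
        return (self.calls != MISSING).mean(axis=0)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.individuals), self.markers, self.calls.copy())

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.individuals), self.markers.subset(keep), self.calls[:, keep]
        )

    def subset_individuals(self, keep_ids) -> "GenotypeMatrix":
        keep_ids = [i for i in self.individuals if i in set(keep_ids)]
        rows = [self._row[i] for i in keep_ids]
        return GenotypeMatrix(keep_ids, self.markers, self.calls[rows])
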