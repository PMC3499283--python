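"""Crossover detection within nuclear families via IBD switches.

For each parent of a full-sib family the transmitted allele is first
deduced per offspring at informative SNPs (parent heterozygous,
transmission unambiguous: homozygous offspring, or heterozygous
offspring with the other parent homozygous).  Each offspring in turn
serves as the template and is compared to its sibs: at markers where
both transmitted alleles are deducible the pair is either identical by
descent (IBD) or not, and any switch between the two states localises a
recombination to the interval between the nearest flanking markers with
defined status.  Switches shared by a strict majority of comparisons
are assigned to the template's meiosis; switches in a minority are
assigned to the sib showing them.  Iterating over all templates and
deduplicating per meiosis by interval intersection removes the
dependence on an arbitrary template choice.

In an intercross both parents are heterozygous at most markers, so the
single-marker rules anchor the transmitted allele only at homozygous
offspring.  Detection therefore alternates with partial parental-phase
reconstruction: grandparental origins are propagated between detected
crossovers, the two parental haplotypes are rebuilt by solving the
parity system that links meioses and markers through the anchored
transmissions, and the reconstructed phase of one parent resolves the
ambiguous transmissions of the other (offspring genotype minus imputed
allele).  The detect/impute cycle repeats until the event set is
stable, which recovers crossovers whose neighbourhood carries no
directly deducible marker.

Single-marker origin islands (a grandparental-origin run of at most
``max_run`` deducible markers flanked by the opposite origin) are the
signature of genotyping errors: the offending genotypes are set missing
and detection is repeated until a fixpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    MISSING,
    GenotypeMatrix,
    MarkerMap,
    NuclearFamily,
    Pedigree,
    RecmapError,
)


@dataclass
class CrossoverEvent:
    """One recombination localised to an inter-marker interval."""

    meiosis_id: str
    offspring_id: str
    parent_id: str
    parent_sex: int
    chromosome: str
    left_index: int  # global marker column of the left flank
    right_index: int
    left_marker: str
    right_marker: str
    left_bp: int
    right_bp: int

    @property
    def midpoint_bp(self) -> float:
        return 0.5 * (self.left_bp + self.right_bp)


@dataclass
class OriginMatrix:
    """Per-meiosis grandparental origin along the marker order.

    ``matrix`` is (meioses x markers) with 0/1 for the two parental
    haplotypes (labelling is arbitrary per meiosis) and -1 unassigned.
    Origins are constant between consecutive crossovers of a meiosis;
    they are unassigned strictly inside event intervals and on
    chromosomes where the meiosis carries no deducible marker at all.
    The phase-reconstruction rate is the assigned fraction of all
    (meiosis, marker) cells.
    """

    meiosis_ids: list[str]
    offspring_ids: list[str]
    parent_id: str
    parent_sex: int
    markers: MarkerMap
    matrix: np.ndarray = field(repr=False)

    @property
    def n_assigned(self) -> int:
        return int((self.matrix != -1).sum())

    @property
    def n_cells(self) -> int:
        return int(self.matrix.size)


def phase_rate(origins) -> float:
    """Assigned fraction of (meiosis, marker) cells, pooled over one or
    several origin matrices."""
    if isinstance(origins, OriginMatrix):
        origins = [origins]
    origins = list(origins)
    total = sum(o.n_cells for o in origins)
    if total == 0:
        raise RecmapError("empty origin matrix: phase rate undefined")
    return sum(o.n_assigned for o in origins) / total


# ---------------------------------------------------------------------------
# single-marker deduction (the observable anchors)


def transmitted_alleles(
    family: NuclearFamily, parent_id: str, gm: GenotypeMatrix
) -> np.ndarray:
    """(n_offspring x n_markers) transmitted-allele matrix in {0, 1, -1}.

    Defined iff the parent is observed heterozygous and the transmitted
    allele is uniquely deducible marker-by-marker: a homozygous offspring
    received that allele; a heterozygous offspring is resolvable only when
    the other parent is called homozygous.
    """
    other_id = family.dam if parent_id == family.sire else family.sire
    ids = set(gm.individuals)
    n_mark = gm.markers.n_markers

    parent_g = (
        gm.genotypes_of(parent_id)
        if parent_id in ids
        else np.full(n_mark, MISSING, dtype=np.int8)
    )
    other_g = (
        gm.genotypes_of(other_id)
        if other_id in ids
        else np.full(n_mark, MISSING, dtype=np.int8)
    )
    informative = parent_g == 1

    T = np.full((len(family.offspring), n_mark), -1, dtype=np.int8)
    for i, off in enumerate(family.offspring):
        if off not in ids:
            continue
        g = gm.genotypes_of(off)
        row = T[i]
        row[g == 0] = 0
        row[g == 2] = 1
        het = g == 1
        row[het & (other_g == 0)] = 1  # other parent gave A, so this one gave B
        row[het & (other_g == 2)] = 0
        row[~informative] = -1
    return T


def informative_markers(
    family: NuclearFamily, parent_id: str, gm: GenotypeMatrix
) -> np.ndarray:
    """Boolean per-marker mask: parent observed heterozygous."""
    if parent_id not in set(gm.individuals):
        return np.zeros(gm.markers.n_markers, dtype=bool)
    return gm.genotypes_of(parent_id) == 1


def ibd_profile(
    template: str, sib: str, family: NuclearFamily, parent_id: str, gm: GenotypeMatrix
) -> np.ndarray:
    """Per-marker IBD status between template and sib for one parent's
    transmissions: 1 IBD, 0 non-IBD, -1 unknown."""
    if template == sib:
        raise RecmapError("template and sib must differ")
    T = transmitted_alleles(family, parent_id, gm)
    ti = family.offspring.index(template)
    si = family.offspring.index(sib)
    out = np.full(gm.markers.n_markers, -1, dtype=np.int8)
    both = (T[ti] >= 0) & (T[si] >= 0)
    out[both] = (T[ti][both] == T[si][both]).astype(np.int8)
    return out


# ---------------------------------------------------------------------------
# switch detection on a transmitted-allele matrix


def _switch_intervals(positions: np.ndarray, status: np.ndarray):
    if positions.size < 2:
        return []
    change = np.flatnonzero(status[:-1] != status[1:])
    return [(int(positions[k]), int(positions[k + 1])) for k in change]


def _detect_from_T(
    T: np.ndarray,
    markers: MarkerMap,
    offspring: list[str],
    min_support: float,
) -> dict[int, list[tuple[int, int]]]:
    """Events per offspring as (left, right) global-column intervals.

    Switch intervals are collected from every unordered sib pair,
    clustered by running intersection (overlapping switches across pairs
    localise the same event), and each cluster is attributed to the
    offspring shared by a strict majority (> min_support) of the covering
    pairs that show the switch; the attribution is repeated on the
    residual pairs so that simultaneous events in two meioses at the same
    interval are each recovered.
    """
    n_off = len(offspring)
    out: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n_off)}

    for chrom in markers.chromosomes():
        cols = markers.chrom_slice(chrom)
        Tc = T[:, cols]
        def_mask = Tc >= 0
        all_ivs = []  # (l, r, i, j) in local coordinates
        spans = {}
        for i in range(n_off):
            for j in range(i + 1, n_off):
                d = np.flatnonzero(def_mask[i] & def_mask[j])
                if d.size < 2:
                    continue
                spans[(i, j)] = (int(d[0]), int(d[-1]))
                for l, r in _switch_intervals(
                    d, (Tc[i, d] == Tc[j, d]).astype(np.int8)
                ):
                    all_ivs.append((l, r, i, j))
        if not all_ivs:
            continue
        clusters = []
        cur = None
        for l, r, i, j in sorted(all_ivs):
            if cur is not None and l < cur["r"]:
                cur["l"] = max(cur["l"], l)
                cur["r"] = min(cur["r"], r)
                cur["members"].append((i, j, l, r))
            else:
                cur = {"l": l, "r": r, "members": [(i, j, l, r)]}
                clusters.append(cur)
        for cl in clusters:
            core_l, core_r = cl["l"], cl["r"]
            covering = [
                pair
                for pair, (lo, hi) in spans.items()
                if lo <= core_l and hi >= core_r
            ]
            showing = list(cl["members"])
            while showing:
                counts = {}
                for i, j, _, _ in showing:
                    counts[i] = counts.get(i, 0) + 1
                    counts[j] = counts.get(j, 0) + 1
                x = min(
                    counts, key=lambda k: (-counts[k], offspring[k])
                )
                n_cover_x = sum(1 for pair in covering if x in pair)
                if n_cover_x == 0 or counts[x] / n_cover_x <= min_support:
                    break  # no attributable meiosis among the residual pairs
                own = [m for m in showing if x in m[:2]]
                l = max(m[2] for m in own)
                r = min(m[3] for m in own)
                if l >= r:  # discordant localisations, fall back to the core
                    l, r = core_l, core_r
                out[x].append((int(cols[l]), int(cols[r])))
                showing = [m for m in showing if x not in m[:2]]

    for oi in out:
        out[oi] = sorted(set(out[oi]))
    return out


# ---------------------------------------------------------------------------
# parental-phase reconstruction


class _ParityUF:
    """Union-find over nodes carrying a relative XOR parity."""

    def __init__(self, n: int):
        self.parent = np.arange(n)
        self.parity = np.zeros(n, dtype=np.int8)

    def find(self, x: int) -> tuple[int, int]:
        x0 = x
        p = 0
        while self.parent[x] != x:
            p ^= self.parity[x]
            x = self.parent[x]
        root = x
        x, acc = x0, p
        while self.parent[x] != x:  # path compression
            nxt = int(self.parent[x])
            nxt_par = int(self.parity[x])
            self.parent[x] = root
            self.parity[x] = acc
            acc ^= nxt_par
            x = nxt
        return root, int(p)

    def union(self, x: int, y: int, w: int) -> None:
        rx, px = self.find(x)
        ry, py = self.find(y)
        if rx == ry:
            return  # conflicting constraints (genotype errors) are ignored
        self.parent[rx] = ry
        self.parity[rx] = px ^ py ^ w


def _extended_parity(
    events: list[tuple[int, int]], span: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Origin parity over ``span`` columns, with a mask that is False
    strictly inside event intervals."""
    if events:
        rights = np.array(sorted(r for _, r in events))
        parity = (np.searchsorted(rights, span, side="right") % 2).astype(np.int8)
    else:
        parity = np.zeros(span.size, dtype=np.int8)
    ok = np.ones(span.size, dtype=bool)
    for l, r in events:
        ok &= ~((span > l) & (span < r))
    return parity, ok


def _impute_from_phase(
    T_obs: np.ndarray,
    events_by_off: dict[int, list[tuple[int, int]]],
    het_mask: np.ndarray,
    markers: MarkerMap,
) -> np.ndarray:
    """Channel-1 imputation: fill transmitted alleles at this parent's
    heterozygous markers by propagating origins between events and solving
    the marker/meiosis parity system from the observed anchors."""
    n_off, n_mark = T_obs.shape
    T_full = T_obs.copy()
    for chrom in markers.chromosomes():
        cols = markers.chrom_slice(chrom)
        m_local = {int(c): i for i, c in enumerate(cols)}
        uf = _ParityUF(len(cols) + n_off)
        parities = {}
        for oi in range(n_off):
            evs = [
                (l, r)
                for l, r in events_by_off.get(oi, [])
                if cols[0] <= l <= cols[-1]
            ]
            parity, ok = _extended_parity(evs, cols)
            parities[oi] = (parity, ok)
            anchors = np.flatnonzero((T_obs[oi, cols] >= 0) & ok)
            for a in anchors:
                w = int(T_obs[oi, cols[a]]) ^ int(parity[a])
                uf.union(int(a), len(cols) + oi, w)
        roots_m = np.empty(len(cols), dtype=np.int64)
        par_m = np.empty(len(cols), dtype=np.int8)
        for i in range(len(cols)):
            r, p = uf.find(i)
            roots_m[i], par_m[i] = r, p
        roots_o = np.full(n_off, -1, dtype=np.int64)
        par_o = np.zeros(n_off, dtype=np.int8)
        anchored = np.zeros(n_off, dtype=bool)
        for oi in range(n_off):
            if not (T_obs[oi, cols] >= 0).any():
                continue  # no anchor: phase of this meiosis is unknown here
            anchored[oi] = True
            roots_o[oi], par_o[oi] = uf.find(len(cols) + oi)

        # refine by majority vote: the union-find solution is exact on
        # conflict-free constraints, but a single bad constraint (from a
        # mislocalised event boundary) can corrupt a whole region; two
        # rounds of marker-wise / meiosis-wise majority repair that
        x_m = par_m.astype(np.int16)  # hap allele carried by parity-0
        f_o = par_o.astype(np.int16)
        valid_m = np.ones(len(cols), dtype=bool)
        anchor_lists = []
        for oi in range(n_off):
            if not anchored[oi]:
                anchor_lists.append(np.empty(0, dtype=np.int64))
                continue
            parity, ok = parities[oi]
            anchor_lists.append(np.flatnonzero((T_obs[oi, cols] >= 0) & ok))
        for _ in range(2):
            votes = np.zeros(len(cols), dtype=np.int32)
            tally = np.zeros(len(cols), dtype=np.int32)
            for oi in range(n_off):
                if not anchored[oi]:
                    continue
                a = anchor_lists[oi]
                parity, _ = parities[oi]
                t = T_obs[oi, cols[a]].astype(np.int16)
                votes[a] += (t ^ parity[a] ^ f_o[oi]).astype(np.int32)
                tally[a] += 1
            with np.errstate(invalid="ignore"):
                x_m = np.where(votes * 2 > tally, 1, 0).astype(np.int16)
            valid_m = (votes * 2 != tally) & (tally > 0)
            for oi in range(n_off):
                if not anchored[oi]:
                    continue
                a = anchor_lists[oi]
                a = a[valid_m[a]]
                if a.size == 0:
                    anchored[oi] = False
                    continue
                parity, _ = parities[oi]
                t = T_obs[oi, cols[a]].astype(np.int16)
                v = int((t ^ parity[a] ^ x_m[a]).sum())
                if 2 * v == a.size:
                    anchored[oi] = False  # phase orientation undecidable
                else:
                    f_o[oi] = 1 if 2 * v > a.size else 0

        for oi in range(n_off):
            if not anchored[oi]:
                continue
            parity, ok = parities[oi]
            # impute only within the meiosis's own anchor span: beyond the
            # outermost deducible markers the phase is unverifiable and a
            # censored edge crossover would be misattributed
            obs = np.flatnonzero(T_obs[oi, cols] >= 0)
            inside = np.zeros(len(cols), dtype=bool)
            inside[obs[0] : obs[-1] + 1] = True
            # residual gating: where this meiosis's own anchors disagree
            # with the reconstruction (a missed or mislocalised event
            # flipped the parity of a region) the phase is wrong there,
            # so nothing is imputed between disagreeing anchors
            a = anchor_lists[oi]
            a = a[valid_m[a]]
            if a.size == 0:
                continue
            resid = (
                T_obs[oi, cols[a]].astype(np.int16) ^ parity[a] ^ int(f_o[oi])
            ) != x_m[a]
            pos_idx = np.searchsorted(a, np.arange(len(cols)))
            left_ok = np.where(
                pos_idx > 0, ~resid[np.clip(pos_idx - 1, 0, a.size - 1)], True
            )
            right_ok = np.where(
                pos_idx < a.size, ~resid[np.clip(pos_idx, 0, a.size - 1)], True
            )
            fill = (
                ok
                & het_mask[cols]
                & (T_full[oi, cols] < 0)
                & valid_m
                & inside
                & left_ok
                & right_ok
            )
            idx = np.flatnonzero(fill)
            T_full[oi, cols[idx]] = (
                (x_m[idx] ^ int(f_o[oi]) ^ parity[idx]).astype(np.int8)
            )
    return T_full


# ---------------------------------------------------------------------------
# family-level joint detection


def _complement_trust(
    G: np.ndarray, full_q: np.ndarray, markers: MarkerMap
) -> np.ndarray:
    """Where the reconstructed phase of parent q can be trusted for
    complementation.

    A homozygous offspring genotype pins q's transmitted allele, so such
    markers act as checkpoints on the reconstructed phase: wherever the
    nearest flanking checkpoint disagrees with the reconstruction (a
    mislocalised or missed event flipped a whole region), imputation
    through q is suppressed there rather than propagated into the other
    parent as spurious switches.
    """
    n_off, n_mark = G.shape
    trust = np.zeros((n_off, n_mark), dtype=bool)
    hom = (G == 0) | (G == 2)
    expected = (G == 2).astype(np.int8)
    for chrom in markers.chromosomes():
        cols = markers.chrom_slice(chrom)
        for oi in range(n_off):
            cp = np.flatnonzero(hom[oi, cols] & (full_q[oi, cols] >= 0))
            if cp.size == 0:
                continue
            agree = full_q[oi, cols[cp]] == expected[oi, cols[cp]]
            idx = np.searchsorted(cp, np.arange(len(cols)))
            left_ok = np.where(idx > 0, agree[np.clip(idx - 1, 0, cp.size - 1)], True)
            right_ok = np.where(
                idx < cp.size, agree[np.clip(idx, 0, cp.size - 1)], True
            )
            trust[oi, cols] = left_ok & right_ok
    return trust


def detect_family(
    family: NuclearFamily,
    gm: GenotypeMatrix,
    parent_sexes: dict[str, int],
    min_support: float = 0.5,
    max_iter: int = 6,
):
    """Joint iterative detection for both parents of one family.

    Returns ``(events_by_parent, origin_by_parent, T_final_by_parent)``
    where events are (offspring index, left, right) interval dicts.
    """
    markers = gm.markers
    parents = (family.sire, family.dam)
    ids = set(gm.individuals)
    G = np.full((len(family.offspring), markers.n_markers), MISSING, dtype=np.int8)
    for i, off in enumerate(family.offspring):
        if off in ids:
            G[i] = gm.genotypes_of(off)
    T_obs = {p: transmitted_alleles(family, p, gm) for p in parents}
    het = {p: informative_markers(family, p, gm) for p in parents}
    T = {p: T_obs[p].copy() for p in parents}

    events = {
        p: _detect_from_T(T[p], markers, family.offspring, min_support)
        for p in parents
    }
    prev = None
    for _ in range(max_iter):
        # cross-impute sequentially: the freshly reconstructed phase of one
        # parent resolves the heterozygous-offspring ambiguity of the other
        for p, q in ((parents[0], parents[1]), (parents[1], parents[0])):
            full_q = _impute_from_phase(T_obs[q], events[q], het[q], markers)
            trust = _complement_trust(G, full_q, markers)
            Tn = T_obs[p].copy()
            cand = (Tn < 0) & het[p][None, :] & (G == 1) & (full_q >= 0) & trust
            comp = 1 - full_q
            Tn[cand] = comp[cand]
            T[p] = Tn
            events[p] = _detect_from_T(T[p], markers, family.offspring, min_support)
        key = tuple(
            sorted((p, oi, tuple(iv)) for p in parents for oi, iv in events[p].items())
        )
        if key == prev:
            break
        prev = key
    for p, q in ((parents[0], parents[1]), (parents[1], parents[0])):
        events[p] = _drop_unanchored_pairs(events[p], T_obs[p], T_obs[q], markers)
    return events, T, T_obs


def _drop_unanchored_pairs(
    events_by_off: dict[int, list[tuple[int, int]]],
    T_obs: np.ndarray,
    T_obs_other: np.ndarray,
    markers: MarkerMap,
) -> dict[int, list[tuple[int, int]]]:
    """Remove event pairs whose intervening segment carries no directly
    deducible marker for either parent.

    A close double crossover whose middle segment anchors neither parent
    can be claimed by both through cross-parent imputation; with no
    observed marker in the segment the attribution is unverifiable, so
    the pair is censored.  When the other parent does anchor the segment
    (and stayed constant there, or it would have claimed the switches),
    this parent's attribution is genotype-backed and the pair is kept.
    """
    chrom_of = markers.df["chrom"].to_numpy()
    out = {}
    for oi, ivs in events_by_off.items():
        ivs = sorted(ivs)
        changed = True
        while changed:
            changed = False
            for k in range(len(ivs) - 1):
                (l1, r1), (l2, r2) = ivs[k], ivs[k + 1]
                if chrom_of[r1] != chrom_of[l2]:
                    continue
                span = np.arange(r1, l2 + 1)
                anchored = (T_obs[oi, span] >= 0).any() or (
                    T_obs_other[oi, span] >= 0
                ).any()
                if not anchored:
                    del ivs[k + 1]
                    del ivs[k]
                    changed = True
                    break
        out[oi] = ivs
    return out


def _events_to_objects(
    family: NuclearFamily,
    parent_id: str,
    parent_sex: int,
    events_by_off: dict[int, list[tuple[int, int]]],
    markers: MarkerMap,
) -> list[CrossoverEvent]:
    md = markers.df
    pos = md["pos_bp"].to_numpy()
    mids = md["marker_id"].to_numpy()
    chrom_of = md["chrom"].to_numpy()
    out = []
    for oi, ivs in events_by_off.items():
        off = family.offspring[oi]
        for l, r in ivs:
            out.append(
                CrossoverEvent(
                    meiosis_id=f"{off}:{parent_id}",
                    offspring_id=off,
                    parent_id=parent_id,
                    parent_sex=parent_sex,
                    chromosome=str(chrom_of[l]),
                    left_index=l,
                    right_index=r,
                    left_marker=str(mids[l]),
                    right_marker=str(mids[r]),
                    left_bp=int(pos[l]),
                    right_bp=int(pos[r]),
                )
            )
    return out


def _build_origin(
    family: NuclearFamily,
    parent_id: str,
    parent_sex: int,
    T_final: np.ndarray,
    events_by_off: dict[int, list[tuple[int, int]]],
    markers: MarkerMap,
) -> OriginMatrix:
    n_off = len(family.offspring)
    matrix = np.full((n_off, markers.n_markers), -1, dtype=np.int8)
    for chrom in markers.chromosomes():
        cols = markers.chrom_slice(chrom)
        for oi in range(n_off):
            if not (T_final[oi, cols] >= 0).any():
                continue
            evs = [
                (l, r)
                for l, r in events_by_off.get(oi, [])
                if cols[0] <= l <= cols[-1]
            ]
            parity, ok = _extended_parity(evs, cols)
            matrix[oi, cols[ok]] = parity[ok]
    return OriginMatrix(
        meiosis_ids=[f"{o}:{parent_id}" for o in family.offspring],
        offspring_ids=list(family.offspring),
        parent_id=parent_id,
        parent_sex=parent_sex,
        markers=markers,
        matrix=matrix,
    )


def detect_crossovers(
    family: NuclearFamily,
    parent_id: str,
    parent_sex: int,
    gm: GenotypeMatrix,
    min_support: float = 0.5,
) -> tuple[list[CrossoverEvent], OriginMatrix]:
    """Detect crossovers in every meiosis of ``parent_id`` into this family
    (runs the joint family inference and returns one parent's share)."""
    other_sex = 3 - parent_sex
    other = family.dam if parent_id == family.sire else family.sire
    events, T, _ = detect_family(
        family, gm, {parent_id: parent_sex, other: other_sex}, min_support
    )
    ev = _events_to_objects(family, parent_id, parent_sex, events[parent_id], gm.markers)
    origin = _build_origin(
        family, parent_id, parent_sex, T[parent_id], events[parent_id], gm.markers
    )
    return ev, origin


def find_origin_islands(
    events_by_off: dict[int, list[tuple[int, int]]],
    T_obs: np.ndarray,
    markers: MarkerMap,
    max_run: int = 1,
) -> list[tuple[int, np.ndarray]]:
    """(offspring index, anchor columns) for every origin run of at most
    ``max_run`` observed deducible markers bracketed by an event pair of
    the same meiosis — the double-recombinant signature."""
    chrom_of = markers.df["chrom"].to_numpy()
    islands = []
    for oi, ivs in events_by_off.items():
        ivs = sorted(ivs)
        for (l1, r1), (l2, r2) in zip(ivs, ivs[1:]):
            if chrom_of[r1] != chrom_of[l2]:
                continue
            span = np.arange(r1, l2 + 1)
            anchors = span[T_obs[oi, span] >= 0]
            if 0 < anchors.size <= max_run:
                islands.append((oi, anchors))
    return islands


def detect_and_clean(
    family: NuclearFamily,
    gm: GenotypeMatrix,
    parent_sexes: dict[str, int],
    min_support: float = 0.5,
    max_run: int = 1,
    max_rounds: int = 10,
):
    """Family detection with double-recombinant repair to a fixpoint.

    Offending genotypes are set missing (on a copy of the matrix) and
    detection is re-run.  Returns (events list, origin list, repaired
    matrix, masked (offspring, marker) pairs).
    """
    gm = gm.copy()
    masked: list[tuple[str, str]] = []
    mids = gm.markers.df["marker_id"].to_numpy()
    for _ in range(max_rounds):
        events, T, T_obs = detect_family(family, gm, parent_sexes, min_support)
        progress = False
        for p in (family.sire, family.dam):
            for oi, anchors in find_origin_islands(
                events[p], T_obs[p], gm.markers, max_run
            ):
                off = family.offspring[oi]
                row = gm.row(off)
                for a in anchors:
                    if gm.calls[row, a] != MISSING:
                        gm.calls[row, a] = MISSING
                        masked.append((off, str(mids[a])))
                        progress = True
        if not progress:
            break
    ev_objects = []
    origins = []
    for p in (family.sire, family.dam):
        ev_objects.extend(
            _events_to_objects(family, p, parent_sexes[p], events[p], gm.markers)
        )
        origins.append(
            _build_origin(family, p, parent_sexes[p], T[p], events[p], gm.markers)
        )
    return ev_objects, origins, gm, masked


#: Double-recombinant repair entry point: detect with masking of
#: single-marker origin islands to a fixpoint (see :func:`detect_and_clean`).
filter_double_recombinants = detect_and_clean


def detect_all(
    gm: GenotypeMatrix,
    ped: Pedigree,
    min_support: float = 0.5,
    max_run: int = 1,
    repair: bool = True,
) -> tuple[list[CrossoverEvent], list[OriginMatrix], GenotypeMatrix]:
    """Run detection for every nuclear family with at least two offspring;
    returns pooled events, all origin matrices and the (possibly repaired)
    genotype matrix."""
    gm_out = gm.copy()
    sex = dict(zip(ped.df["id"], ped.df["sex"].astype(int)))
    all_events: list[CrossoverEvent] = []
    all_origins: list[OriginMatrix] = []
    for fam in ped.families(min_offspring=2):
        sexes = {fam.sire: sex.get(fam.sire, 1), fam.dam: sex.get(fam.dam, 2)}
        if repair:
            ev, og, gm_fam, _ = detect_and_clean(fam, gm_out, sexes, min_support, max_run)
            # carry the per-family repairs into the shared matrix
            rows = [gm_out.row(o) for o in fam.offspring if o in set(gm_out.individuals)]
            gm_out.calls[rows] = gm_fam.calls[rows]
        else:
            ev, og = [], []
            for p in (fam.sire, fam.dam):
                e, o = detect_crossovers(fam, p, sexes[p], gm_out, min_support)
                ev.extend(e)
                og.append(o)
        all_events.extend(ev)
        all_origins.extend(og)
    return all_events, all_origins, gm_out


def write_events_tsv(events: list[CrossoverEvent], path) -> None:
    import pandas as pd

    rows = [
        (
            e.meiosis_id,
            e.parent_id,
            e.parent_sex,
            e.chromosome,
            e.left_marker,
            e.right_marker,
            e.left_bp,
            e.right_bp,
        )
        for e in events
    ]
    pd.DataFrame(
        rows,
        columns=[
            "meiosis_id",
            "parent_id",
            "parent_sex",
            "chrom",
            "left_marker",
            "right_marker",
            "left_bp",
            "right_bp",
        ],
    ).to_csv(path, sep="\t", index=False)
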