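"""IO round-trips, marker-order reconciliation and the QC cascade."""

import itertools

import numpy as np
import pandas as pd
import pytest

from recmap import gtio_qc, pedsim, pipeline
from recmap.core import (
    MISSING,
    GenotypeMatrix,
    MarkerMap,
    ParseError,
    Pedigree,
    MARKER_COLUMNS,
)


def _mini_gm():
    markers = MarkerMap(
        pd.DataFrame(
            [(f"m{i}", "chr1", 1000 * (i + 1), i, "both") for i in range(4)],
            columns=MARKER_COLUMNS,
        )
    )
    ped = Pedigree(
        pd.DataFrame(
            [
                ("s", "0", "0", 1, "f1"),
                ("d", "0", "0", 2, "f1"),
                ("o1", "s", "d", 1, "f1"),
                ("o2", "s", "d", 2, "f1"),
            ],
            columns=["id", "sire", "dam", "sex", "family"],
        )
    )
    calls = np.array(
        [[1, 1, 0, 2], [1, 0, 1, 2], [0, 1, MISSING, 2], [2, 0, 1, 2]], dtype=np.int8
    )
    return GenotypeMatrix(["s", "d", "o1", "o2"], markers, calls), ped


@pytest.mark.parametrize("dialect", ["ped_map", "tsv"])
def test_round_trip_lossless(tmp_path, dialect, small_dataset):
    gm, ped = small_dataset["gm"], small_dataset["ped"]
    prefix = tmp_path / "ds"
    if dialect == "ped_map":
        gtio_qc.write_ped_map(gm, ped, prefix)
    else:
        gtio_qc.write_tsv(gm, ped, prefix)
    gm2, markers2, ped2 = gtio_qc.read_genotypes(prefix, dialect)
    assert gm2.individuals == gm.individuals
    assert markers2.marker_ids == gm.markers.marker_ids
    assert np.array_equal(gm2.calls, gm.calls)
    assert len(ped2.families(min_offspring=2)) == len(ped.families(min_offspring=2))


def test_ped_zero_zero_is_missing(tmp_path):
    gm, ped = _mini_gm()
    gtio_qc.write_ped_map(gm, ped, tmp_path / "x")
    content = (tmp_path / "x.ped").read_text()
    assert " 0 0" in content  # o1's missing call
    gm2, _, _ = gtio_qc.read_genotypes(tmp_path / "x", "ped_map")
    assert gm2.calls[2, 2] == MISSING


def test_unknown_allele_code_names_line(tmp_path):
    gm, ped = _mini_gm()
    gtio_qc.write_ped_map(gm, ped, tmp_path / "x")
    lines = (tmp_path / "x.ped").read_text().splitlines()
    lines[1] = lines[1].replace(" A ", " Z ", 1)
    (tmp_path / "x.ped").write_text("\n".join(lines) + "\n")
    with pytest.raises(ParseError, match="line 2"):
        gtio_qc.read_genotypes(tmp_path / "x", "ped_map")


def test_duplicate_marker_id_rejected(tmp_path):
    (tmp_path / "y.map").write_text("chr1\tm1\t0\t100\nchr1\tm1\t0\t200\n")
    (tmp_path / "y.ped").write_text("")
    with pytest.raises(ParseError, match="duplicated marker"):
        gtio_qc.read_genotypes(tmp_path / "y", "ped_map")


def test_pedigree_unknown_parent_rejected():
    with pytest.raises(ParseError, match="unknown"):
        Pedigree(
            pd.DataFrame(
                [("a", "ghost", "0", 1, "f1")],
                columns=["id", "sire", "dam", "sex", "family"],
            )
        )


# ---------------------------------------------------------------------------
# order reconciliation


def _map_from(order, chrom="chr1", pos=None):
    pos = pos or {m: 1000 * (i + 1) for i, m in enumerate(order)}
    return MarkerMap(
        pd.DataFrame(
            [(m, chrom, pos[m], i, "both") for i, m in enumerate(order)],
            columns=MARKER_COLUMNS,
        )
    )


def _is_linear_extension(merged, base):
    """Brute-force oracle: base markers appear in the merged order in
    their base order."""
    idx = {m: i for i, m in enumerate(merged)}
    present = [m for m in base if m in idx]
    return all(idx[a] < idx[b] for a, b in zip(present, present[1:]))


class TestReconcileOrders:
    def test_identity(self):
        rh = _map_from(["m1", "m2", "m3"])
        out, excluded = gtio_qc.reconcile_orders(rh, _map_from(["m1", "m2", "m3"]))
        assert out.marker_ids == ["m1", "m2", "m3"]
        assert excluded == []

    def test_consistent_insertion(self):
        rh = _map_from(["m1", "m2", "m4"])
        asm = _map_from(["m1", "m2", "m3", "m4"])
        out, excluded = gtio_qc.reconcile_orders(rh, asm)
        assert out.marker_ids == ["m1", "m2", "m3", "m4"]
        assert excluded == []
        assert _is_linear_extension(out.marker_ids, rh.marker_ids)
        assert _is_linear_extension(out.marker_ids, asm.marker_ids)

    def test_inverted_neighbourhood_suppresses_insertion(self):
        rh = _map_from(["m1", "m2", "m4"])
        asm = _map_from(["m2", "m3", "m1", "m4"])  # m1/m2 inverted vs RH
        out, excluded = gtio_qc.reconcile_orders(rh, asm)
        assert out.marker_ids == ["m1", "m2", "m4"]  # RH order kept
        assert "m3" in excluded
        assert _is_linear_extension(out.marker_ids, rh.marker_ids)

    def test_chromosome_conflict_excluded(self):
        rh = _map_from(["m1", "m2", "m3"])
        asm_df = _map_from(["m1", "m2", "mx", "m3"]).df
        asm_df.loc[asm_df["marker_id"] == "m2", "chrom"] = "chr2"
        out, excluded = gtio_qc.reconcile_orders(rh, MarkerMap(asm_df))
        assert "m2" in out.marker_ids  # RH is the basic order
        assert _is_linear_extension(out.marker_ids, rh.marker_ids)


# ---------------------------------------------------------------------------
# QC cascade


class TestCallRateFilter:
    def test_strict_inequality_at_threshold(self):
        # 96/100 dropped, 98/100 retained at threshold 0.97
        markers = _map_from([f"m{i}" for i in range(2)])
        calls = np.ones((100, 2), dtype=np.int8)
        calls[:4, 0] = MISSING
        calls[:2, 1] = MISSING
        gm = GenotypeMatrix([f"i{k}" for k in range(100)], markers, calls)
        out, dropped = gtio_qc.filter_call_rate(gm, 0.97)
        assert dropped == ["m0"]
        assert out.markers.marker_ids == ["m1"]

    def test_exactly_at_threshold_dropped(self):
        markers = _map_from(["m0"])
        calls = np.ones((100, 1), dtype=np.int8)
        calls[:3, 0] = MISSING  # call rate exactly 0.97
        gm = GenotypeMatrix([f"i{k}" for k in range(100)], markers, calls)
        _, dropped = gtio_qc.filter_call_rate(gm, 0.97)
        assert dropped == ["m0"]

    def test_dropped_set_matches_brute_recount(self, small_dataset):
        gm = pedsim.inject_errors(small_dataset["gm"], 0.0, 0.05, seed=9)
        _, dropped = gtio_qc.filter_call_rate(gm, 0.97)
        expected = [
            gm.markers.marker_ids[j]
            for j in range(gm.markers.n_markers)
            if (gm.calls[:, j] != MISSING).sum() / gm.n_individuals <= 0.97
        ]
        assert dropped == expected

    def test_monotone_in_threshold(self, small_dataset):
        gm = pedsim.inject_errors(small_dataset["gm"], 0.0, 0.05, seed=9)
        kept = [
            gtio_qc.filter_call_rate(gm, t)[0].markers.n_markers
            for t in (0.90, 0.95, 0.97, 0.99)
        ]
        assert kept == sorted(kept, reverse=True)


class TestMendelianChecker:
    def test_matches_trio_enumeration(self):
        """All 27 two-parent trio genotype combinations against the
        brute-force transmission oracle."""
        markers = _map_from(["m0"])
        alleles = {0: (0,), 1: (0, 1), 2: (1,)}
        for s, d, c in itertools.product((0, 1, 2), repeat=3):
            gm = GenotypeMatrix(
                ["s", "d", "o"],
                markers,
                np.array([[s], [d], [c]], dtype=np.int8),
            )
            ped = Pedigree(
                pd.DataFrame(
                    [("s", "0", "0", 1, "f"), ("d", "0", "0", 2, "f"),
                     ("o", "s", "d", 1, "f")],
                    columns=["id", "sire", "dam", "sex", "family"],
                )
            )
            expected_ok = any(
                a + b == c for a in alleles[s] for b in alleles[d]
            )
            found = gtio_qc.check_mendelian(gm, ped)
            assert (found == []) == expected_ok, (s, d, c)

    def test_single_parent_missing_relaxes_constraint(self):
        markers = _map_from(["m0"])
        # sire AA, dam missing, child BB: impossible (sire must give A)
        gm = GenotypeMatrix(
            ["s", "d", "o"], markers, np.array([[0], [MISSING], [2]], dtype=np.int8)
        )
        ped = Pedigree(
            pd.DataFrame(
                [("s", "0", "0", 1, "f"), ("d", "0", "0", 2, "f"),
                 ("o", "s", "d", 1, "f")],
                columns=["id", "sire", "dam", "sex", "family"],
            )
        )
        assert len(gtio_qc.check_mendelian(gm, ped)) == 1
        gm.calls[2, 0] = 1  # child AB is fine: A from sire, B from dam
        assert gtio_qc.check_mendelian(gm, ped) == []

    def test_planted_flips_found_on_families(self, small_dataset):
        gm, ped = small_dataset["gm"], small_dataset["ped"]
        assert gtio_qc.check_mendelian(gm, ped) == []


class TestQcPolicy:
    def _three_family_setup(self):
        cfg = pedsim.SimConfig(
            chrom_lengths_bp=[10_000_000],
            n_markers_per_chrom=40,
            male_map_cM=[0.0],
            female_map_cM=[0.0],
            n_families=3,
            offspring_per_family=6,
            seed=21,
        )
        ped, markers, gm, _ = pipeline.simulate_dataset(cfg)
        return gm, ped

    def test_single_family_marker_masked_not_dropped(self):
        gm, ped = self._three_family_setup()
        inc = [("chr1_m5", "fam1", "fam1_F2_1")]
        out, _, report = gtio_qc.apply_qc_policy(gm, ped, inc, marker_family_limit=1)
        assert "chr1_m5" in out.markers.marker_ids
        j = out.markers.marker_ids.index("chr1_m5")
        assert out.calls[out.row("fam1_F2_1"), j] == MISSING
        assert out.calls[out.row("fam2_F2_1"), j] != MISSING

    def test_multi_family_marker_dropped(self):
        gm, ped = self._three_family_setup()
        inc = [
            ("chr1_m5", "fam1", "fam1_F2_1"),
            ("chr1_m5", "fam2", "fam2_F2_2"),
            ("chr1_m5", "fam3", "fam3_F2_3"),
        ]
        out, _, report = gtio_qc.apply_qc_policy(gm, ped, inc, marker_family_limit=1)
        assert "chr1_m5" not in out.markers.marker_ids
        assert report.markers_dropped_mendel == 1

    def test_bad_individual_removed(self):
        gm, ped = self._three_family_setup()
        inc = [(f"chr1_m{j}", "fam1", "fam1_F2_1") for j in range(1, 11)]
        out, ped2, report = gtio_qc.apply_qc_policy(
            gm, ped, inc, marker_family_limit=20, individual_error_limit=0.05
        )
        assert "fam1_F2_1" not in out.individuals
        assert report.individuals_removed == 1

    def test_report_matches_matrix_diff(self):
        gm, ped = self._three_family_setup()
        inc = [("chr1_m5", "fam1", "fam1_F2_1"), ("chr1_m9", "fam2", "fam2_F2_2")]
        out, _, report = gtio_qc.apply_qc_policy(gm, ped, inc, marker_family_limit=1)
        n_diff = int(
            ((out.calls == MISSING) & (gm.calls != MISSING)).sum()
        )
        assert report.genotypes_set_missing == n_diff

    def test_qc_idempotent(self):
        gm, ped = self._three_family_setup()
        gm = pedsim.inject_errors(gm, 0.01, 0.01, seed=22)
        once_gm, once_ped, _ = gtio_qc.run_qc(gm, ped)
        twice_gm, twice_ped, rep2 = gtio_qc.run_qc(once_gm, once_ped)
        assert np.array_equal(once_gm.calls, twice_gm.calls)
        assert once_ped.individuals == twice_ped.individuals


class TestSelectFamilies:
    def test_boundary_four_vs_five(self):
        rows = [("s", "0", "0", 1, "f"), ("d", "0", "0", 2, "f"),
                ("s2", "0", "0", 1, "g"), ("d2", "0", "0", 2, "g")]
        rows += [(f"a{k}", "s", "d", 1, "f") for k in range(4)]
        rows += [(f"b{k}", "s2", "d2", 1, "g") for k in range(5)]
        ped = Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "family"]))
        out = gtio_qc.select_families(ped, min_fullsibs=5)
        fams = out.families(min_offspring=1)
        assert [f.family_id for f in fams] == ["g"]

    def test_identity_when_all_large(self, small_dataset):
        ped = small_dataset["ped"]
        out = gtio_qc.select_families(ped, min_fullsibs=5)
        assert out.individuals == ped.individuals

    def test_matches_size_tally(self, rng):
        rows = []
        sizes = rng.integers(1, 10, size=12)
        for f, size in enumerate(sizes):
            rows += [(f"s{f}", "0", "0", 1, f"f{f}"), (f"d{f}", "0", "0", 2, f"f{f}")]
            rows += [(f"o{f}_{k}", f"s{f}", f"d{f}", 1, f"f{f}") for k in range(size)]
        ped = Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "family"]))
        out = gtio_qc.select_families(ped, min_fullsibs=5)
        kept = {f.family_id for f in out.families(min_offspring=1)}
        assert kept == {f"f{f}" for f, size in enumerate(sizes) if size >= 5}
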