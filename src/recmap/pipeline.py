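"""End-to-end convenience drivers: simulate, QC, detect, map."""

from __future__ import annotations

import numpy as np

from . import gtio_qc, mapbuild, pedsim, xover


def simulate_dataset(config: pedsim.SimConfig, intensity=None):
    """Pedigree, markers, genotypes (with configured errors) and truth."""
    ped = pedsim.simulate_pedigree(config)
    markers = pedsim.uniform_markers(config)
    gm, truth = pedsim.simulate_meioses(ped, markers, config, intensity)
    if config.genotype_error_rate > 0 or config.missing_rate > 0:
        gm = pedsim.inject_errors(
            gm, config.genotype_error_rate, config.missing_rate, config.seed + 1
        )
    return ped, markers, gm, truth


def run_pipeline(
    config: pedsim.SimConfig,
    intensity=None,
    qc: bool = True,
    min_support: float = 0.5,
    max_run: int = 1,
    bin_bp: int = 1_000_000,
):
    """Simulate a dataset and run the full analysis on it.

    Returns a dict with the simulated inputs (including truth), the
    detected events and origin matrices, the three genetic maps and the
    per-scope bin tables.
    """
    ped, markers, gm, truth = simulate_dataset(config, intensity)
    if qc:
        gm_qc, ped_qc, report = gtio_qc.run_qc(gm, ped)
    else:
        gm_qc, ped_qc, report = gm, ped, None
    events, origins, gm_clean = xover.detect_all(
        gm_qc, ped_qc, min_support=min_support, max_run=max_run
    )
    maps = mapbuild.build_maps(events, origins, gm_clean.markers)
    bins = {scope: mapbuild.bin_rates(maps[scope], bin_bp) for scope in maps}
    return {
        "config": config,
        "pedigree": ped_qc,
        "markers": gm_clean.markers,
        "genotypes": gm_clean,
        "truth": truth,
        "events": events,
        "origins": origins,
        "maps": maps,
        "bins": bins,
        "qc_report": report,
    }


def f2_truth(truth, ped):
    """Restrict crossover truth to meioses into F2 offspring (the meioses
    the detector can see)."""
    off = {
        fam_off
        for fam in ped.families(min_offspring=2)
        for fam_off in fam.offspring
    }
    return [t for t in truth if t.meiosis_id.split(":")[0] in off]


def match_events_to_truth(events, truth, markers, edge_margin: int = 1):
    """Greedy 1-1 matching of detected events to true crossovers.

    A detected event matches a true crossover of the same meiosis when the
    true bp position falls inside the event's flanking-marker interval.
    True crossovers within ``edge_margin`` markers of a chromosome end are
    censored (undetectable by design) and excluded from sensitivity.
    Returns (n_true_eligible, n_matched, n_detected, n_false).
    """
    pos = {
        chrom: markers.df.loc[markers.df["chrom"] == chrom, "pos_bp"].to_numpy()
        for chrom in markers.chromosomes()
    }
    true_points = []  # (meiosis, chrom, bp)
    for t in truth:
        for p in t.crossover_positions_bp:
            lo = pos[t.chromosome][edge_margin]
            hi = pos[t.chromosome][-1 - edge_margin]
            if lo <= p <= hi:
                true_points.append([t.meiosis_id, t.chromosome, p, False])
    n_detected = len(events)
    n_matched_events = 0
    for e in events:
        hit = None
        for tp in true_points:
            if (
                not tp[3]
                and tp[0] == e.meiosis_id
                and tp[1] == e.chromosome
                and e.left_bp <= tp[2] <= e.right_bp
            ):
                hit = tp
                break
        if hit is not None:
            hit[3] = True
            n_matched_events += 1
    n_true = len(true_points)
    n_matched = sum(1 for tp in true_points if tp[3])
    return n_true, n_matched, n_detected, n_detected - n_matched_events


def sex_map_ratio(maps) -> float:
    """Female / male total genome map length."""
    return maps["female"].total_cM / maps["male"].total_cM
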