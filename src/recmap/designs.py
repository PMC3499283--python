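"""Canned simulation study designs used for end-to-end validation.

Each function fixes the conditions of one parameter-recovery study:
crossover detection accuracy on a dense panel, genome map-length
recovery on a multi-chromosome intercross, sex-ratio recovery with a
female/male genome-length ratio of 1.26, and a feature-enrichment study
on a synthetic genome whose GC content and GC-rich motif density follow
the latent recombination intensity of the female map while the male map
stays flat.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import pedsim, pipeline, seqfeat, stats_enrich
from .core import FEMALE, MALE


def crossover_recovery_study(seed: int = 1) -> dict:
    """~1,000 meioses on a 2,000-marker panel, no genotyping error.

    True crossovers more than one marker interval from a chromosome end
    are eligible; a detected event matches when its flanking-marker
    interval contains the true position in the same meiosis.  Returns a
    dict with the match counts and the phase-reconstruction rate.
    """
    from . import xover

    config = pedsim.SimConfig(
        chrom_lengths_bp=[100_000_000, 100_000_000],
        n_markers_per_chrom=1_000,
        male_map_cM=[90.0, 80.0],
        female_map_cM=[110.0, 100.0],
        n_families=63,
        offspring_per_family=8,
        seed=seed,
    )
    res = pipeline.run_pipeline(config, qc=False)
    truth = pipeline.f2_truth(res["truth"], res["pedigree"])
    n_true, n_matched, n_detected, n_false = pipeline.match_events_to_truth(
        res["events"], truth, res["markers"]
    )
    return {
        "n_true": n_true,
        "n_matched": n_matched,
        "n_detected": n_detected,
        "n_false": n_false,
        "n_meioses": 2 * config.n_families * config.offspring_per_family,
        "phase_rate": xover.phase_rate(res["origins"]),
    }


def map_length_study(seed: int = 1):
    """Intercross of 17 families with a 2,000 cM sex-averaged genome
    (18 chromosomes, male 100 / female 122.2 cM each).

    Returns (maps, truth_by_scope, n_meioses_per_sex).
    """
    n_chrom = 18
    config = pedsim.SimConfig(
        chrom_lengths_bp=[120_000_000] * n_chrom,
        n_markers_per_chrom=1_000,  # chip-like density (~2,000 SNPs/chrom on the 60K panel)
        male_map_cM=[100.0] * n_chrom,
        female_map_cM=[122.2] * n_chrom,
        n_families=17,
        offspring_per_family=10,
        seed=seed,
    )
    res = pipeline.run_pipeline(config, qc=False)
    truth = {
        "male": 100.0 * n_chrom,
        "female": 122.2 * n_chrom,
        "sex_averaged": 111.1 * n_chrom,
        "per_chrom_sex_averaged": 111.1,
    }
    return res["maps"], truth, config.n_families * config.offspring_per_family


def sex_ratio_study(seed: int = 1):
    """1,000 meioses per sex with the female/male genome ratio set to
    2,244/1,782 = 1.2593 (four chromosomes at chip-like marker density).

    Returns (estimated_ratio, true_ratio, standard_error).
    """
    config = pedsim.SimConfig(
        chrom_lengths_bp=[120_000_000] * 4,
        n_markers_per_chrom=1_000,
        male_map_cM=[1782.0 / 20] * 4,
        female_map_cM=[2244.0 / 20] * 4,
        n_families=125,
        offspring_per_family=8,
        seed=seed,
    )
    res = pipeline.run_pipeline(config, qc=False)
    ratio = pipeline.sex_map_ratio(res["maps"])
    n_f = sum(1 for e in res["events"] if e.parent_sex == FEMALE)
    n_m = sum(1 for e in res["events"] if e.parent_sex == MALE)
    se = ratio * np.sqrt(1.0 / n_f + 1.0 / n_m)
    return ratio, 2244.0 / 1782.0, se


#: Per-bin planting rates (occurrences per Mb at unit intensity), loosely
#: matching chip-era per-Mb magnitudes of these motifs in a mammalian genome.
ENRICHMENT_MOTIF_RATES = {
    "CCTCCT": 380.0,
    "CCTCCCT": 120.0,
    "CTCTCCC": 110.0,
    "CCCCCCC": 120.0,
    "CCCCACCCC": 35.0,
    "CCNCCNGGNGG": 16.0,
    "CCNCCNTNNCCNC": 30.0,
}


def enrichment_study(
    seed: int = 1,
    planting_strength: float = 1.0,
    n_families: int = 32,
    motifs=tuple(ENRICHMENT_MOTIF_RATES),
):
    """Synthetic-genome feature/recombination study.

    Two 30 Mb chromosomes; a lognormal latent recombination intensity per
    1 Mb bin drives (a) where female crossovers fall, (b) the bin GC
    target and (c) the motif-planting rates (scaled by
    ``planting_strength``).  The male map has the same genome length but
    a flat landscape, so female recombination is sensitive to GC and
    motif density while male recombination is not.

    Returns a dict with the joined per-bin table (rates for the three
    scopes plus features) and the genome truth.
    """
    rng = np.random.default_rng(seed)
    bin_bp = 1_000_000
    chrom_lengths = {"chr1": 30_000_000, "chr2": 30_000_000}
    log_int = {c: rng.normal(0.0, 0.6, size=30) for c in chrom_lengths}
    inten = {c: np.exp(v) / np.exp(v).mean() for c, v in log_int.items()}
    gc = {
        c: np.clip(0.42 + 0.05 * (log_int[c] / 0.6), 0.30, 0.55) for c in chrom_lengths
    }
    plant = {
        c: inten[c] ** planting_strength / (inten[c] ** planting_strength).mean()
        for c in chrom_lengths
    }
    genome = pedsim.simulate_genome(
        chrom_lengths,
        gc,
        motif_rates={m: ENRICHMENT_MOTIF_RATES[m] for m in motifs},
        latent_intensity=plant,
        bin_size=bin_bp,
        seed=seed + 1,
    )
    config = pedsim.SimConfig(
        chrom_lengths_bp=list(chrom_lengths.values()),
        n_markers_per_chrom=600,
        male_map_cM=[60.0, 60.0],
        female_map_cM=[60.0, 60.0],
        n_families=n_families,
        offspring_per_family=8,
        seed=seed + 2,
    )
    res = pipeline.run_pipeline(
        config, intensity={FEMALE: inten, MALE: None}, qc=False
    )
    bins = res["bins"]["sex_averaged"].rename(
        columns={"rate_cM_per_Mb": "rate_sex_averaged"}
    )
    for scope in ("male", "female"):
        bins[f"rate_{scope}"] = res["bins"][scope]["rate_cM_per_Mb"].to_numpy()
    features = seqfeat.feature_table(
        genome.sequences,
        bins,
        chrom_lengths=chrom_lengths,
        motifs=motifs,
    )
    return {
        "bins": bins,
        "features": features,
        "genome": genome,
        "intensity": inten,
        "result": res,
    }


def end_distance_study(seed: int = 1, n_bins: int = 2_000, decay: bool = True):
    """Synthetic bin table with rates decaying in distance-to-end (or flat).

    Returns the CorrelationResult of rate vs distance to the closest
    chromosome end.
    """
    rng = np.random.default_rng(seed)
    d = rng.uniform(0.0, 75.0, size=n_bins)
    noise = rng.normal(0.0, 0.15, size=n_bins)
    rate = (np.exp(-d / 25.0) + 0.2 + noise) if decay else (1.0 + noise)
    bins = pd.DataFrame(
        {
            "chrom": "c",
            "start_bp": np.arange(n_bins) * 1_000_000,
            "end_bp": (np.arange(n_bins) + 1) * 1_000_000,
            "rate_cM_per_Mb": rate,
        }
    )
    return stats_enrich.end_distance_correlation(bins, d)


def null_pvalue_study(seed: int = 1, n_reps: int = 1_000, n: int = 50):
    """Pearson p-values under independence; returns the array of p-values."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_reps)
    for k in range(n_reps):
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        out[k] = stats_enrich.pearson_with_p(x, y).p_value
    return out
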