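# Methods

## Problem setting

`recmap` builds genetic (linkage) maps of a genome from dense SNP
genotypes of structured pedigrees — the classical substrate being an F2
line cross genotyped on a ~60K SNP chip. The pipeline has four stages:
quality control of genotypes against the pedigree, crossover detection
within nuclear families, map construction with the Haldane function,
and correlation/enrichment analysis of the resulting per-megabase
recombination rates against sequence features (GC content, GC-rich
motifs such as the CTCF consensus CCNCCNGGNGG and the PRDM9 binding
consensus CCNCCNTNNCCNC, repeat classes, distance to chromosome ends).

Because real pedigree genotypes of this kind are rarely redistributable,
the package ships a synthetic-data generator with complete ground truth
(every simulated crossover, every planted motif), and its validation is
parameter recovery: simulate under known conditions, run the pipeline,
compare estimate with truth.

## Crossover detection

Within a nuclear family and for one parent, the *transmitted allele* of
an offspring at a SNP is directly deducible when the parent is
heterozygous and either (a) the offspring is homozygous, or (b) the
offspring is heterozygous and the other parent is homozygous. At
markers where two sibs' transmitted alleles are both deducible the pair
is either identical by descent (IBD) for that parent's transmission or
not; a switch between the two states along the chromosome localises a
crossover to the interval between the nearest flanking markers with
defined status.

Switch intervals are collected from **every unordered sib pair**,
clustered by running intersection (switches of the same event seen
through different pairs overlap), and each cluster is attributed to the
offspring shared by a strict majority (configurable `min_support`,
default 0.5) of the covering pairs that show the switch. Attribution is
repeated on the residual pairs, so two meioses recombining in the same
interval are each recovered. This pairwise formulation is equivalent to
iterating every offspring as the comparison template and removes any
dependence on a template choice; the deduplicated event set is invariant
to offspring ordering. When only one pair covers an interval the
attribution is ambiguous and is fixed deterministically on the name-wise
first offspring (the event count, hence the map, is unaffected).

### Parental-phase reconstruction

In an intercross both F1 parents are heterozygous at most markers, so
rule (a) alone anchors a meiosis only at homozygous offspring, and a
crossover flanked by a long heterozygous stretch would be poorly
localised or lost. Detection therefore alternates with partial phase
reconstruction:

1. Grandparental origins are propagated between the detected crossovers
   of each meiosis (origins are constant between crossovers).
2. The two parental haplotypes are rebuilt by solving the XOR parity
   system that links markers and meioses through the anchored
   transmissions (union-find with parities, followed by two rounds of
   marker-wise/meiosis-wise majority refinement, which is robust to
   isolated wrong constraints from mislocalised event boundaries).
3. The reconstructed phase of one parent resolves the ambiguous
   transmissions of the other by complementation: at an informative
   marker with a heterozygous offspring, the allele not contributed by
   the reconstructed parent was contributed by the other.

Two safety rules keep reconstruction errors from seeding false events.
Imputation is confined to each meiosis's own span of directly deducible
markers, and it is suppressed between anchors whose observed values
disagree with the reconstruction (the residual of the parity solve —
the signature of a missed or mislocalised event in that region).
Parents are updated sequentially and the detect/impute cycle repeats
until the event set is stable (at most 6 sweeps in practice; 2–3
typical).

A close double crossover whose intervening segment carries no directly
deducible marker for either parent cannot be attributed and is censored
(both events dropped) rather than guessed. Likewise, events before the
first or after the last deducible marker of a meiosis are undetectable.
Both censoring mechanisms shrink with marker density; at chip-like
density (≈0.1 cM between markers) the measured sensitivity is ≈99 %
with ≈0.1 % false events, and the residual map-length bias is under 3 %.

### Sex attribution needs within-line polymorphism

With founder lines fixed for alternate alleles, both F1 parents are
heterozygous at *every* marker and the family's genotype likelihood is
symmetric under swapping the sire's and dam's transmissions: no data can
attribute a crossover to a parent. Real line crosses segregate within
lines, which is what creates markers informative for exactly one
parent. The generator therefore defaults to a within-line minor allele
frequency (`founder_maf`) of 0.15, giving ≈20 % single-parent
informative markers; setting it to 0 reproduces the degenerate design.

### Double-recombinant repair

A single-marker grandparental-origin island — a run of at most
`max_run` (default 1) deducible markers flanked by the opposite origin
on both sides — is the signature of a genotyping error, not of two
crossovers. The offending genotypes are set missing, the paired events
deleted, and detection re-run to a fixpoint. Genuine double crossovers
spanning more than `max_run` deducible markers are untouched.

### Phase-reconstruction rate

Reported as the assigned fraction of all (meiosis, marker) cells of the
per-family origin matrices: cells inside event intervals, beyond a
meiosis's information span, or belonging to meioses of an ungenotyped
parent are unassigned. Under this definition a fully typed pedigree
scores ≈0.99 and the rate declines as parent genotypes are removed,
matching the behaviour expected when mothers are partially ungenotyped.
Other denominators (e.g. restricting to directly deducible markers) are
defensible; this one is used consistently.

## Map construction

Per adjacent-marker interval, the recombination fraction is
r = (crossover events in the interval) / (informative meioses covering
it), where a meiosis covers an interval when its assigned origin span
reaches both flanking markers. An event localised to a multi-interval
span contributes fractionally, proportional to interval bp length (the
least-informative apportioning; midpoint assignment would concentrate
it). r ≥ 0.5 in an interval raises an error pointing at the marker
order. Distances use the Haldane mapping function d = −50·ln(1−2r) cM —
interference-free, matching the Poisson crossover model of the
generator — with the exact inverse r = (1−e^(−d/50))/2.

Sex-specific maps use only that parent sex's events with sex-specific
coverage; the sex-averaged map pools all events with combined coverage
(it is not the mean of the two sex maps). Bin rates are computed in
SNP-delimited bins of approximately 1 Mb: each boundary is the first
marker at or beyond 1 Mb from the previous boundary, so bins tile
exactly the marker-covered span and the bin cM sums telescope to the
chromosome total (conservation to 1e−9 relative, asserted in tests).
Rates before the first and after the last SNP are undefined and no bins
are emitted there. For plotting, rates can be smoothed with a centered
moving average (default 5 bins) that shrinks at chromosome ends.

## Sequence features

GC content per bin excludes ambiguous bases from the denominator (a bin
with no unambiguous base is NaN and drops out of correlations
pairwise). Motifs over {A,C,G,T,N} (N = any base) are counted by match
start position, overlapping occurrences included, on both strands by
scanning the forward pattern and the reverse-complement pattern against
the forward sequence; a motif whose pattern equals its own reverse
complement is scanned once, so palindromes are not double-counted.
Forward-only counting is available behind a flag. Soft-masked bases are
uppercased. Repeat classes come from a user-supplied RepeatMasker-style
BED; a feature is counted in the bin containing its start and its bp
coverage is clipped to each bin. Distance to the closest chromosome end
is min(midpoint, length − midpoint) in Mb.

## Statistics

Pearson correlations use the t transform with n−2 df for two-sided
p-values; Spearman is Pearson on mid-ranks. Bins with undefined rate or
feature are excluded pairwise, not listwise. Recombination *jungles*
and *deserts* are the top and bottom floor(q·n) bins by rate (q = 0.10),
with deterministic tie-breaking by genomic coordinate; a degenerate rate
distribution (quantiles overlapping) raises an error. The J/D ratio is
the mean feature abundance in jungles over deserts. GC-stratified rates
use fixed-width GC classes (default 0.01) and report the lowest class
where the female mean rate exceeds the male one. Raw p-values are
reported; a Benjamini–Hochberg column is emitted for convenience but not
used by any decision in the package.

## The synthetic generator, and what passing tests do not show

The generator emulates: two founder lines with configurable within-line
MAF, F1 intercross, full-sib F2 families; Poisson (interference-free)
crossover counts with sex-specific genetic lengths; an optional latent
per-bin recombination intensity (optionally sex-specific) that modulates
crossover placement; genotyping error (random flips to a different legal
genotype) and missingness; genomes with per-bin GC targets and motifs
planted at Poisson rates proportional to the latent intensity.

It does **not** emulate: crossover interference (the Haldane/Poisson
assumption is exact in simulation, merely approximate in nature),
segregation distortion, genotype-calling artefacts correlated across
markers or individuals, assembly errors in marker order, or realistic
repeat landscapes. Parameter recovery here therefore validates the
inference machinery under its own model assumptions; on real data the
absolute accuracies will be lower wherever those assumptions are
violated (notably interference, which shortens Haldane maps relative to
interference-aware ones).

## Study designs used in validation

- Crossover recovery: 63 families × 8 offspring (≈1,000 meioses per
  parent side), two 100 Mb chromosomes, 1,000 markers each, error-free.
- Map-length recovery: 17 families × 10 offspring, 18 chromosomes of
  120 Mb at 1,000 markers each (chip-like density), male 100 cM and
  female 122.2 cM per chromosome (2,000 cM sex-averaged genome).
- Sex-ratio recovery: 125 families × 8 offspring (1,000 meioses per
  sex), four chromosomes, female/male genome ratio 2,244/1,782 ≈ 1.26.
- Enrichment: two 30 Mb chromosomes, lognormal latent intensity per
  1 Mb bin (σ = 0.6 on the log scale, mean 1); bin GC = 0.42 ±
  0.05·(standardised log-intensity), clipped to [0.30, 0.55] (0.42 being
  a typical mammalian genome average); motif planting rates proportional
  to intensity; the female map follows the intensity landscape while the
  male map is flat, so female recombination is GC- and motif-sensitive
  by construction and the male map acts as the negative control.

Problem sizes were chosen to be chip-realistic per chromosome while
keeping the genome count small; all are configurable.

## Numerical and degenerate-input conventions

Physical positions are 1-based inclusive bp; bins are half-open
[start, end). cM values are written to 2 decimals in output files but
kept at full precision internally. A chromosome with fewer than two
markers yields no bins (warning-free, empty result). Call-rate
filtering uses a strict inequality ("higher than" the threshold). The
QC cascade is iterated to a fixpoint because masking Mendelian errors
can push a marker below the call-rate threshold. Mendelian checking
with a missing parent simply drops that parent's constraint; a missing
offspring call is never inconsistent.
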