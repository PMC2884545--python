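# Methods

## The analysis model

`chromstate` classifies gene promoters from ChIP-seq read libraries for RNA
Pol II, H3K4me3, H3K27me3, H3K36me3 and an unmodified-H3 control, combined
with RNA-seq expression (RPKM) tables and microarray Present/Absent calls.
All coordinates are 0-based half-open; the TSS of a minus-strand transcript
is its annotated end, and every window offset is strand-oriented.

### Analysis windows

Per transcript, relative to the TSS:

| window            | interval        | used for                          |
|-------------------|-----------------|-----------------------------------|
| Pol II promoter   | −250 .. +250    | Pol II enrichment, stalling index |
| K4/K27 promoter   | 0 .. +500       | H3K4me3 / H3K27me3, valency       |
| gene body         | +500 .. +1000   | stalling index (length > 1 kb)    |
| K36 window        | +500 .. +1500   | H3K36me3 (length > 1.5 kb)        |

### Transcript eligibility

Dense genomes put promoters inside or next to neighbouring genes, which
corrupts window counts. Three filtering steps, applied per analysis:

1. transcripts shorter than 500 bp are dropped (`too_short`);
2. a transcript is dropped from a promoter analysis iff its promoter window
   for that analysis intersects the transcript span of a *different* gene
   (`overlap_conflict`); additionally, non-overlapping opposite-strand
   transcript pairs with TSSs closer than 400 bp are dropped from the
   Pol II analysis only (`tss_too_close`), since only the −250..+250 window
   reaches across the TSS;
3. survivors define per-gene eligibility: promoter-eligible (≥ 1 surviving
   transcript in either promoter analysis), stalling-eligible (surviving
   Pol II transcript > 1 kb), K36-eligible (surviving transcript > 1.5 kb).

Every exclusion is either intrinsic or symmetric over the input set, so the
filter is idempotent, order-independent, and verified against an O(n²)
brute-force reimplementation in the tests.

For multi-isoform genes one dominant transcript represents the gene,
selected by an ordered criterion chain (primary window read count →
length-conditional secondary count → longest transcript → seeded random
choice). The secondary criterion is evaluated per transcript — gene-body
reads for transcripts long enough to have a body window, the alternate
mark's promoter count otherwise — which is one defensible reading of a rule
stated only for all-long or all-short tie groups. The tie-break seed is
derived per gene from the run seed (xor with a CRC of the gene id, masked
below 2^31) and recorded in the run report.

### Poisson enrichment calibration

The null model scatters a library's `N` unique reads uniformly over the
mappable genome `G` (default 120,381,546 bp — the sum of the six major
euchromatic chromosome arms of the dm3 assembly). A fixed window of `w` bp
then holds Poisson(λ = N·w/G) reads. For counts 1..99 the exact upper-tail
probability is tabulated and the significance threshold is the smallest
count with tail ≤ α (default 0.05). Tails are exact `scipy.stats.poisson`
survival values, never normal approximations; an independent brute-force
mass-summation oracle in the test suite agrees to 1e-12. No
multiple-testing correction is applied — calls are per-window at α, with
the number of windows tested reported alongside. With 1,342,075 reads,
500-bp windows and the default genome length, the tail at 11 reads is
0.0274 (≈ 0.03) and the threshold is 11 — the package's reference worked
example.

Whether window counts assign a read by its 5′ position or by its
strand-aware fragment midpoint is configurable (`five_prime` default,
`midpoint` alternative); neither convention can be verified against the
original analysis, and the flag exposes the ambiguity rather than hiding
it. Calibration uses unique post-deduplication read counts (at most three
copies of an identical alignment are retained).

### Classifications

- **Valency**: bivalent iff both H3K4me3 and H3K27me3 are significant in
  the 0..+500 window of the gene's dominant transcript; monovalent with
  exactly one; `neither` otherwise.
- **Stalling index** SI = promoter reads / gene-body reads. SI is +∞ when
  the body is empty but the promoter is not (classified stalled when
  significant — the limit of the rule), and undefined (NaN, reported) when
  both are empty.
- **Pol II class**: `active` (SI ≤ 3, significant), `stalled` (SI ≥ 5,
  significant), `none` (not significant). Significant genes with
  3 < SI < 5 — a range the three-class rule leaves open — are reported as
  an explicit `intermediate` bucket rather than silently dropped.
- **Expression**: silent < 0.5 RPKM ≤ intermediate < 1 RPKM ≤ expressed
  (working cutoffs), or a strict scheme where silent means RPKM = 0;
  expressed genes split low/moderate/high at configurable bounds
  (tertiles by default, since no canonical boundaries exist).
  Log values always use log2(RPKM + 1).
- **Flags**: differentiation (RPKM < 0.5 undifferentiated, ≥ 1
  differentiated), up-regulated (≥ 2-fold with the denominator floored at
  0.5), poised candidate (significant promoter Pol II with RPKM < 1).

Percentages in reports use round-half-up, one decimal by default and
nearest-integer where headline figures are conventionally printed as
integers.

### Islands and saturation

Chromosomes are tiled with non-overlapping windows (200 bp default; 400 bp
recommended for the broader H3K27me3/H3K36me3 marks), a window is eligible
when its count beats the Poisson background tail at P0 = 0.2, and adjacent
eligible windows merge with no gap allowed — appropriate for a gene-dense
genome. Candidate islands are scored by the summed per-window Poisson
surprise −ln P(count | λ). The retention threshold is an empirical null:
the same number of reads is placed uniformly at random (20 seeded
replicates), and islands are kept where the expected number of
equally-scoring null islands is ≤ the E-value (genome-wide reading). This
deliberately replaces the analytic island-score null of full SICER-style
callers — the empirical null is simpler, seeded, and sufficient for
saturation-curve shape; numeric identity with SICER is not claimed, and
gap > 0 aggregation and control-library normalization are out of scope.

Saturation analysis shuffles the library once (seeded), takes cumulative
subsamples at 2.5%, 5%, …, 100% and calls islands in each with a matched
E-value schedule 3, 6, …, 120.

## The synthetic-data generator

The generator plants ground truth at the exact statistical structure the
calibration assumes: background reads uniform over a single synthetic
chromosome; marked genes receive additional Poisson reads whose positions
are uniform within the mark's window (so every window count is exactly
Poisson and type-I tests are sharp); sequenced fragments are centred on
those positions with the read taken off either end at random, so plus- and
minus-strand 5′ densities sit `fragment_size` apart (160 bp default).

Defaults are the study conditions: 2,000 genes (2–6 kb, random strand,
1.5–3 kb gaps) on a 20-Mb chromosome; enrichment fold 5; valency mix
30% K4-only / 15% K27-only / 5% bivalent / 50% neither; Pol II mix
35% active / 15% stalled / 50% none; 60% of genes expressed. Planted
special cases (short transcripts, nested overlapping gene pairs,
head-to-head TSS pairs 300 bp apart, multi-isoform genes sharing a TSS)
exercise every exclusion reason with exactly known counts.

Two generator parameters deserve justification:

- **Background rate 0.0064 reads/bp** (λ = 3.2 per 500-bp window). The
  realized size of the discrete threshold test — the exact tail probability
  at the calibrated threshold — oscillates between ~0.02 and ~0.05 as λ
  varies. The default was chosen by an analytic scan so that every
  library's calibration (background plus its mark-specific enrichment
  reads) sits mid-plateau, keeping per-mark false-positive rates near
  1–2% with margins checked against library-size sampling noise. At a
  depth where a library lands just below a threshold increment, the
  per-mark false-positive rate reaches 5% and two-mark specificity drops
  to ~90% — a property of the calibration itself, worth knowing when
  interpreting `neither`/`none` calls on real data.
- **Stalled-gene promoter:body ratio 14**. Planted stalled genes carry a
  promoter read rate of `promoter_body_ratio` × the background body rate
  (no extra body reads), so their expected SI equals the ratio. Because
  the SI denominator is a small Poisson count, an expected SI barely above
  the ≥ 5 call boundary is recovered unreliably (at E[SI] = 8 roughly a
  fifth of truly stalled genes fall below the cutoff by body-count noise
  alone); 14 reflects the strong promoter-proximal accumulation of a
  genuinely paused polymerase and keeps the planted class recoverable.
  Active genes get equal promoter and body enrichment (expected SI 1).

Expression: expressed genes draw RPKM = max(1, lognormal(ln 8, 1)); silent
genes draw below 0.5 (zero-inflated beta); half of the silent genes are
turned on (RPKM ≥ 1) in the differentiated condition. Differentiation and
up-regulation truth flags are recomputed from the drawn values, so they
hold by construction. Microarray calls are Present in all replicates
(3 by default) for detected genes, with a 5% false-absent fraction flipped
to all-Absent and 2% of genes given conflicting multi-probe calls.

**What the generator does not emulate**: mappability structure, GC bias,
duplicate-rate modelling, correlated chromatin classes (valency and Pol II
status are drawn independently of expression, unlike real data where they
are strongly coupled), peaked within-window binding profiles, and
multi-chromosome genomes (single chromosome by default; nothing in the
pipeline is chromosome-count-sensitive). Passing recovery tests therefore
demonstrates correctness of the statistical machinery under its own
assumptions, not performance on real libraries.

## Fragment-size estimation

The estimator cross-correlates smoothed (10-bp) per-strand 5′-position
densities and returns the lag in 0..500 maximizing the summed correlation.
Two numerical details matter at realistic depth. First, correlation is
restricted to read-dense segments (500-bp bins above the genome mean plus
four Poisson standard deviations, padded by the search range): uniformly
scattered background reads pair at every lag alike, and their noise is
comparable to the enrichment peak, which under uniform-in-window placement
is a flat-topped triangle. Each segment is centred by its local strand
means — without centring, the segment selection itself (conditioned on
high total count) induces a spurious short-lag correlation. Second, the
correlation function is smoothed over lags (21-point window) before the
argmax, since residual noise is correlated over roughly the density
smoothing scale. Clean planted libraries are recovered exactly; the
full-scale Pol II library recovers 160 ± 10 bp across seeds, while the
weaker histone-mark libraries at desk-scale depth localize the flat peak
only to ~±25 bp. The control (H3) library has no enrichment and therefore
no identifiable offset — estimation there errors out if a strand is
missing and is otherwise meaningless by construction.

## Numerical and degenerate-input choices

- Tail probabilities computed via `poisson.sf` (log-space internally);
  pvalue tables are monotone non-increasing with P(X ≥ 0) = 1.
- Windows extending past a chromosome start are truncated at 0 with a
  warning; reads extending past ends are clipped.
- A calibration whose threshold lies beyond count 99 raises an error
  telling the caller to extend the range, rather than silently saturating.
- Empty read libraries yield empty island lists; empty denominators yield
  NaN percentages; genes with no eligible transcript raise a no-selection
  error rather than guessing.
- All randomness (tie-breaks, Monte-Carlo nulls, subsampling, generation)
  flows from explicit seeds; repeated runs are byte-identical.

## Problem sizes used by the test suite

The suite runs the full pipeline on one shared 2,000-gene / 20-Mb dataset
(≈ 135k reads per library), module tests on a 300-gene / 4-Mb dataset, and
saturation on a 10-Mb library with 250 planted regions of heterogeneous
strength (3–15× background, so weak regions emerge only at depth, as real
peaks do). Oracle-equivalence checks cover 1,000 random library
configurations. The whole suite completes in well under a minute on a
single core.

## Known limitations

- The eligibility filter's overlap rule is an interval test per promoter
  window; curated per-locus judgements of which overlaps "do not affect"
  a promoter may differ for pathological gene arrangements.
- Genome-scale gene counts from real libraries (e.g. numbers of bivalent
  or stalled genes) depend on the original deposited data, annotation
  vintage and aligner, and are not reproducible from synthetic data; the
  package reproduces the printed calibration example and the count-pair
  arithmetic, and validates the machinery by planted-truth recovery.
- Island calling makes no claim of numeric identity with SICER; E-value
  semantics are genome-wide, and gaps are unsupported.
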