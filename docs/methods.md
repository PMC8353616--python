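# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open; GTF I/O converts to/from
1-based inclusive. "Upstream"/"downstream" and every window offset are
strand-oriented (upstream = 5' direction of the feature's strand). A PAS
`site` is the cleavage position: the last templated base is at site − 1
and the site position itself is treated as the first untemplated tail
base, so reads from a cleaved transcript end strictly before `site`.

## PAS annotation sets

Site records carry source flags from three site databases (DB1–DB3) and a
curated gene annotation (GENCODE). The *known* set keeps sites reported in
at least two databases or present in the curated annotation; the
*stringent* subset requires all three databases or the curated annotation.
Duplicates are merged by exact (chrom, site, strand) key — no fuzzy
coordinate merging. The train/validation split draws a uniform random
partition with |train| = round(N·ratio) (round-half-up); at the reference
scale of 251,071 stringent sites and ratio 0.9 this gives 225,964 and
25,107. A peak 3' end "overlaps" a known site when the site falls in the
strand-oriented window [−50, +25] around the end, boundaries inclusive
(the inclusive choice is ours; the window itself is fixed).

## Peak calling

3' tag chemistry piles read 5' starts in a ~400-nt window ending at the
cleavage site, so candidate sites are called on read-start coverage with a
fixed window width (default 400 nt):

* Coverage is accumulated per transcript in spliced (exon) coordinate
  space, so called windows can span exon junctions and map back to
  multi-block genomic footprints; intron coverage is scanned separately
  per intron in contiguous genomic space, and intron-derived peaks carry
  `category="intronic"` (their 3' ends lie outside all exons).
* The caller is greedy: the window with the highest remaining start count
  is accepted, the starts it consumed are removed, and the loop repeats
  until the best window falls below `min_count` (default 10). Among
  equal-count windows the most 3' one is taken, because the informative
  edge of a pile is its downstream boundary — the cleavage site. Accepted
  summits must be more than `min_dist` (default 10 nt) apart. The peak's
  3' end is the downstream window edge.
* Modality: each peak profile is tested for unimodality with the dip
  statistic (below); rejection at α = 0.05 triggers a split at the deepest
  coverage minimum between the two highest smoothed modes, with read
  counts partitioned by side. An Anderson–Darling normality statistic on
  the same position sample is kept as metadata only.
* Aggregation: within a gene, peaks whose genomic overlap is ≥ 50% of the
  shorter peak are grouped transitively and each group keeps only its
  maximally expressed member; the operation is idempotent.
* Filters: peaks with ≤ 1% of their gene's summed read count are dropped;
  intronic peaks with ≥ 8 consecutive A in the strand-oriented window
  [3'end − 10, 3'end + 20] (clipped at contig bounds) are dropped as
  internal-priming artifacts. Exonic peaks are never touched by the A-run
  filter.

### Dip statistic

No dip-test implementation is available in the environment, so the
statistic is computed in-package from its convex/concave characterisation:
a unimodal CDF is convex left of the mode and concave right of it, and the
best sup-norm convex approximation of a function sits midway above its
convex envelope. The dip is therefore

    dip = ½ · min over modal split m of max( gapL(m), gapR(m) )

where gapL(m) is the largest gap between the ECDF and its greatest convex
minorant over points left of m, and gapR(m) the mirror-image quantity on
the right (computed with an incremental monotone-chain hull). This equals
the classical dip up to junction subtleties at the modal interval;
p-values are calibrated by Monte Carlo against uniform samples of matched
size using the *same* statistic, which gives the test correct size by
construction. Peak profiles are converted to samples by weighted quantiles
(never more points than reads, so duplicated positions cannot masquerade
as modes) plus ±0.5 dither to break integer ties.

## Sequence classifier

Architecture (widths configurable; defaults are the full-scale design):
two 1-D convolutions (128 filters × width 12 over 4 channels, then 64
filters × width 6) with ReLU; max-pooling with window = stride = 4; a
BiLSTM with 128 units per direction whose final states are concatenated; a
dense ReLU layer of 1024 units with dropout 0.3; and a 2-unit softmax
head. One-hot encoding uses channel order (A, T, G, C); N encodes as an
all-zero row, and windows with > 10% N are excluded from training. The
whole network — forward, backward, Adam — is implemented in NumPy inside
the package; `ModelSpec.scaled(f)` shrinks filter/unit counts (not motif
widths) for desk-scale work.

Training sets: positives are 200-nt windows around annotated sites. The
*shifted* construction draws, per site, 10 distinct integer offsets from
round(N(0, 10)) (|offset| ≤ 90 enforced by resampling so the site stays
inside the window) and removes exact duplicate sequences globally; the
*fixed* baseline takes one window centred on each site. Negatives are
uniform random intergenic windows avoiding all annotated sites, matched in
number. Training uses cross-entropy, Adam, and early stopping on a 5%
held-out monitor slice (patience in epochs; the best-epoch weights are
restored). Reference-scale settings are batch 5000 and 100 epochs with
patience 10; the desk-scale benchmark uses a quarter-width model, batch
256 and ≤ 10 epochs, which suffices for held-out AUC ≥ 0.99 on the planted
signal corpus. A window is called positive iff probability > 0.5
(strictly; 0.5 exactly is negative).

Evaluation utilities: per-offset true-positive rate on windows shifted in
5-nt strides up to ±50 nt (the positional-tolerance profile), and
true-negative rate on intergenic windows centred on planted A-runs of
length 8–15 far (≥ 1 kb) from any annotated site (the internal-priming
probe). Filter motifs are extracted from the first convolutional layer by
collecting, per filter, the maximally activating 12-mer (activation > 0)
from each positive training sequence; columns of the aligned 12-mers give
the PPM, PWM = log2((PPM + 10⁻³)/0.25), and motifs are sorted by total
information content (2 − column entropy, summed).

## Quantification

Each surviving PAS is assigned to the transcript of its gene with maximal
exonic overlap with the peak footprint (ties → longest transcript); the
feature's exon chain is the peak footprint itself — possibly spanning exon
junctions of that transcript — clipped at the cleavage site, and features
are written as a PAS-based GTF (transcript_id = feature id).
Peaks matching no transcript become contiguous features flagged
unspliced. UMI counting assigns each primary, mapped, tagged read to the
sense-strand feature with the largest overlap; exact ties — nested
isoforms sharing their exon prefix — go to the *shortest* feature, because
a 3' tag read in the shared region piles against the nearest cleavage
site. Distinct UMI strings are counted once per (barcode, feature); no
error-aware UMI collapsing is attempted. RPM over a stranded region is
(reads overlapping the region, MAPQ ≥ 3, sense strand, multi-region
counting allowed) / (total mapped primary reads) × 10⁶; for database PASs
the region is the 400 nt upstream of the annotated site, for called PASs
the reported peak region.

## Evaluation

Enrichment score = log2((RPM_up + 0.1)/(RPM_down + 0.1)) over the 400-nt
flanks of a 3' end (strand-oriented, clipped at contig bounds). Confusion
matrices compare model calls (probability > 0.5) against
enrichment-defined truth (score ≥ cutoff, default 2, sweep
{1.5, 1.75, 2, 2.25, 2.5}) on peaks with expression RPM ≥ 1; F1 =
2TP/(2TP + FP + FN). ROC curves sweep thresholds with tied scores
grouped; AUC is trapezoidal and agrees with the Mann–Whitney rank
statistic to 10⁻⁹. The recapture rate is the fraction of expressed
(upstream-RPM ≥ 1) annotated sites falling within the −50/+25 window of
any identified peak 3' end.

## APA statistics

"Proximal" is the PAS farthest from the annotated gene 3' end (shortest
3'UTR); single-PAS genes are excluded from usage scoring. Usage =
log2((CPM_proximal + 1)/(Σ CPM_rest + 1)) with CPM per cell over all PAS
features. Per-cell global preference is the mean usage over genes with
nonzero counts in that cell and ≥ 2 PASs, Z-scored across scored cells
with the sample SD (ddof = 1); a zero-variance cell set gets all-zero Z.
Differential usage per feature uses log2 fold change of group mean CPM
(+1 to avoid division by zero), a two-sided Wilcoxon rank-sum P value, and
the expressing-cell fraction per group; significance requires
|log2FC| ≥ 1.2, P ≤ 0.05 and fraction ≥ 0.3 in at least one group (the
"at least one group" reading is our resolution of an ambiguity). Motif
occurrence scans the DNA-alphabet hexamers {AATAAA, ATTAAA, AGTAAA,
ACTAAA, AAGAAA, AACAAA} in [−50, +25]; a site counts once regardless of
the number of hits, while positional profiles count every motif start.

## Synthetic data

The generator emulates the geometry the pipeline assumes, with defaults
chosen as the study conditions: 50 multi-exon genes (three exons, 600-nt
introns) on 2 chromosomes, 2–3 PASs per gene spaced 600 nt in a long last
exon, 200 cells, Poisson(0.5) molecules per site per cell (~100 reads per
site), read length 90. Each planted site carries (with probability
`polya_signal_strength`, default 1) AATAAA within [−30, −20], CA at the
junction and a 70%-T stretch at [+5, +25]. Read 5' starts are uniform in
[site − 400, site − 50] and reads are clipped so they end before the
cleavage position. Intergenic background contains Poisson-placed A/T
homopolymer runs (0.5/kb, lengths 6–15) mimicking the low-complexity
content of real intergenic sequence — without them, sampled negatives
would never show the classifier an A-rich window and the internal-priming
probe would be unrealistically hard. Internal-priming artifacts are
planted in 30% of genes as a 12-A run deep in the first intron with a
150-read upstream pile; the depth makes the pile's 5' edge densely
sampled, so the called 3' end lands within the A-run scan window (with
sparse piles the edge gap occasionally shifts the called end past the
window — an edge-sampling artifact of the fixture, not a filter
property). PCR duplicates re-emit the same (barcode, UMI) at a
configurable rate.

What the generator does **not** emulate: junction-spanning reads (start
windows are sized to fit within one exon; junction-spanning *peak
footprints* are exercised by unit fixtures instead), sequencing errors,
ambient RNA, doublets, barcode collisions beyond random 12-mers, realistic
base composition inside genes, or biological variation in peak width.
Passing tests therefore demonstrate the pipeline's correctness under its
own geometric assumptions, not performance on real libraries.

## Scale choices

Desk-scale problem sizes are used throughout the tests and the acceptance
script: a 500-site training split (5,000 shifted positives + 5,000
negatives), a quarter-width classifier, 50-gene/200-cell peak-calling
studies, and 500-feature/200-cells-per-group APA calibrations. These sizes
keep a full run in minutes while leaving every statistical conclusion
(recovery ≥ 90%, AUC ≥ 0.95, null false-flag ≤ 7%, power ≥ 90%)
comfortably away from its threshold.

## Known limitations

* The greedy fixed-width caller resolves sites no closer than ~the window
  width; adjacent PASs < 400 nt apart rely on the multimodality split.
* Dip p-values are Monte Carlo (200 null draws by default): p has ~0.5%
  resolution and the α = 0.05 decision is itself stochastic at the margin,
  though seeded and deterministic per run.
* UMI counting uses exact string identity; sequencing errors in UMIs would
  inflate counts on real data.
* The classifier's positional tolerance is bounded by the training shift
  distribution (σ = 10 nt, |offset| ≤ 90); tolerance degrades beyond
  ±40 nt, which matches the design rather than contradicting it.
* Differential-usage logFC is computed on CPM over PAS features only; on
  real data library-composition effects could bias CPM relative to a
  full-transcriptome normalisation.
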