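# Methods

This note documents the models and procedures implemented in identiscape,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not demonstrate
about real data. No empirical claim is made here beyond what the test suite
and `scripts/acceptance.py` themselves compute.

## Coordinates and interval algebra

All regions are 0-based half-open `[start, end)` (BED convention); TSS are
points tested with half-open membership, so a TSS at the exact end of a
region is outside it. Chromosome names are compared by exact string match
and strand is carried but ignored by overlap tests. `merge_intervals`
joins intervals whose gap is ≤ `max_gap` (gap 0 joins touching intervals,
which bridges no bases and therefore cannot change any ≥ 1 bp overlap
query — `overlap_any` exploits this by querying against the merged cover).

## Identity-gene calling

Per tissue, a peak is a **broad domain** iff its length is strictly greater
than `broad_multiplier × median(peak lengths)` (default multiplier 3; the
median of an even count is the mean of the two central values). The focal
tissue's broad domains are labelled by their **shared fraction**: the
number of other tissues whose *broad-domain* set overlaps the domain by
≥ 1 bp, divided by the number of other tissues. A domain is ID iff this
fraction is strictly below `specificity_threshold` (default 0.25), else
UBQ. Sharing is judged against other tissues' broad domains rather than
their raw peaks because breadth is the phenotype being compared; "detected
in" is operationalised as ≥ 1 bp overlap (the simplest testable rule —
no minimum reciprocal fraction is required, though the threshold is a
config knob). Genes take ID over UBQ when hit by both domain types so the
reported ID/UBQ lists are disjoint; genes under no broad domain are OTHER,
making the classification an exhaustive, exclusive partition of the
annotation. The tissue-specificity expression index is the mean over focal
replicates minus the mean over control tissues of each tissue's replicate
mean (a mean of means, so unequal replicate counts do not reweight
tissues).

## Differential acetylation regions

The upstream window-based differential engine is out of scope; this module
consumes its bin table (chrom, start, end, log2fc, pvalue). P-values are
BH-adjusted across all tested bins genome-wide — one FDR filter, not
per-peak. A bin is UP/DOWN iff FDR ≤ 0.05 and its fold change is
strictly positive/negative; a significant bin with log₂FC exactly 0 has no
sign and stays NS. Bins join the peak they overlap by ≥ 75 bp (largest
overlap wins; ties go to the leftmost peak; peaks must be pre-merged).
Per peak, with `u` UP and `d` DOWN bins, the region direction is UNCHANGED
if `u = d = 0`; UP if `d = 0 < u`; DOWN if `u = 0 < d` (the natural limits
of the ratio rule, flagged in output); otherwise `r = u/d` gives UP iff
`r ≥ 2`, DOWN iff `r ≤ 0.5`, and MIXED in the unnamed middle band, which
is excluded from UP/DOWN gene sets. Genes link to regions by TSS overlap
or a supplied distal-link table; class association uses Fisher 2×2 tables
of each gene class versus OTHER inside/outside each region category, with
BH correction across rows.

A statistical note on calibration that shapes the tests: with genuinely
changed regions present, the BH step-up threshold adapts to the
true-signal fraction (roughly `α × π₁ × power` per bin), so a small but
non-zero rate of null peaks acquiring one significant bin — and hence an
UP or DOWN label — is an unavoidable property of a single genome-wide FDR
filter, not an implementation defect. The test suite therefore checks
(a) near-zero false regions under the global null (rate ≤ 1.5× the nominal
FDR) and (b) a bounded false-call rate on null peaks in the mixed setting,
alongside ≥ 90% planted-direction recovery.

## Super-enhancers

Stitching is interval merging with a 12,500 bp gap; TSS exclusion distance
defaults to 0 (no masking), matching common practice for cofactor
cistromes. Stitched signal is the sum of member-peak scores (length is
used for unscored input). The cutoff implements the geometric tangent rule
discretely: signals sorted ascending, rank and signal min–max scaled to
[0, 1] (max scaling; some implementations use a high percentile — left as
a possible extension), and the cutoff is the unscaled signal at the first
index whose forward finite-difference slope reaches 1. Because the scaled
curve rises from 0 to 1 over a unit run, the mean slope is 1 and such an
index always exists; all-equal signals yield zero super-enhancers by
convention. `is_super` uses strict inequality, so enhancers tied with the
cutoff signal are not super. Flags are invariant under positive affine
rescaling of the signals (the scaling absorbs it).

## TF co-binding and cistrome enrichment

Occupancy is binary ≥ 1 bp overlap of an enhancer with any site of a TF.
Strata are closed integer ranges over the count of *additional* bound TFs
(focal excluded), defaulting to 0–2 / 3–5 / 6–8 for nine TFs; they must
tile the range exactly, and degrees above the top bound raise an error
rather than clipping silently. Empty strata report missing values, never
0%. Enrichment universes default to all tested regions (UP ∪ DOWN ∪
unchanged); each universe region contributes to a 2×2 table by exact
coordinate membership in the query and ≥ 1 bp overlap with the target set.
The p-value always comes from the uncorrected Fisher exact test; the log
odds ratio applies Haldane's +0.5 to every cell only when some cell is
zero, and is defined as exactly 0 when query and rest provide no contrast
(e.g. query = universe). Clustering of the log-odds matrix uses scipy's
Ward linkage on raw rows, which reproduces the ward.D2 agglomeration on
Euclidean distances (merge heights are checked against a naive
Lance–Williams implementation in the tests).

## Expression statistics

**Size factors** are DESeq-style median-of-ratios: per sample, the median
over all-positive genes of the count divided by the gene's geometric mean.
Factors are meaningful up to a common scale; multiplying one library by c
multiplies its factor *relative to the others* by c.

**Scaled fold changes**: genes in the lowest 20% of baseline-condition
mean expression are dropped (ties broken by gene id; the count is
⌊0.2 n⌋), then the whole retained matrix is z-scaled by one global mean
and one global SD (ddof = 1, matching R's `scale`), and the scaled fold
change is the difference of per-gene condition means on the scaled data —
equivalently raw log₂FC divided by the global SD, hence rank-identical to
the raw fold change within a dataset.

**Bagplot**: Tukey (halfspace) depth counts, for each data point, the
minimum number of points (itself included) in a closed halfplane bounded
by a line through it. Depth is computed exactly by an angular
rotating-halfplane sweep (O(n log n) per point) for n ≤ 5,000 and by 1,000
seeded random projection directions beyond that. The depth median is the
deepest point (centroid of the deepest set on ties). The bag starts as the
convex hull of the ⌈n/2⌉ deepest points (depth ties broken toward the
depth median) — but ties can leave extra equal-depth points strictly
inside that hull, so the polygon is shrunk about the depth median, via its
Minkowski gauge, to the largest size at which exactly ⌈n/2⌉ points are
inside-or-on; generic point sets are unaffected. The loop is the bag
inflated ×3 about the depth median (the classical default), and points
outside the loop are outliers. Collinear clouds are rejected with advice
to use a univariate summary.

**Quartile enrichment** ranks repressed genes (default gate: scaled fold
change < 0, configurable) from least to most repressed, splits them into
four near-equal groups with remainder genes in the earlier quartiles, and
reports each quartile's identity-gene fraction relative to Q1 (absolute
fractions with a flag when Q1 has none), with an overall chi-square test
and BH-corrected per-quartile Fisher tests against Q1. The ranking uses
the fold changes as provided; whether raw or scaled values are supplied is
the caller's choice.

**GSEA** implements the weighted running-sum statistic: hits add
|score|^weight normalized by the sum over hits, misses subtract 1/(N−m);
the enrichment score is the signed extremum, and with weight 0 the
statistic reduces to the classic Kolmogorov–Smirnov prefix form. The null
comes from seeded gene-set permutations (random same-size sets); NES
divides the ES by the mean |ES| of same-sign permutations and the FDR is
the same-sign tail fraction — the standard single-gene-set simplification.
The difference-of-classes ranking metric is provided as a helper; the
module otherwise takes the ranking as input.

## Developmental projection

Batch adjustment is location-only and reference-anchored: per gene, each
non-reference batch is shifted so its anchor-condition (control) mean
equals the reference batch's anchor-stage (adult) mean; the reference
batch is returned bit-identical. This is a deliberate, documented
approximation of mean-only empirical-Bayes batch correction: an optional
normal-prior shrinkage of the per-gene shifts toward the batch-wide mean
shift (method-of-moments hyperparameters) is available but off by default,
since with adequate anchor replication the plain mean adjustment is
unbiased and easier to reason about. PCA is fitted on reference samples
only, in covariance form (no unit-variance gene scaling), via SVD of the
reference-centered matrix; the PC1 variance fraction is the top squared
singular value over their sum. All other samples are supplementary: they
are centered by the *reference* gene means and projected onto the PC1
loadings, so a supplementary copy of a reference sample lands on the same
coordinate. Orientation is fixed by requiring the adult reference samples
to average a positive coordinate; coordinates are invariant to gene-wise
constant shifts. Prenatal-like stages may be kept in the fit and dropped
only from display by the caller.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of `SynthConfig`; the same seed gives
byte-identical output, and generators sharing a seed agree on the planted
gene classes. Defaults were chosen once as plausible desk-scale study
conditions and are not tuned per test:

- 10 tissues, 2,000 genes 50 kb apart on one chromosome, 200 identity and
  200 housekeeping genes, 3,000 peaks per tissue; background peak lengths
  lognormal (median 700 bp, σ = 0.45 — a typical promoter-peak size
  range); planted broad domains at 5× the tissue's median background
  length (comfortably past the 3× rule) with ×1.0–1.3 jitter, placed over
  identity-gene TSS in the focal tissue only and over housekeeping-gene
  TSS in every tissue.
- Differential bins: 10 bins per peak, planted |log₂FC| = 1 with
  bin-level noise SD 0.4 and exact z-test p-values (uniform under the
  null); 25% of peaks UP and 25% DOWN by default.
- Cistromes: nine TFs; co-binding degree drawn from Binomial(9, p₁) for
  inactivated enhancers and Binomial(9, p₀) otherwise with
  log[(p₁/(1−p₁))/(p₀/(1−p₀))] equal to the configured slope (default 1),
  which makes the log-odds of inactivation *exactly* linear in degree.
- Expression: stage profiles `b + (s − 1)·v` with identity genes rising by
  2 log₂ units from newborn (s = 0) to adult (s = 1) and a planted fetal
  set falling; per-entry noise SD 0.3; per-study gene-wise batch offsets
  (SD 1); injured samples at dedifferentiation weights w ∈ {0, 0.25, 0.5,
  0.75, 1} (stage 1 − w); a stress study repressing identity genes by the
  effect size and inducing a planted stress set; Poisson single-cell
  counts around size-scaled adult means (300 cells).

What passing on these fixtures shows: the rules and statistics are
implemented correctly and recover planted structure under their own
assumptions at realistic effect sizes. What it does not show: robustness
to the messiness of real data — peak-caller artefacts, copy-number and
mappability biases, correlated bins, overdispersed counts, partially
shared domains between related tissues, or batch effects that change
variance rather than location. Those require the real upstream engines
this package deliberately consumes rather than reimplements.

## Problem sizes and numerical choices

Seed-swept checks use 20 seeds; the identity sweep runs 10 tissues × 3,000
peaks per seed and the projection sweep 2,000 genes × ~36 samples —
desk-scale sizes chosen so the whole suite and the acceptance script each
complete in seconds while leaving the planted-recovery margins wide.
Oracle-equivalence tests (interval merge closure, exhaustive Tukey-depth
direction scan, brute-force tangent search, naive Ward agglomeration,
dense eigendecomposition) assert agreement to 1e-9 or exact integer
equality. Floating-point tie handling: bag membership uses a 1e-9 relative
gauge tolerance; depth computations use exact comparisons on the input
coordinates.

## Known limitations

- The differential engine (loess normalization, quasi-likelihood bin
  tests) is upstream; the built-in z-test exists only for the synthetic
  pipeline.
- Super-enhancer signal is unsubtracted peak-score sum; input-control
  subtraction belongs upstream.
- The GSEA FDR is the single-set permutation tail, not the multi-set
  normalized-ES pooling of the full algorithm.
- The batch adjustment corrects locations only (by design); variance
  differences between studies pass through to the projection.
- Exact Tukey depth is quadratic-time in n per call; beyond 5,000 points
  the seeded projection approximation is used.
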