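# Methods

`mirprofiler` re-implements, as a tested library and CLI, the computational
workflow of a five-class miRNA microarray study of hereditary breast
carcinomas: BRCA1- and BRCA2-associated carcinomas (BRCA1-C, BRCA2-C),
normal breast tissue from carriers of either mutation (BRCA1-N, BRCA2-N),
and normal tissue from non-carriers (Healthy-N). This note documents the
models, parameter choices, numerical conventions and known limitations.

## Preprocessing

Raw median fluorescence intensities are floored at a threshold (default 1),
log2-transformed, and percentile-shift normalized: each sample's 75th
percentile of log2 intensities (computed across probes, linear
interpolation — the type-7 convention used by numpy's default and common
spreadsheet software) is subtracted from that sample, so every sample's
post-shift 75th percentile is exactly 0. The presence filter then keeps a
probe iff there is at least one class in which *every* sample's normalized
value lies at or above that sample's 50th percentile. Two conventions were
genuinely open and are fixed here: the band's lower bound is inclusive
(the conservative reading; the upper bound at the 100th percentile is
vacuous), and the filter operates on normalized values, i.e. after the
percentile shift (matching the order in which the operations are
described). Filtering order is recorded in the pipeline config.

## Differential expression

Two-class comparisons use Welch's unequal-variance t-test
(Welch–Satterthwaite degrees of freedom, two-sided p); three or more
groups use Welch's heteroscedastic F. Probes whose two groups are constant
and equal get p = 1 by convention and a log message rather than an
exception. p-values are adjusted per comparison with Benjamini–Hochberg
step-up over exactly the probes in the tested (presence-filtered) matrix.
Fold change is computed from normalized log2 group means as
2^(Δmean), reported as a magnitude ≥ 1 plus an up/down direction; a probe
is called differentially expressed iff FC ≥ 1.5 **and** q < 0.05 (both
thresholds configurable; FC ≥ 2.0 is the conventional stricter input for
downstream pathway tools). Top-k rankings sort by q ascending, then FC
magnitude descending, then probe id — the final tie-break makes ranked
output reproducible. The two "axes" (BRCA1-C vs BRCA1-N and BRCA2-C vs
BRCA2-N) are intersected into shared and axis-specific calls; a probe
called in opposite directions by the two axes is excluded from the shared
set and surfaced in a direction-conflict report.

### A calibration caveat that matters at this design's sample sizes

Welch's p-value is a moment approximation whose deep tail degrades when
one group is small. Direct simulation (4 × 10^6 Gaussian null replicates)
at this study's axis-1 sizes (17 vs 5) gives
P(p < t)/t ≈ 2.5 at t = 10^-3, ≈ 4.7 at 1.3 × 10^-4 and ≈ 6.3 at
5 × 10^-5, whereas the balanced 17-vs-17 case is essentially calibrated
(ratio ≈ 0.9). The probability that BH rejects *anything* under a global
null is governed by exactly these deep-tail quantiles (p(i) ≤ q·i/m), so
with m = 862 probes the family-wise any-call rate is ≈ 0.25 rather than
the nominal ≈ 0.05, and the FC ≥ 1.5 conjunction does not repair it: the
false positives come from underestimated within-group variance, not from
small mean differences. Per-test calibration at ordinary α (0.05) is fine,
and the suite verifies it on the balanced 5-vs-5 comparison. The
acceptance suite keeps a deliberately failing test documenting the
family-wise property; users of this design should treat isolated
borderline calls in the unbalanced comparisons with suspicion — this is a
property of the published method at these sample sizes, not of this
implementation.

## Chromosomal analysis

Loci are parsed from annotation strings of the form
`Chr21q21.1:17911409-17911489 [+]` (1-based closed intervals; both ASCII
hyphen-minus and the Unicode minus are accepted as the reverse-strand
glyph). Probes without a parseable locus are retained in the expression
analysis but tallied separately (`n_unlocalized`) and excluded from all
chromosomal statistics. The two axes' per-chromosome count vectors are
compared with a Freeman–Halton-style exact test on the 2×K table
(zero-margin chromosomes dropped): the p-value is the fixed-margin
probability of a table at most as probable as the observed one, estimated
by Monte-Carlo with Patefield sampling (default 100,000 tables, seeded);
the reported statistic is the observed table's Pearson chi-square and is
labeled as such, since exact-test software differs in which statistic it
prints. Hotspots are loci — chromosome + cytoband, with a 1-Mb
coordinate-bin fallback for band-less loci — carrying ≥ 4 called miRNAs in
one axis; direction consistency and cross-axis sharing are annotated.
Fragile-site overlap is the fraction of *localized* called probes whose
locus matches a catalog entry (cytoband match including band/sub-band
containment, or coordinate overlap; BED input is converted from 0-based
half-open to 1-based closed).

## qPCR relative quantification

Replicate Ct values are averaged on the cycle scale first; ΔCt is the
target's mean Ct minus the reference miRNA's (miR-125a-5p by default) per
sample. Two instrument cohorts are harmonized through samples measured on
both: per target, the offset is the mean over shared samples of
(ΔCt_cohort1 − ΔCt_cohort2), subtracted from all cohort-1 values — the
mean-offset rule is one reasonable reading of replicate-based
cross-cohort normalization and is isolated in a single operation.
ΔΔCt subtracts the baseline-class (Healthy-N) mean per target; RQ =
2^(−ΔΔCt) with amplification efficiency fixed at 2.0. Class comparison
uses the tie-corrected Kruskal–Wallis test on ΔCt values (not on RQ) with
significance at p ≤ 0.01, the stricter level conventional when several
classes are compared; a fully tied input is flagged degenerate (H = 0,
p = 1). Pairwise post-hoc comparisons are not part of the core workflow.

## SOM clustering

Probes and samples are clustered on rectangular self-organizing maps
(defaults: 6×6 grid, 100,000 iterations for probes; 3×3, 20,000 for
samples; initial learning rate 0.02). Items are mean-centered per vector;
the best-matching node is chosen under the Pearson-centered distance
d = 1 − r, while node updates average in vector space (standard SOM
practice). The schedule — exact composition undocumented in classic
desktop clustering tools — is a config constant: at step t of T one item
(cyclic over a seeded shuffle) updates all nodes within a hard Euclidean
grid radius shrinking linearly from the grid diagonal to 0, with learning
rate lr0·(1 − t/T); nodes initialize as a seeded sample of distinct items.
For display, items are ordered by node index and, within each node, by
complete-linkage hierarchical ordering under the same distance; the
ordered matrix is written as a CDT file readable by TreeView-style
viewers. Like any sequential SOM, the map can leave dead units and merge
adjacent clusters on pathological geometries; the suite asserts the
qualitative claim that matters here — carcinoma and normal samples do not
mix — on study-like synthetic data.

## Cross-study consensus

Published study findings are aggregated per (miRNA, direction):
concordant-study count, total samples of supporting studies, and the mean
of the fold-change magnitudes those studies supplied (entries whose mean
rests on a single value are flagged). Ranking is vote-counting — study
count, then total samples, then average FC, then miRNA id — with a
minimum of two concordant studies; direction-conflicted miRNAs produce
separate up and down entries plus a conflict report, never a silent drop.
No pooled effect-size model is fitted: with per-study variances
unavailable, rank-based vote counting is the defensible aggregation. The
bundled six-study compilation encodes each study's findings and sample
total; per-study totals are explicit inputs because published study
descriptions mix counting conventions (pairs vs samples, tumors vs
tumors + normals). Fold changes are included only where individually
attributable — the two-study rows whose printed range identifies both
values; rows with ≥ 3 studies or a single-value average carry no FC rather
than an invented attribution. Reported averages round half-up
(2.005 → 2.01), matching how printed tables round.

## Synthetic data

The generator emulates the study design, not array physics. Raw
intensities are 2^(baseline + class effect + ε): per-probe baselines from
Normal(6, 2) log2 units truncated at 0 (a realistic dynamic range whose
lower tail exercises the floor rule), ε probe-independent Gaussian with
default sd 0.5 log2 units (typical within-class variability for FFPE
arrays), class sizes 17/9/5/5/10. Planted effects add ±2 log2 units to
the carcinoma class of the affected axis (both classes for shared
probes); the default planted design mirrors the study footprint — 145
axis-1, 96 axis-2, 53 shared DE probes with 41/8 up-regulated per axis,
shared down-regulated hotspots at 5q32, 14q32.2, 14q32.31 and 21q21.1, an
axis-1 up-regulated hotspot at 7q32.2, 44/20 axis-specific probes with
unknown loci, and a fragile-site catalog covering 20.8% of localized
axis-1 DE probes. Planted DE probes sit on expressed baselines (clipped
to ≥ mean + 1.5) because the study only ever calls probes that pass its
presence filter; every non-hotspot probe receives a unique cytoband so no
hotspot can arise by accident, and fragile-site entries are drawn from
non-hotspot probes so one catalog band cannot sweep in co-located probes.
An 862-probe synthetic matrix represents the *post-filter* probe set (the
BH family of the published analysis); recovery evaluations therefore do
not re-apply the presence filter, which has its own planted 2006→862-style
tests. The generator does not emulate probe-probe correlation, dye or
spatial artifacts, or batch structure — passing recovery tests show the
statistics recover planted signal under idealized noise, not that the
pipeline is robust to real array artifacts.

qPCR simulation: Ct = ref_Ct − log2(relative expression) + cohort offset
+ Normal(0, tech_sd) per replicate (duplicates by default; tech_sd 0.1
cycles; ref_Ct 20). The planted inter-cohort offset (default 1.5 cycles)
is applied to target assays only, emulating assay-chemistry differences
that survive reference normalization — exactly what shared-replicate
harmonization must remove. Study-list simulation reports each miRNA
independently per study with a configurable report probability and
direction-flip probability; a deterministic variant plants an exact
multi-study overlap structure (e.g. 15 of 92 up-regulated miRNAs in ≥ 2
studies).

One global seed feeds fixed-index `SeedSequence` streams per artifact, so
adding an artifact never perturbs the others and a fixed seed yields
byte-identical files.

## Determinism and problem sizes

All randomness (Monte-Carlo exact test, SOM, generators) flows from named
seeds; pipeline reruns from one config are byte-identical, manifest
included. The test suite and the acceptance script size their simulations
to run comfortably on one CPU: 1,000 replicate null datasets of 862
probes for the calibration measurement, the full 862-probe planted design
for recovery, 10^5 Monte-Carlo tables per exact test, and a 500-probe
demo dataset (reduced SOM schedules: 4×4/4,000 and 2×2/1,000) for the
end-to-end determinism check.
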