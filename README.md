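# mirprofiler

A reusable, tested implementation of a five-class miRNA microarray
analysis workflow for hereditary breast cancer: carcinomas and normal
breast tissue from BRCA1 and BRCA2 germ-line mutation carriers plus
normal tissue from non-carriers (classes `BRCA1-C`, `BRCA2-C`, `BRCA1-N`,
`BRCA2-N`, `Healthy-N`). It is aimed at transcriptomics analysts who want
the individual stages of such a study — or the whole pipeline — as
scriptable, seedable, unit-tested operations rather than point-and-click
steps.

The stages, each its own module with a matching CLI subcommand:

- **preprocess** — intensity floor at 1, log2, per-sample 75th-percentile
  shift normalization, and the presence filter that keeps a probe iff all
  samples of at least one class express it at or above their per-sample
  median.
- **diffexpr** — per-probe Welch t-test (Welch ANOVA for ≥3 groups),
  Benjamini–Hochberg FDR per comparison, fold change from normalized log2
  means (FC = 2^Δ, magnitude + direction), DE call iff FC ≥ 1.5 and
  q < 0.05, top-k ranking by (FDR, then FC), and the two-axis
  shared/specific intersection.
- **chromosomal** — per-chromosome counts of called miRNAs (unknown loci
  tallied separately), a Monte-Carlo Freeman–Halton exact test on the 2×K
  axis-by-chromosome table, cytoband hotspot detection (≥4 miRNAs at one
  locus), and fragile-site overlap fractions.
- **qpcr** — comparative-Ct quantification: replicate means, ΔCt against
  a reference miRNA (miR-125a-5p), two-cohort harmonization via shared
  replicate samples, ΔΔCt against the Healthy-N baseline, RQ = 2^(−ΔΔCt),
  and Kruskal–Wallis class comparison at p ≤ 0.01.
- **som_cluster** — self-organizing maps over probes (6×6) and samples
  (3×3) under the Pearson-centered distance 1 − r, with complete-linkage
  ordering inside nodes and CDT export for heatmap viewers.
- **consensus** — cross-study vote counting: per (miRNA, direction) the
  number of concordant studies, the sample-weighted total, and the average
  fold change, ranked in that key order.
- **synthetic** — generators for all of the above with known ground
  truth: planted per-class effects, hotspot and fragile-site annotations,
  two-cohort Ct tables, and multi-study DE lists with controllable
  concordance.

See `docs/methods.md` for the statistical conventions, parameter
defaults, and known limitations (including a documented deep-tail
calibration caveat of Welch's test at this design's unbalanced sample
sizes).

## Worked example

Rank the bundled six-study breast-cancer literature compilation (per-study
sample totals: Chen 24, Iorio 110, Ouyang 6, Tahiri 58, Tanic 36, Yan 8):

```bash
$ profiler consensus --studies src/mirprofiler/data/literature_studies.csv --out consensus.csv
up: 15/15 (100.0%) in >= 2 studies
down: 15/15 (100.0%) in >= 2 studies
wrote consensus.csv
$ head -5 consensus.csv
mirna_id,direction,n_studies,studies,total_samples,avg_fc,fc_range,single_value_fc
hsa-miR-21,up,5,"Chen, Iorio, Tahiri, Tanic, Yan",236,,,False
hsa-miR-155,up,3,"Iorio, Tahiri, Yan",176,,,False
hsa-miR-210,up,2,"Iorio, Tahiri",168,2.23,1.43-3.03,False
hsa-miR-149,up,2,"Iorio, Tahiri",168,1.94,1.08-2.8,False
```

Reading the output: miR-21 tops the ranking because five studies
(236 samples in total) report it up-regulated concordantly; miR-210
outranks miR-149 — same study count, same 168 samples — on its larger
average fold change (2.23, from the two studies' 1.43 and 3.03). The
overlap lines say every miRNA in this compilation is backed by at least
two studies, which is true by construction: the file contains only the
multi-study rows, with fold changes included only where individually
attributable to a study. `avg_fc` is blank where per-study attribution
is not possible.

Generate a planted synthetic study and run the whole pipeline on it:

```bash
$ profiler simulate --seed 7 --out demo --run
demo dataset written to demo
results written to demo/results
```

`demo/results/` then contains the normalized matrix and filter report,
per-comparison DE tables with a Table-style summary of up/down counts,
the shared/axis-specific intersection and top-10 listings, chromosome
distributions with the exact-test p-value, hotspot and fragile-site
reports, the SOM-ordered CDT heatmap, ΔΔCt/RQ/Kruskal–Wallis qPCR tables,
the consensus ranking, and a manifest with the config hash and seeds.
`demo/truth.json` holds the planted ground truth for comparison.

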