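# Methods

This note documents the statistical models behind `qimbalance`, the
conventions and defaults that matter for interpreting its output, and the
design choices made where more than one reasonable convention exists.

## Quality-imbalance metrics

Sample quality enters the package exclusively as `P_low ∈ [0, 1]`, the
per-sample probability of being of low quality produced by an external
classifier. The package deliberately does not model how `P_low` is
obtained; it is a measurement.

**Point-biserial QI (default).** `QI = |corr(P_low, g)|` with `g` the 0/1
group code. Since one variable is dichotomous this equals the point-biserial
correlation; it is invariant to which group is coded 1 and bounded in
[0, 1]. Cutoffs: < 0.18 low, > 0.30 high, strict inequalities (a value at a
cutoff is *intermediate*). Cutoffs are configurable everywhere they are
used.

**Spearman variant.** The absolute rank correlation, invariant under any
strictly increasing transform of `P_low`; same cutoffs. Note that because
the binary group codes are midrank-tied, the maximum attainable value is
slightly below 1 (e.g. 2/√5 ≈ 0.894 for 2+2 samples); the classification
cutoffs are far from this regime, so the bound has no practical effect.

**CTDiff.** `|median(P_low|control) − median(P_low|disease)|` divided by the
mean absolute difference over all unordered sample pairs *pooled across
groups*. Non-negative and scale-invariant, with no upper bound; cutoffs
0.5 / 1. The original formulation of the central-tendency-difference
statistic is not fully specified in our sources with respect to pooled
versus within-group pair differences; the pooled reading is implemented and
is not silently switchable — the denominator convention is a documented
constant of the implementation.

**Degenerate input policy.** Constant `P_low`, or a group too small for the
metric, raises `DegenerateInputError` rather than returning 0: a silent
zero would classify a broken dataset as perfectly balanced.

**Quality outliers.** Tukey fences on the pooled `P_low` values:
a sample is an outlier if it lies beyond `Q3 + 1.5·IQR` or `Q1 − 1.5·IQR`,
with linear-interpolation quantiles (numpy's default, matching the common
`is_outlier`-style helpers; the interpolation rule is a parameter).

## Synthetic data generator

The generator emulates the structure the analysis assumes — it is a tool
for validating the pipeline's statistical behaviour, not a model fitted to
any real dataset.

**Counts.** `K_ij ~ NB(mean μ_ij, dispersion α_j)` with

```
μ_ij = s_i · b_j · 2^( β_dis,j·g_i + β_q,j·q_i + π_{j,pair(i)} )
```

- `q_i ∈ [0, 1]`: latent per-sample quality, reported as `P_low,i = q_i`
  (identity link — the classifier is treated as a perfect probe; classifier
  noise can be emulated by lowering the quality effect);
- `s_i`: log-normal size factor, log-sd `libsize_sd` (default 0.2);
- `b_j`: log-normal baseline (log-mean 4, log-sd 1 → median ≈ 55 counts);
- `α_j ~ Gamma(shape 2, scale 0.05)` (mean dispersion 0.1, typical for bulk
  RNA-seq);
- `β_q,j`: +e for planted low-quality markers, −e for high-quality markers,
  0 otherwise (default e = 2 on the log2 scale — a strong but realistic
  degradation response);
- `β_dis,j`: for planted disease genes, random sign and magnitude
  `d·U(0.5, 1.5)` so the planted disease genes form a ranked list; 0
  otherwise;
- `π_{j,p}`: optional per-pair, per-gene normal effect (sd `pair_sd`,
  default 0.3) shared by the two samples of a pair, giving a paired design
  something to absorb.

**QI targeting.** Within each group, `q` is Beta-distributed with common
concentration κ (`quality_concentration`, default 10) and group means
`0.5 ∓ δ/2`. The gap δ is found by bisection so that the *population*
point-biserial correlation

```
r(δ) = δ·√(p(1−p)) / √( (1−p)·Var₀ + p·Var₁ + p(1−p)·δ² )
```

matches `qi_target` to within 0.02. Unreachable targets (possible at low κ)
raise `CalibrationError` carrying the achievable bound. The realized QI of
each emitted dataset is recorded in its ground-truth record; across
replicates its mean tracks the target to well within ±0.1 for targets in
[0.2, 0.8]. At `qi_target = 0` the realized value is the null |point-biserial|,
whose mean at n = 20 is √(2/π)/√19 ≈ 0.18 — a sampling floor, not a bias.

**Planted outliers.** `n_outliers` samples (preferentially in the disease
group, so that they confound the contrast) have `q` redrawn from a Beta
concentrated at `outlier_p_low` (default 0.95). This emulates the common
real situation of a few badly degraded samples on one side of the
comparison.

**Peak data.** The ChIP-seq-like generator places one candidate peak per
500-bp bin of a toy chromosome, present per sample with probability 0.8;
log2 enrichment is normal around a per-bin baseline with the same
`β·q` quality effect in marker bins. Peaks lie within bins by construction
in the generator; the binning code itself handles bin-spanning peaks and is
tested against a brute-force overlap oracle.

**Collections.** Marker-derivation scenarios share marker gene identities
across datasets while disease genes differ per dataset; dataset k uses seed
`base_seed + k`. All generator output is byte-identical for identical
configuration.

## Differential expression

`de.run_de` wraps the pydeseq2 negative-binomial GLM: median-of-ratios size
factors, per-gene dispersion estimation, Wald test of the group
coefficient, BH adjustment across tested genes. Design options: a pairing
factor, and sample quality as the continuous covariate `1 − P_low` (so
higher-quality samples carry the higher covariate value). Genes with
all-zero counts are flagged untested and excluded from the BH family.
Independent filtering, Cook's-distance filtering/refitting and fold-change
shrinkage are disabled by default: defaults aim at calibrated raw
statistics rather than any particular release's post-processing, and exact
numerical parity with a specific DESeq2 version is explicitly not a goal —
the engine is validated by calibration (null false-positive rate ≲ 0.1% at
BH < 0.05 in the battery) and by recovery of planted effects.

Significance: padj < 0.05 and |log2FC| > 1, both strict; the fold-change
gate can be dropped (`use_lfc=False`). Top-gene ranking: padj ascending,
ties by |log2FC| descending, then gene id — a deterministic total order.

## Markers and recurrence

Gene–quality correlations are Pearson correlations between
`log2(count/size_factor + 1)` and `P_low` (the expression scale is a
parameter: raw / normalized / log2; the log scale is the default because
the NB model is log-linear in quality). Zero-variance genes are excluded
with a flag, never reported as r = 0. Calls: low-quality marker r > 0.4,
high-quality marker r < −0.4, strict. The threshold is the only gate — no
secondary p-value filter — because at the 16–20-sample scale |r| > 0.4
corresponds to p ≲ 0.08 and the recurrence requirement provides the real
error control.

Recurrence counts N per direction across datasets; a feature conflicting in
direction contributes to each direction separately and only enters the
catalog where that direction's N ≥ `min_datasets` (default 2). The
recurrence table reports cumulative counts (features with N ≥ k), hence is
non-increasing in k.

Bins: fixed 500-bp tiles, 0-based half-open; a peak contributes to every
bin it overlaps; per bin and sample the count and min/max/mean enrichment
are kept. Bin–quality correlations use mean enrichment with absent-peak
cells as 0 (restricting to peak-bearing samples is the configurable
alternative), require peaks in ≥ 3 samples, and call markers at |r| > 0.3 —
looser than for genes because binning and bin-to-gene annotation add noise.
Bin-to-gene annotation maps each bin to the nearest TSS on the same
chromosome (distance from bin midpoint; ties to the smaller coordinate,
then lexicographic gene id).

## Enrichment

One-sided hypergeometric upper-tail test per gene set after intersecting
sets with the stated universe; sets outside [15, 500] genes (after
intersection) are skipped. Default adjustment is Bonferroni (the convention
of the marker-regulator analyses this mirrors); BH is available. The
universe defaults to the genes tested in the originating analysis.

## Subsets, proportions, mitigation

**Subsets.** Per group, the `pool_size` (15) samples with the lowest
`P_low` form the top-quality pool and the 15 with the highest the
bottom-quality pool (ties break by sample id; pools overlap when a group
has fewer than 30 samples). Per iteration one 10-sample group is drawn from
each pool and combined into the four combos BB, BT, TB, TT, each drawn
group serving in two combos; 3 iterations give 12 subsets. Each subset's QI
is computed on its own 20 samples, and the response curve is an OLS fit of
subset DEG count on subset QI.

**Proportions.** For datasets with ≤ 50 samples, ≥ 500 DEGs and ≥ 50 known
disease genes (inclusive boundaries), the marker proportion is the share of
catalog markers (N ≥ 2, either direction) among the top 500 DEGs, and the
disease proportion the share of the top 50 known disease genes found in the
top 500 DEGs. OLS of proportion on QI is fitted separately for paired and
unpaired datasets.

**Mitigation.** Two strategies: refit with the `1 − P_low` covariate, or
remove IQR quality outliers before testing (or both). Evaluation: split
significant genes by log2FC sign, run ORA on each list, define *low-quality
pathways* as sets enriched in low-quality markers, and compare the
percentage of low-quality pathways among differential pathways with and
without the strategy. Verdict per sign: `better` / `worse` when the overlap
percentage changes by at least 15% *relative to baseline* (the absolute
percentage-point reading is available via `relative=False`; the 15% rule's
reference is ambiguous in common usage, so the choice is explicit and
configurable), `excluded` when the baseline overlap is zero pathways,
otherwise `no_change`.

## Evaluation battery: problem sizes and what passing shows

`qimbalance.benchmarks` fixes the scenarios used by the acceptance tests
and `scripts/acceptance.py`. Chosen sizes:

- numerical cross-checks: 1000 random cohorts (n ∈ [8, 96]) for the QI
  index; 200 instances (n ≤ 30) for CTDiff; 40 ORA instances with
  universes ≤ 25 genes (where exhaustive enumeration is exact);
- null calibration: 10 replicates of 2000 null genes, 10+10 samples;
- DEG-inflation ladder: QI targets {0, 0.5, 0.9}, 10 replicates each,
  1000 genes with 300 quality-affected genes (effect 2);
- marker recovery: 13 low-QI datasets (target 0.1), 2000 genes, 200+200
  shared markers;
- subset builder: one 30+30-sample source with broad within-group quality
  (κ = 1.5), 1000 genes;
- proportion ladder: 5 QI levels × 5 replicates, 2000 genes with 400+400
  markers and 100 disease genes at effect 0.7 — sized so that the top-500
  cut is selective and dilution of disease genes is visible at desk scale;
- mitigation: 10 replicates of 800 genes, 60+60 markers at effect 4, four
  planted outliers at `P_low ≈ 0.97` with tight within-group quality
  (κ = 40) so the outliers are detectable by the IQR rule; the pathway
  layer uses FDR-only gene selection, which at this problem size gives the
  enrichment step measurable signal.

These scenarios demonstrate internal correctness and the direction and
rough magnitude of the quality-imbalance effects under the generator's
assumptions. They do not establish effect sizes in real data: the generator
has no batch structure, no correlated gene modules beyond the planted
roles, an error-free quality probe (`P_low = q`), and log2-linear effects.
Real datasets will show the same phenomena only to the extent these
assumptions approximate them.

## Known limitations

- The QI index measures linear association of `P_low` with the group code;
  non-monotone confounding (e.g. both tails degraded) is invisible to it.
- The ChIP-seq path consumes peak calls; peak calling, blacklists and
  genome builds are out of scope, and enrichment for bin-derived gene lists
  uses ORA rather than a ranked permutation test.
- Marker calling at fixed |r| thresholds is sample-size dependent; the
  defaults follow the 16–30-sample regime the method targets.
- `pydeseq2` is the single differential engine; results at very small
  counts or extreme designs inherit its behaviour.
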