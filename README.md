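# qimbalance

Quality-imbalance analysis for case/control sequencing studies.

In bulk RNA-seq (and ChIP-seq) case/control datasets, per-sample quality is
often confounded with the comparison groups: if the disease samples happen to
be of systematically lower quality than the controls, genes that respond to
sample degradation masquerade as disease genes. `qimbalance` quantifies this
confounding, identifies the genes (and genomic bins) that track quality,
measures how the confounding inflates differential-expression results, and
evaluates two mitigation strategies. It is aimed at bioinformaticians
auditing public datasets or their own study designs, and every analysis can
be exercised end to end on synthetic data with known ground truth.

Per-sample quality enters as `P_low`, the probability that a sample is of
low quality, as produced by an upstream quality classifier — `qimbalance`
treats it as an input measurement.

## The quality-imbalance (QI) index

For a dataset with binary group codes `g_i ∈ {0, 1}` (control/disease) and
quality probabilities `p_i = P_low,i`, the QI index is

```
QI = | corr(p, g) |
```

the absolute Pearson correlation, which for a dichotomous variable is the
point-biserial correlation `(M1 − M0)/σ_p · √(n1·n0)/n`. QI = 0 means quality
and group are unconfounded; QI = 1 means fully confounded. A dataset with
QI < 0.18 is classed *low*, above 0.30 *high*. Two alternative metrics are
provided: the absolute Spearman correlation (same cutoffs) and the central
tendency difference

```
CTDiff = | median(p | control) − median(p | disease) | / mean_{i<j} |p_i − p_j|
```

with cutoffs 0.5 and 1.

Around the index, the package implements:

- **marker discovery** (`qimbalance.markers`): genes whose
  log2-normalized expression correlates with `P_low` at |r| > 0.4
  (low-quality markers: positive r; high-quality markers: negative r),
  aggregated into a cross-dataset recurrence catalog; the ChIP-seq analogue
  assigns peaks to 500-bp genomic bins and correlates per-bin mean
  enrichment at |r| > 0.3;
- **differential expression** (`qimbalance.de`): negative-binomial GLM Wald
  tests (via pydeseq2) with optional pairing factor and optional `1 − P_low`
  continuous covariate, BH adjustment, significance at padj < 0.05 and
  |log2FC| > 1;
- **quality-stratified subsets** (`qimbalance.subsets`): fixed-size
  10+10-sample subsets drawn from top-/bottom-quality pools to isolate the
  QI effect on DEG counts from the sample-size effect;
- **over-representation analysis** (`qimbalance.enrich`): one-sided
  hypergeometric tests against GMT gene-set collections, Bonferroni by
  default;
- **reproducibility & mitigation** (`qimbalance.repro`): proportions of
  quality markers / known disease genes among the top 500 DEGs as a
  function of QI, and the covariate / IQR-outlier-removal mitigation
  strategies judged by the ≥15% change rule on low-quality-pathway
  contamination;
- **a synthetic-data generator** (`qimbalance.synth`): negative-binomial
  counts with log2-linear planted quality and disease effects, a latent
  per-sample quality driving `P_low`, library-size variation, optional
  pairing and planted quality outliers, and a calibrated, tunable QI level.

## Worked example

```python
import qimbalance as qb
from qimbalance import de

cfg = qb.SimConfig(n_control=10, n_disease=10, n_genes=1000,
                   n_low_markers=150, n_high_markers=150, n_disease_genes=50,
                   quality_effect=2.0, disease_effect=2.0,
                   qi_target=0.8, seed=1)
counts, samples, truth = qb.simulate_dataset(cfg)

print(qb.qi_pearson(samples))
result = de.run_de(counts, samples)
print(len(de.significant_genes(result, use_lfc=False)))
result_cov = de.run_de(counts, samples, use_quality_covariate=True)
print(len(de.significant_genes(result_cov, use_lfc=False)))
```

prints

```
QIResult(metric='pearson', value=0.8079836992341856, qi_class='high', n_samples=20)
251
54
```

The simulated dataset is heavily confounded (QI ≈ 0.81, class *high*).
Of the 251 genes significant at BH < 0.05, 184 are planted quality markers
and only 50 are true disease genes (17 are false positives on null genes) —
quality imbalance has tripled the apparent signal. Adding `1 − P_low` as a
covariate collapses the list to 54 genes, close to the planted disease
signal.

The same workflow is available from the shell:

```
qimbalance simulate --seed 1 --outdir run/ --qi-target 0.8
qimbalance qi --samples run/samples.tsv
qimbalance de --counts run/counts.tsv --samples run/samples.tsv --out run/de.tsv
qimbalance demo --seed 1 --outdir demo/
```

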