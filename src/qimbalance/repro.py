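"""Reproducibility metrics and quality-imbalance mitigation evaluation.

Quantifies how quality imbalance degrades the biological relevance of
differential-gene lists — the share of quality markers among the top
differential genes rises with the QI index while the share of known
disease genes falls — and evaluates two mitigation strategies:

* **covariate** — refit the differential model with 1 - P_low as a
  continuous covariate;
* **outlier_removal** — drop samples whose P_low lies beyond 1.5 x IQR
  Tukey fences before testing.

A strategy is judged per dataset and per fold-change sign on the share of
*low-quality pathways* (gene sets enriched in low-quality markers) among
the *differential pathways* (sets enriched in the up- or down-regulated
significant genes): a relative decrease of at least 15% is ``better``, a
relative increase of at least 15% ``worse``, otherwise ``no_change``;
datasets whose baseline overlap is zero pathways are ``excluded``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import de, enrich, qi
from .exceptions import DegenerateInputError
from .markers import MarkerCatalog
from .tables import validate_sample_table


@dataclass(frozen=True)
class ProportionResult:
    """Share of a reference gene list among the top differential genes."""

    dataset_id: str
    qi_value: float
    paired: bool
    kind: str  # marker_in_deg | disease_in_deg
    numerator: int
    denominator: int

    @property
    def proportion(self) -> float:
        return self.numerator / self.denominator


@dataclass(frozen=True)
class MitigationReport:
    """Outcome of one mitigation strategy on one dataset and DEG sign."""

    dataset_id: str
    strategy: str
    deg_sign: str  # pos | neg
    baseline_overlap_pct: float
    mitigated_overlap_pct: float
    baseline_overlap_count: int
    verdict: str  # better | worse | no_change | excluded


def eligible_datasets(
    datasets: pd.DataFrame,
    max_samples: int = 50,
    min_degs: int = 500,
    min_disease_genes: int = 50,
) -> pd.DataFrame:
    """Filter datasets for the proportion analyses.

    Expects columns n_samples, n_degs, n_disease_genes. Boundaries are
    inclusive: <= max_samples, >= min_degs, >= min_disease_genes.
    """
    mask = (
        (datasets["n_samples"] <= max_samples)
        & (datasets["n_degs"] >= min_degs)
        & (datasets["n_disease_genes"] >= min_disease_genes)
    )
    return datasets[mask]


def marker_proportion_in_degs(
    top_degs: list[str],
    catalog: MarkerCatalog,
    dataset_id: str = "dataset",
    qi_value: float = float("nan"),
    paired: bool = False,
    min_datasets: int | None = None,
) -> ProportionResult:
    """Share of catalog quality markers (either direction) in the top DEGs."""
    if not top_degs:
        raise ValueError("empty top-DEG list")
    if catalog.table.empty:
        raise ValueError("empty marker catalog")
    markers = catalog.features(min_n=min_datasets)
    numerator = len(set(top_degs) & markers)
    return ProportionResult(dataset_id, qi_value, paired, "marker_in_deg",
                            numerator, len(top_degs))


def disease_gene_proportion(
    top_degs: list[str],
    disease_genes: list[str],
    top_k: int = 50,
    dataset_id: str = "dataset",
    qi_value: float = float("nan"),
    paired: bool = False,
) -> ProportionResult:
    """Share of the top-k known disease genes recovered among the top DEGs."""
    if len(disease_genes) < top_k:
        raise ValueError(
            f"disease list has {len(disease_genes)} genes; need >= {top_k}"
        )
    top_disease = set(disease_genes[:top_k])
    numerator = len(set(top_degs) & top_disease)
    return ProportionResult(dataset_id, qi_value, paired, "disease_in_deg",
                            numerator, top_k)


def qi_proportion_regression(results: list[ProportionResult]) -> dict[str, dict]:
    """OLS of proportion on QI, fitted separately for paired and unpaired
    datasets. Returns per-stratum slope, intercept and R-squared."""
    import statsmodels.api as sm

    frame = pd.DataFrame([
        {"qi_value": r.qi_value, "proportion": r.proportion, "paired": r.paired}
        for r in results
    ])
    out = {}
    for paired, grp in frame.groupby("paired"):
        label = "paired" if paired else "unpaired"
        if len(grp) < 3 or grp["qi_value"].nunique() < 2:
            raise DegenerateInputError(f"stratum {label!r} too small for OLS")
        X = sm.add_constant(grp["qi_value"].to_numpy(float))
        fit = sm.OLS(grp["proportion"].to_numpy(float), X).fit()
        out[label] = {"slope": float(fit.params[1]),
                      "intercept": float(fit.params[0]),
                      "r_squared": float(fit.rsquared),
                      "n": int(len(grp))}
    return out


def degcount_vs_size_regression(datasets: pd.DataFrame, min_degs: int = 50) -> dict:
    """Per-QI-class OLS of DEG count on sample count.

    Expects columns n_samples, deg_count, qi_class (low/high); datasets
    below ``min_degs`` significant genes are dropped first. Returns both
    slopes and their ratio (high over low).
    """
    import statsmodels.api as sm

    kept = datasets[datasets["deg_count"] >= min_degs]
    out = {}
    for cls in ("low", "high"):
        grp = kept[kept["qi_class"] == cls]
        if len(grp) < 3 or grp["n_samples"].nunique() < 2:
            raise DegenerateInputError(
                f"QI class {cls!r} has too few datasets after the >= {min_degs} DEG filter"
            )
        X = sm.add_constant(grp["n_samples"].to_numpy(float))
        fit = sm.OLS(grp["deg_count"].to_numpy(float), X).fit()
        out[f"slope_{cls}"] = float(fit.params[1])
    out["slope_ratio"] = out["slope_high"] / out["slope_low"]
    return out


def marker_enrichment_in_disease_genes(
    disease_genes,
    catalog: MarkerCatalog,
    universe,
    min_datasets: int | None = None,
) -> dict[str, float]:
    """One-sided Fisher test of marker over-representation in disease genes.

    Builds, per marker direction, the 2x2 table of disease-gene membership
    against marker membership over the universe and tests for
    over-representation (upper tail).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    disease = set(disease_genes) & universe
    out = {}
    for direction in ("low", "high"):
        markers = catalog.features(direction=direction, min_n=min_datasets) & universe
        a = len(disease & markers)
        b = len(disease - markers)
        c = len(markers - disease)
        d_cell = len(universe) - a - b - c
        out[direction] = float(
            stats.fisher_exact([[a, b], [c, d_cell]], alternative="greater")[1]
        )
    return out


# ---------------------------------------------------------------------------
# Mitigation


def _differential_pathways(
    result: pd.DataFrame,
    gene_sets: enrich.GeneSetCollection,
    sign: str,
    fdr: float,
    lfc: float,
    use_lfc: bool,
    alpha: float,
    min_size: int,
    max_size: int,
    adjust: str,
) -> set[str]:
    genes = de.significant_genes(result, fdr=fdr, lfc=lfc, use_lfc=use_lfc)
    direction = result.loc[genes, "log2fc"]
    signed = [g for g in genes
              if (direction[g] > 0 if sign == "pos" else direction[g] < 0)]
    if not signed:
        return set()
    universe = set(result.index[result["tested"]])
    table = enrich.ora(signed, gene_sets, universe, min_size=min_size,
                       max_size=max_size, adjust=adjust)
    return enrich.significant_sets(table, alpha=alpha)


def mitigation_verdict(
    baseline_overlap_count: int,
    baseline_overlap_pct: float,
    mitigated_overlap_pct: float,
    change_threshold: float = 0.15,
    relative: bool = True,
) -> str:
    """Apply the >=15%-change rule to a pair of overlap percentages.

    ``excluded`` when the baseline overlap is zero pathways; otherwise
    ``better`` / ``worse`` when the overlap percentage decreased / increased
    by at least ``change_threshold`` (relative to baseline by default,
    absolute percentage points when ``relative`` is False), else
    ``no_change``.
    """
    if baseline_overlap_count == 0:
        return "excluded"
    if relative:
        change = (mitigated_overlap_pct - baseline_overlap_pct) / baseline_overlap_pct
    else:
        change = (mitigated_overlap_pct - baseline_overlap_pct) / 100.0
    if change <= -change_threshold:
        return "better"
    if change >= change_threshold:
        return "worse"
    return "no_change"


def evaluate_mitigation(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    low_quality_pathways: set[str],
    gene_sets: enrich.GeneSetCollection,
    strategy: str,
    dataset_id: str = "dataset",
    fdr: float = 0.05,
    lfc: float = 1.0,
    use_lfc: bool = True,
    alpha: float = 0.05,
    min_size: int = 15,
    max_size: int = 500,
    adjust: str = "bonferroni",
    change_threshold: float = 0.15,
    relative: bool = True,
) -> list[MitigationReport]:
    """Compare differential-pathway contamination with and without mitigation.

    ``low_quality_pathways`` is the pre-derived set of pathways enriched in
    low-quality markers. ``strategy`` is one of covariate, outlier_removal,
    both. Returns one report per DEG sign (pos / neg).
    """
    if strategy not in ("covariate", "outlier_removal", "both"):
        raise ValueError(f"unknown mitigation strategy {strategy!r}")
    samples = validate_sample_table(samples)

    baseline = de.run_de(counts, samples)

    mit_samples = samples
    if strategy in ("outlier_removal", "both"):
        outliers = qi.detect_quality_outliers(samples)
        mit_samples = samples[~samples["sample_id"].isin(outliers)].reset_index(drop=True)
        for code, label in ((0, "control"), (1, "disease")):
            if (mit_samples["group"] == code).sum() < 2:
                raise DegenerateInputError(
                    f"outlier removal leaves fewer than 2 {label} samples"
                )
    mit_counts = counts[mit_samples["sample_id"].tolist()]
    use_cov = strategy in ("covariate", "both")
    mitigated = de.run_de(mit_counts, mit_samples, use_quality_covariate=use_cov)

    reports = []
    for sign in ("pos", "neg"):
        kwargs = dict(fdr=fdr, lfc=lfc, use_lfc=use_lfc, alpha=alpha,
                      min_size=min_size, max_size=max_size, adjust=adjust)
        base_paths = _differential_pathways(baseline, gene_sets, sign, **kwargs)
        mit_paths = _differential_pathways(mitigated, gene_sets, sign, **kwargs)
        base_count = len(base_paths & low_quality_pathways)
        base_pct = 100.0 * base_count / len(base_paths) if base_paths else 0.0
        mit_count = len(mit_paths & low_quality_pathways)
        mit_pct = 100.0 * mit_count / len(mit_paths) if mit_paths else 0.0
        verdict = mitigation_verdict(base_count, base_pct, mit_pct,
                                     change_threshold, relative)
        reports.append(MitigationReport(
            dataset_id=dataset_id, strategy=strategy, deg_sign=sign,
            baseline_overlap_pct=base_pct, mitigated_overlap_pct=mit_pct,
            baseline_overlap_count=base_count, verdict=verdict,
        ))
    return reports


def mitigation_summary(reports: list[MitigationReport]) -> pd.DataFrame:
    """Tally verdicts per strategy and DEG sign (excluded datasets dropped
    from the verdict columns but reported)."""
    frame = pd.DataFrame([r.__dict__ for r in reports])
    rows = []
    for (strategy, sign), grp in frame.groupby(["strategy", "deg_sign"]):
        counted = grp[grp["verdict"] != "excluded"]
        rows.append({
            "strategy": strategy,
            "deg_sign": sign,
            "n_datasets": len(counted),
            "better": int((counted["verdict"] == "better").sum()),
            "worse": int((counted["verdict"] == "worse").sum()),
            "no_change": int((counted["verdict"] == "no_change").sum()),
            "excluded": int((grp["verdict"] == "excluded").sum()),
        })
    return pd.DataFrame(rows)
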