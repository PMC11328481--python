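"""Synthetic evaluation battery for the quality-imbalance pipeline.

Each function sets up a ground-truth scenario with the generator, runs the
relevant part of the analysis end to end, and returns summary numbers as a
plain dict. The battery covers:

* numerical cross-checks of the QI metrics and the hypergeometric ORA
  against independent reference computations (closed forms and exhaustive
  enumeration);
* statistical calibration of the differential engine on null data;
* the inflation of differential-gene counts with increasing quality
  imbalance, and its damping by a fold-change cutoff;
* recovery of planted quality markers across a collection of datasets;
* the quality-stratified subset construction and its DEG-vs-QI response;
* the proportion of quality markers / known disease genes among top
  differential genes along a QI ladder;
* the outlier-removal mitigation strategy on datasets with planted
  quality-outlier samples.

Problem sizes are desk scale (hundreds to a few thousand genes, 20-sample
datasets, ~10 replicates); every function is deterministic given ``seed``.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import de, enrich, markers, qi, repro, subsets, synth
from .pipeline import _synthetic_gene_sets
from .tables import validate_sample_table


def _random_cohort(rng, n=None):
    n = n if n is not None else int(rng.integers(8, 97))
    n0 = int(rng.integers(2, n - 1))
    return pd.DataFrame({
        "sample_id": [f"s{i:03d}" for i in range(n)],
        "group": [0] * n0 + [1] * (n - n0),
        "p_low": rng.uniform(0, 1, size=n),
        "pair_id": pd.NA,
    })


# ---------------------------------------------------------------------------
# Numerical cross-checks


def qi_oracle_check(seed: int, n_instances: int = 1000) -> dict:
    """Point-biserial QI vs brute-force Pearson and the closed form
    (M1-M0)/sigma * sqrt(n1*n0)/n, plus group-relabel invariance."""
    rng = np.random.default_rng(seed)
    max_brute = max_closed = max_relabel = 0.0
    worst_bound = 0.0
    for _ in range(n_instances):
        t = _random_cohort(rng)
        p = t["p_low"].to_numpy()
        g = t["group"].to_numpy()
        value = qi.qi_pearson(t).value
        pc, gc = p - p.mean(), g - g.mean()
        brute = abs((pc * gc).sum() / np.sqrt((pc**2).sum() * (gc**2).sum()))
        n1, n0 = int(g.sum()), int((1 - g).sum())
        closed = abs((p[g == 1].mean() - p[g == 0].mean()) / p.std()
                     * np.sqrt(n1 * n0) / (n0 + n1))
        relabel = qi.qi_pearson(t.assign(group=1 - t["group"])).value
        max_brute = max(max_brute, abs(value - brute))
        max_closed = max(max_closed, abs(value - closed))
        max_relabel = max(max_relabel, abs(value - relabel))
        worst_bound = max(worst_bound, value - 1.0, -value)
    return {"max_abs_error_brute": max_brute, "max_abs_error_closed_form": max_closed,
            "max_relabel_diff": max_relabel, "bound_violation": max(worst_bound, 0.0),
            "n": n_instances}


def ctdiff_oracle_check(seed: int, n_instances: int = 200) -> dict:
    """CTDiff vs explicit all-pairs enumeration (n <= 30), plus exact scale
    invariance under p_low -> c * p_low."""
    rng = np.random.default_rng(seed)
    max_err = max_scale = 0.0
    for _ in range(n_instances):
        t = _random_cohort(rng, n=int(rng.integers(4, 31)))
        p, g = t["p_low"].to_numpy(), t["group"].to_numpy()
        value = qi.qi_ctdiff(t).value
        med = abs(np.median(p[g == 0]) - np.median(p[g == 1]))
        pairs = [abs(a - b) for a, b in itertools.combinations(p, 2)]
        max_err = max(max_err, abs(value - med / np.mean(pairs)))
        scaled = qi.qi_ctdiff(t.assign(p_low=t["p_low"] * 0.5)).value
        max_scale = max(max_scale, abs(value - scaled))
    return {"max_abs_error_enumeration": max_err,
            "max_scale_invariance_diff": max_scale, "n": n_instances}


def ora_oracle_check(seed: int, n_instances: int = 40) -> dict:
    """ORA p-value vs exhaustive overlap enumeration on universes <= 25,
    and the Bonferroni identity padj = min(1, m*p)."""
    rng = np.random.default_rng(seed)
    max_p = max_bonf = 0.0
    for _ in range(n_instances):
        m = int(rng.integers(8, 26))
        universe = [f"u{i}" for i in range(m)]
        k = int(rng.integers(2, m - 2))
        nq = int(rng.integers(2, m - 2))
        gene_set = frozenset(rng.choice(universe, k, replace=False))
        query = set(rng.choice(universe, nq, replace=False))
        sets = enrich.GeneSetCollection(sets={"A": gene_set,
                                              "B": frozenset(universe[: max(2, k // 2)])})
        res = enrich.ora(query, sets, universe, min_size=1, max_size=500)
        n_tested = len(res)
        for _, row in res.iterrows():
            kk, x = int(row["set_size"]), int(row["overlap"])
            exact = sum(math.comb(kk, j) * math.comb(m - kk, nq - j)
                        for j in range(x, min(kk, nq) + 1)) / math.comb(m, nq)
            max_p = max(max_p, abs(row["p"] - exact))
            max_bonf = max(max_bonf, abs(row["padj"] - min(1.0, n_tested * row["p"])))
    return {"max_abs_error_enumeration": max_p,
            "max_bonferroni_identity_diff": max_bonf, "n": n_instances}


# ---------------------------------------------------------------------------
# Statistical calibration and recovery


def null_calibration(seed: int, n_replicates: int = 10, n_genes: int = 2000) -> dict:
    """Fraction of null genes significant at BH < 0.05 when nothing is
    planted (10 + 10 samples)."""
    fracs = []
    for rep in range(n_replicates):
        cfg = synth.SimConfig(
            n_control=10, n_disease=10, n_genes=n_genes,
            n_low_markers=0, n_high_markers=0, n_disease_genes=0,
            quality_effect=0.0, disease_effect=0.0, qi_target=0.0,
            seed=seed + rep,
        )
        counts, samples, _ = synth.simulate_dataset(cfg)
        result = de.run_de(counts, samples)
        tested = result[result["tested"] & result["padj"].notna()]
        fracs.append(float((tested["padj"] < 0.05).mean()))
    return {"mean_fraction_significant": float(np.mean(fracs)),
            "n": n_replicates}


def deg_inflation_ladder(
    seed: int,
    qi_targets: tuple = (0.0, 0.5, 0.9),
    n_replicates: int = 10,
    n_genes: int = 1000,
) -> dict:
    """Mean significant-gene counts across a QI ladder, with 300 planted
    quality-affected genes and no disease signal, under FDR-only and
    FDR + fold-change selection."""
    mean_fdr, mean_both = {}, {}
    for level, target in enumerate(qi_targets):
        fdr_counts, both_counts = [], []
        for rep in range(n_replicates):
            cfg = synth.SimConfig(
                n_control=10, n_disease=10, n_genes=n_genes,
                n_low_markers=150, n_high_markers=150, n_disease_genes=0,
                quality_effect=2.0, qi_target=target,
                seed=seed + 1000 * level + rep,
            )
            counts, samples, _ = synth.simulate_dataset(cfg)
            result = de.run_de(counts, samples)
            fdr_counts.append(len(de.significant_genes(result, use_lfc=False)))
            both_counts.append(len(de.significant_genes(result)))
        mean_fdr[target] = float(np.mean(fdr_counts))
        mean_both[target] = float(np.mean(both_counts))
    lo, hi = qi_targets[0], qi_targets[-1]
    return {
        "mean_deg_fdr_only": mean_fdr,
        "mean_deg_fdr_lfc": mean_both,
        "fdr_only_gap": mean_fdr[hi] - mean_fdr[lo],
        "fdr_lfc_gap": mean_both[hi] - mean_both[lo],
        "n": n_replicates * len(qi_targets),
    }


def marker_recovery(seed: int, n_datasets: int = 13, n_genes: int = 2000) -> dict:
    """Recovery of 200 + 200 shared planted markers across a low-QI
    collection: sensitivity at recurrence N >= 2, precision at N >= 4."""
    shared = [f"g{j:05d}" for j in range(400)]
    base = synth.SimConfig(
        n_control=10, n_disease=10, n_genes=n_genes,
        n_low_markers=200, n_high_markers=200, n_disease_genes=100,
        quality_effect=2.0, qi_target=0.1, seed=seed,
    )
    collection = synth.simulate_collection(base, n_datasets, shared)
    calls, r_tables = [], []
    for counts, samples, _ in collection:
        r_table = markers.gene_quality_correlations(counts, samples)
        r_tables.append(r_table)
        calls.append(markers.call_markers(r_table))
    catalog = markers.recurrence(calls, min_datasets=2, r_tables=r_tables)
    truth = set(shared)
    at2 = catalog.features(min_n=2)
    at4 = catalog.features(min_n=4)
    rec = catalog.recurrence
    non_increasing = bool(
        (np.diff(rec["low_markers"]) <= 0).all()
        and (np.diff(rec["high_markers"]) <= 0).all()
    )
    return {
        "sensitivity_n2": len(at2 & truth) / len(truth),
        "precision_n4": len(at4 & truth) / len(at4) if at4 else float("nan"),
        "recurrence_non_increasing": non_increasing,
        "n": n_datasets,
    }


def subset_structure(seed: int, n_genes: int = 1000) -> dict:
    """Subset builder on a quality-separable synthetic source: subset count
    and QI spread, and the OLS slope of DEG count on subset QI."""
    cfg = synth.SimConfig(
        n_control=30, n_disease=30, n_genes=n_genes,
        n_low_markers=150, n_high_markers=150, n_disease_genes=50,
        quality_effect=2.0, disease_effect=1.0,
        quality_concentration=1.5, qi_target=0.0, seed=seed,
    )
    counts, samples, _ = synth.simulate_dataset(cfg)
    specs = subsets.build_subsets(samples, n_iterations=3, seed=seed + 1)
    qi_values = [s.qi_value for s in specs]
    curve = subsets.subset_response_curve(specs, counts, samples, use_lfc=False)
    sizes = {len(s.control_ids) + len(s.disease_ids) for s in specs}
    return {
        "n_subsets": len(specs),
        "subset_sizes": sorted(sizes),
        "qi_range": max(qi_values) - min(qi_values),
        "deg_slope": curve["slope"],
        "r_squared": curve["r_squared"],
        "n": len(specs),
    }


def proportion_ladder(
    seed: int,
    qi_targets: tuple = (0.05, 0.25, 0.5, 0.7, 0.88),
    n_replicates: int = 5,
    n_genes: int = 2000,
) -> dict:
    """Marker and disease-gene proportions in the top 500 DEGs along a QI
    ladder; Spearman correlation of the per-level means with the ladder.

    The marker catalog is derived, as in the marker analysis, from a
    separate low-QI collection sharing the planted marker identities; the
    disease-gene list is the planted disease genes ranked by effect size.
    """
    n_markers = 800
    shared = [f"g{j:05d}" for j in range(n_markers)]
    catalog_base = synth.SimConfig(
        n_control=10, n_disease=10, n_genes=n_genes,
        n_low_markers=n_markers // 2, n_high_markers=n_markers // 2,
        n_disease_genes=50, quality_effect=2.0, qi_target=0.1,
        seed=seed + 50_000,
    )
    collection = synth.simulate_collection(catalog_base, 4, shared)
    calls = [markers.call_markers(markers.gene_quality_correlations(c, s))
             for c, s, _ in collection]
    catalog = markers.recurrence(calls, min_datasets=2)

    marker_means, disease_means = [], []
    for level, target in enumerate(qi_targets):
        mk, dz = [], []
        for rep in range(n_replicates):
            cfg = synth.SimConfig(
                n_control=10, n_disease=10, n_genes=n_genes,
                n_low_markers=n_markers // 2, n_high_markers=n_markers // 2,
                n_disease_genes=100, quality_effect=2.0, disease_effect=0.7,
                qi_target=target, seed=seed + 1000 * level + rep,
            )
            counts, samples, truth = synth.simulate_dataset(
                cfg, marker_low=shared[: n_markers // 2],
                marker_high=shared[n_markers // 2:])
            result = de.run_de(counts, samples)
            top = de.top_n_genes(result, n=500)
            mk.append(repro.marker_proportion_in_degs(
                top, catalog, qi_value=truth.realized_qi).proportion)
            disease = truth.genes[truth.genes["role"] == "disease"]
            ranked = disease.reindex(
                disease["beta_disease"].abs().sort_values(ascending=False).index
            ).index.tolist()
            dz.append(repro.disease_gene_proportion(
                top, ranked, top_k=50, qi_value=truth.realized_qi).proportion)
        marker_means.append(float(np.mean(mk)))
        disease_means.append(float(np.mean(dz)))
    return {
        "marker_proportion_means": marker_means,
        "disease_proportion_means": disease_means,
        "marker_proportion_spearman": float(
            spearmanr(qi_targets, marker_means).statistic),
        "disease_proportion_spearman": float(
            spearmanr(qi_targets, disease_means).statistic),
        "n": n_replicates * len(qi_targets),
    }


def mitigation_benchmark(seed: int, n_replicates: int = 10, n_genes: int = 800) -> dict:
    """Outlier-removal mitigation on datasets with planted quality-outlier
    samples: how often the verdict is ``better`` and how often removal
    reduces the realized QI index.

    Low-quality pathways are derived per replicate by ORA of the planted
    low markers against gene sets with planted pathway structure; the
    differential-pathway lists use FDR-only gene selection so the pathway
    layer has measurable signal at this problem size.
    """
    better = qi_reduced = evaluable = 0
    for rep in range(n_replicates):
        cfg = synth.SimConfig(
            n_control=10, n_disease=10, n_genes=n_genes,
            n_low_markers=60, n_high_markers=60, n_disease_genes=40,
            quality_effect=4.0, disease_effect=2.0,
            quality_concentration=40.0, dispersion_shape=(2.0, 0.025),
            qi_target=0.1, n_outliers=4, outlier_p_low=0.97,
            seed=seed + rep,
        )
        counts, samples, truth = synth.simulate_dataset(cfg)
        gene_sets = _synthetic_gene_sets(truth, seed + rep)
        low_markers = set(truth.genes.index[truth.genes["role"] == "low_marker"])
        lowq_table = enrich.ora(low_markers, gene_sets, set(counts.index))
        low_quality_pathways = enrich.significant_sets(lowq_table)
        reports = repro.evaluate_mitigation(
            counts, samples, low_quality_pathways, gene_sets,
            strategy="outlier_removal", use_lfc=False)
        verdicts = {r.deg_sign: r.verdict for r in reports}
        if verdicts["pos"] != "excluded":
            evaluable += 1
            if verdicts["pos"] == "better":
                better += 1
        outliers = qi.detect_quality_outliers(samples)
        kept = samples[~samples["sample_id"].isin(outliers)].reset_index(drop=True)
        kept = validate_sample_table(kept)
        if qi.qi_pearson(kept).value < qi.qi_pearson(samples).value:
            qi_reduced += 1
    return {
        "fraction_better": better / n_replicates,
        "fraction_evaluable": evaluable / n_replicates,
        "fraction_qi_reduced": qi_reduced / n_replicates,
        "n": n_replicates,
    }
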