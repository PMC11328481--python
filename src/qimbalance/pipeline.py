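"""Desk-scale pipeline orchestration over plain-text artifacts.

Stages consume and produce only TSV / BED / GMT files under a run
directory, so any stage can be re-run from its inputs and reproduces its
outputs bit-identically for a fixed seed. Configuration is a flat TOML
file; every tunable defaults to the package-wide values (QI cutoffs
0.18/0.30 and 0.5/1, marker thresholds 0.4 genes / 0.3 bins, FDR 0.05 with
|log2FC| > 1, pool size 15, 500-bp bins, Bonferroni ORA adjustment).
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from pathlib import Path

import pandas as pd

from . import de, enrich, markers, qi, repro, subsets, synth
from .exceptions import PipelineError
from .tables import read_counts, read_sample_table, write_counts, write_sample_table

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand", "enrichment"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "qi_metric": "pearson",
    "qi_cutoff_low": 0.18,
    "qi_cutoff_high": 0.30,
    "ctdiff_cutoff_low": 0.5,
    "ctdiff_cutoff_high": 1.0,
    "gene_r_threshold": 0.4,
    "bin_r_threshold": 0.3,
    "min_datasets": 2,
    "fdr": 0.05,
    "lfc": 1.0,
    "use_lfc": True,
    "pool_size": 15,
    "n_iterations": 3,
    "bin_width": 500,
    "ora_adjust": "bonferroni",
    "ora_min_size": 15,
    "ora_max_size": 500,
}


def load_config(path) -> dict:
    """Read a TOML config, filling unset keys with package defaults."""
    with open(path, "rb") as fh:
        user = tomllib.load(fh)
    config = dict(DEFAULT_CONFIG)
    config.update(user)
    for key in ("qi_cutoff_low", "gene_r_threshold", "bin_r_threshold", "fdr"):
        if not 0 <= config[key] <= 1:
            raise PipelineError(f"config: {key}={config[key]} outside [0, 1]")
    return config


def write_peaks_bed(peaks: pd.DataFrame, path) -> None:
    peaks[BED_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_peaks_bed(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", names=BED_COLUMNS)


def _cutoffs(config: dict) -> dict:
    return {
        "pearson": (config["qi_cutoff_low"], config["qi_cutoff_high"]),
        "spearman": (config["qi_cutoff_low"], config["qi_cutoff_high"]),
        "ctdiff": (config["ctdiff_cutoff_low"], config["ctdiff_cutoff_high"]),
    }


def write_truth(truth: synth.TruthRecord, outdir: Path, prefix: str = "") -> None:
    truth.genes.to_csv(outdir / f"{prefix}truth_genes.tsv", sep="\t",
                       index_label="gene_id")
    truth.sample_truth.to_csv(outdir / f"{prefix}truth_samples.tsv", sep="\t",
                              index=False)


def make_fixtures(seed: int, outdir, n_datasets: int = 6) -> list[Path]:
    """Write a miniature dataset collection (16 samples x 500 genes each)
    spanning low to high QI; used by the test suite and the demo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    qi_targets = [0.05, 0.2, 0.5, 0.7, 0.85, 0.0][:n_datasets]
    paths = []
    for k, target in enumerate(qi_targets):
        cfg = synth.SimConfig(
            n_control=8, n_disease=8, n_genes=500,
            n_low_markers=40, n_high_markers=40, n_disease_genes=30,
            qi_target=target, seed=seed + k,
        )
        counts, samples, truth = synth.simulate_dataset(cfg)
        stem = outdir / f"dataset{k}"
        write_counts(counts, f"{stem}_counts.tsv")
        write_sample_table(samples, f"{stem}_samples.tsv")
        write_truth(truth, outdir, prefix=f"dataset{k}_")
        paths.append(stem)
    return paths


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc


def run_pipeline(config: dict, outdir) -> Path:
    """Run the synthetic end-to-end demo pipeline.

    simulate -> QI -> subsets -> DE -> markers -> enrichment -> mitigation,
    writing TSV artifacts and a JSON log of parameters to ``outdir``.
    Idempotent for a fixed config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    cutoffs = _cutoffs(config)

    # --- simulate a small collection with shared markers
    base = synth.SimConfig(
        n_control=10, n_disease=10, n_genes=800,
        n_low_markers=60, n_high_markers=60, n_disease_genes=40,
        qi_target=0.1, seed=seed,
    )
    shared = [f"g{j:05d}" for j in range(120)]
    collection = _stage("simulate", synth.simulate_collection, base, 4, shared)
    # one extra quality-imbalanced dataset with planted outliers for mitigation
    imb_cfg = dataclasses.replace(base, qi_target=0.5, n_outliers=3, seed=seed + 100)
    imb_counts, imb_samples, imb_truth = _stage("simulate", synth.simulate_dataset,
                                                imb_cfg, marker_low=shared[:60],
                                                marker_high=shared[60:])

    qi_rows, calls, r_tables = [], [], []
    for k, (counts, samples, truth) in enumerate(collection):
        write_counts(counts, outdir / f"dataset{k}_counts.tsv")
        write_sample_table(samples, outdir / f"dataset{k}_samples.tsv")
        res = _stage("qi", qi.qi_index, samples, config["qi_metric"], cutoffs)
        qi_rows.append({"dataset": f"dataset{k}", "metric": res.metric,
                        "qi_index": res.value, "qi_class": res.qi_class,
                        "n_samples": res.n_samples})
        r_table = _stage("markers", markers.gene_quality_correlations, counts, samples)
        r_tables.append(r_table)
        calls.append(markers.call_markers(r_table, threshold=config["gene_r_threshold"]))
    imb_res = qi.qi_index(imb_samples, config["qi_metric"], cutoffs)
    qi_rows.append({"dataset": "imbalanced", "metric": imb_res.metric,
                    "qi_index": imb_res.value, "qi_class": imb_res.qi_class,
                    "n_samples": imb_res.n_samples})
    pd.DataFrame(qi_rows).to_csv(outdir / "qi_results.tsv", sep="\t", index=False)

    catalog = _stage("markers", markers.recurrence, calls,
                     config["min_datasets"], r_tables)
    catalog.table.to_csv(outdir / "marker_catalog.tsv", sep="\t", index=False)
    catalog.recurrence.to_csv(outdir / "marker_recurrence.tsv", sep="\t", index=False)

    # --- differential expression on the imbalanced dataset
    result = _stage("de", de.run_de, imb_counts, imb_samples)
    de.write_de_result(result, outdir / "de_result.tsv")

    # --- gene sets: planted pathway structure over the simulated genome
    gene_sets = _synthetic_gene_sets(imb_truth, seed)
    enrich.write_gmt(gene_sets, outdir / "gene_sets.gmt")
    low_markers = sorted(catalog.features(direction="low"))
    universe = set(imb_counts.index)
    if low_markers:
        lowq_table = _stage("enrich", enrich.ora, set(low_markers) & universe,
                            gene_sets, universe, config["ora_min_size"],
                            config["ora_max_size"], config["ora_adjust"])
        lowq_table.to_csv(outdir / "low_quality_pathways.tsv", sep="\t", index=False)
        low_quality_pathways = enrich.significant_sets(lowq_table)
    else:
        low_quality_pathways = set()

    # --- mitigation on the imbalanced dataset
    reports = []
    for strategy in ("covariate", "outlier_removal"):
        reports.extend(_stage("mitigate", repro.evaluate_mitigation,
                              imb_counts, imb_samples, low_quality_pathways,
                              gene_sets, strategy, "imbalanced",
                              config["fdr"], config["lfc"], config["use_lfc"],
                              min_size=config["ora_min_size"],
                              max_size=config["ora_max_size"],
                              adjust=config["ora_adjust"]))
    repro.mitigation_summary(reports).to_csv(outdir / "mitigation_report.tsv",
                                             sep="\t", index=False)

    (outdir / "run_log.json").write_text(json.dumps({
        "package": "qimbalance",
        "config": {k: v for k, v in config.items()},
        "stages": ["simulate", "qi", "markers", "de", "enrich", "mitigate"],
    }, indent=2, sort_keys=True))
    return outdir


def _synthetic_gene_sets(truth: synth.TruthRecord, seed: int,
                         set_size: int = 25, n_null_sets: int = 10) -> enrich.GeneSetCollection:
    """Gene sets with planted structure: sets drawn from low markers, from
    disease genes, and from null genes of a simulated dataset."""
    import numpy as np

    rng = np.random.default_rng(seed + 7)
    genes = truth.genes
    groups = {
        "LOWQ": list(genes.index[genes["role"] == "low_marker"]),
        "DISEASE": list(genes.index[genes["role"] == "disease"]),
        "NULL": list(genes.index[genes["role"] == "null"]),
    }
    sets: dict[str, frozenset] = {}
    for label, pool in groups.items():
        n_sets = n_null_sets if label == "NULL" else 2
        for i in range(n_sets):
            size = min(set_size, len(pool))
            sets[f"{label}_{i}"] = frozenset(rng.choice(pool, size, replace=False))
    return enrich.GeneSetCollection(sets=sets)
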