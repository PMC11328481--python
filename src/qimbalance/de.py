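"""Differential expression between disease and control groups.

A thin, validated wrapper around the pydeseq2 negative-binomial GLM
(median-of-ratios size factors, per-gene dispersion, Wald test of the group
coefficient, Benjamini-Hochberg adjustment). The design can optionally
include a pairing factor and/or sample quality as a continuous covariate;
for the covariate, 1 - P_low is used so that higher-quality samples get the
higher covariate value.

Independent filtering, Cooks-based filtering/refitting and log2FC shrinkage
are off by default: the defaults here aim at calibrated raw statistics, not
at any particular DESeq2 release's post-processing.

Results are returned as a per-gene DataFrame (the ``DEResult`` layout):
``log2fc`` (disease vs control), ``p``, ``padj`` and ``tested`` (False for
all-zero genes, which are excluded from testing and from the BH family).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError
from .tables import align_counts, validate_sample_table

DE_COLUMNS = ["log2fc", "p", "padj", "tested"]


def _quiet_pydeseq2():
    for name in ("pydeseq2", "pydeseq2.dds", "pydeseq2.ds"):
        logging.getLogger(name).setLevel(logging.ERROR)


def run_de(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    use_quality_covariate: bool = False,
    use_pairing: bool = False,
) -> pd.DataFrame:
    """Per-gene Wald test of disease vs control on raw counts.

    Design: ``~ group`` plus, optionally, a pairing factor and/or the
    continuous covariate ``1 - p_low``. Returns a DataFrame indexed by gene
    with columns log2fc, p, padj, tested.
    """
    samples = validate_sample_table(samples)
    counts = align_counts(counts, samples)
    if use_pairing and samples["pair_id"].isna().any():
        raise ValueError("pairing requested but pair_id incomplete")
    if use_quality_covariate and samples["p_low"].isna().any():
        raise ValueError("quality covariate requested but p_low missing")

    tested_mask = counts.sum(axis=1) > 0
    if not tested_mask.any():
        raise DegenerateInputError("count matrix is all zero; nothing to test")
    sub = counts.loc[tested_mask]

    meta = pd.DataFrame(index=pd.Index(samples["sample_id"], name="sample"))
    meta["group"] = pd.Categorical(
        np.where(samples["group"].to_numpy() == 1, "disease", "control"),
        categories=["control", "disease"],
    )
    design = "~group"
    if use_pairing:
        meta["pair"] = pd.Categorical(samples["pair_id"].astype(str).to_numpy())
        design = "~pair + group"
    if use_quality_covariate:
        meta["quality"] = 1.0 - samples["p_low"].to_numpy(float)
        design = design + " + quality"

    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    _quiet_pydeseq2()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dds = DeseqDataSet(
            counts=sub.T.set_axis(meta.index, axis=0),
            metadata=meta,
            design=design,
            refit_cooks=False,
            quiet=True,
            n_cpus=1,
        )
        dds.deseq2()
        stats = DeseqStats(
            dds,
            contrast=["group", "disease", "control"],
            independent_filter=False,
            cooks_filter=False,
            quiet=True,
        )
        stats.summary()
    res = stats.results_df

    out = pd.DataFrame(index=counts.index, columns=DE_COLUMNS)
    out["tested"] = tested_mask
    out.loc[res.index, "log2fc"] = res["log2FoldChange"]
    out.loc[res.index, "p"] = res["pvalue"]
    out.loc[res.index, "padj"] = res["padj"]
    out[["log2fc", "p", "padj"]] = out[["log2fc", "p", "padj"]].astype(float)
    out["tested"] = out["tested"].astype(bool)
    return out


def significant_genes(
    result: pd.DataFrame,
    fdr: float = 0.05,
    lfc: float = 1.0,
    use_lfc: bool = True,
) -> list[str]:
    """Genes with padj < fdr and (optionally) |log2fc| > lfc.

    Both inequalities are strict, so a gene at exactly the cutoff is not
    selected. Untested genes and genes with undefined padj never qualify.
    """
    if result.empty:
        return []
    mask = result["tested"] & (result["padj"] < fdr)
    if use_lfc:
        mask &= result["log2fc"].abs() > lfc
    return result.index[mask.fillna(False)].tolist()


def top_n_genes(result: pd.DataFrame, n: int = 500) -> list[str]:
    """Top genes by significance: padj ascending, then |log2fc| descending,
    then gene id lexicographic. Untested genes are excluded."""
    tested = result[result["tested"]].copy()
    tested["_abs_lfc"] = tested["log2fc"].abs()
    tested["_gene"] = tested.index.astype(str)
    ranked = tested.sort_values(
        ["padj", "_abs_lfc", "_gene"], ascending=[True, False, True],
        na_position="last",
    )
    return ranked.index[: min(n, len(ranked))].tolist()


def read_de_result(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df["tested"] = df["tested"].astype(bool)
    return df


def write_de_result(result: pd.DataFrame, path) -> None:
    result.to_csv(path, sep="\t", index_label="gene_id")
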