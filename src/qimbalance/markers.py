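"""Quality-marker genes and bins, and their recurrence across datasets.

A *low-quality marker* is a feature (gene, or 500-bp genomic bin for
ChIP-seq-like data) whose signal correlates positively with P_low within a
dataset; a *high-quality marker* correlates negatively. Markers are called
per dataset by a Pearson-correlation threshold (|r| > 0.4 for genes, > 0.3
for bins) and become catalog entries when they recur with consistent
direction in at least ``min_datasets`` datasets. The recurrence count N per
feature is the number of datasets in which it was called.

Gene expression is correlated on a log2(size-factor-normalized count + 1)
scale by default (configurable: raw / normalized / log2); bin enrichment
uses the per-bin mean peak enrichment with absent-peak cells treated as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError
from .tables import align_counts, validate_sample_table

GENE_R_THRESHOLD = 0.4
BIN_R_THRESHOLD = 0.3


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style size factors: per-sample median ratio to the geometric
    mean gene profile, over genes expressed in every sample."""
    with np.errstate(divide="ignore"):
        log_counts = np.log(counts.to_numpy(float))
    log_geo_mean = log_counts.mean(axis=1)
    usable = np.isfinite(log_geo_mean)
    if not usable.any():
        raise DegenerateInputError(
            "no gene is expressed in every sample; size factors undefined"
        )
    log_ratios = log_counts[usable] - log_geo_mean[usable, None]
    sf = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _transform(counts: pd.DataFrame, scale: str) -> pd.DataFrame:
    if scale == "raw":
        return counts.astype(float)
    sf = median_of_ratios_size_factors(counts)
    normalized = counts / sf
    if scale == "normalized":
        return normalized
    if scale == "log2":
        return np.log2(normalized + 1.0)
    raise ValueError(f"unknown expression scale {scale!r}")


def _rowwise_pearson(matrix: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of each matrix row against y; rows with zero variance are
    flagged (second return) and get NaN."""
    yc = y - y.mean()
    y_ss = float(yc @ yc)
    xc = matrix - matrix.mean(axis=1, keepdims=True)
    x_ss = (xc**2).sum(axis=1)
    zero_var = x_ss == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / np.sqrt(x_ss * y_ss)
    r[zero_var] = np.nan
    return r, zero_var


def gene_quality_correlations(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    scale: str = "log2",
) -> pd.DataFrame:
    """Per-gene Pearson correlation between expression and P_low.

    Returns a DataFrame indexed by gene with columns ``r`` and ``excluded``
    (True for zero-variance genes, whose correlation is undefined — they are
    flagged rather than reported as r = 0).
    """
    samples = validate_sample_table(samples)
    counts = align_counts(counts, samples)
    if len(samples) < 4:
        raise DegenerateInputError("need >= 4 samples for gene-quality correlations")
    p_low = samples["p_low"].to_numpy(float)
    if np.ptp(p_low) == 0:
        raise DegenerateInputError("p_low is constant; correlations undefined")
    expr = _transform(counts, scale).to_numpy(float)
    r, zero_var = _rowwise_pearson(expr, p_low)
    return pd.DataFrame({"r": r, "excluded": zero_var}, index=counts.index)


def call_markers(r_table: pd.DataFrame, threshold: float = GENE_R_THRESHOLD) -> dict[str, set]:
    """Split features into low-/high-quality marker sets by correlation sign.

    Strict inequality: |r| must exceed the threshold. Excluded (zero
    variance) features are never called.
    """
    if r_table.empty:
        raise ValueError("empty correlation table")
    ok = r_table[~r_table["excluded"] & r_table["r"].notna()]
    return {
        "low": set(ok.index[ok["r"] > threshold]),
        "high": set(ok.index[ok["r"] < -threshold]),
    }


@dataclass
class MarkerCatalog:
    """Cross-dataset marker catalog.

    ``table`` has one row per (feature, direction) with recurrence count
    ``n_datasets`` (only features meeting ``min_datasets`` are kept) and the
    per-dataset r values that produced the calls. ``recurrence`` counts, for
    each k >= min_datasets, the features recurring in at least k datasets
    (cumulative, hence non-increasing in k).
    """

    table: pd.DataFrame
    recurrence: pd.DataFrame
    min_datasets: int
    feature_kind: str = "gene"

    def features(self, direction: str | None = None, min_n: int | None = None) -> set:
        t = self.table
        if direction is not None:
            t = t[t["direction"] == direction]
        if min_n is not None:
            t = t[t["n_datasets"] >= min_n]
        return set(t["feature"])


def recurrence(
    marker_calls: list[dict[str, set]],
    min_datasets: int = 2,
    r_tables: list[pd.DataFrame] | None = None,
    feature_kind: str = "gene",
) -> MarkerCatalog:
    """Aggregate per-dataset marker calls into a recurrence catalog.

    ``marker_calls`` is one dict per dataset, as produced by
    :func:`call_markers`. N is counted per direction; a feature called low
    in some datasets and high in others contributes to each direction's
    count separately.
    """
    if len(marker_calls) < 2:
        raise ValueError("recurrence needs calls from >= 2 datasets")
    rows = []
    for direction in ("low", "high"):
        counts: dict[str, int] = {}
        hits: dict[str, list[float]] = {}
        for d_idx, calls in enumerate(marker_calls):
            for feat in calls[direction]:
                counts[feat] = counts.get(feat, 0) + 1
                if r_tables is not None:
                    hits.setdefault(feat, []).append(
                        float(r_tables[d_idx].loc[feat, "r"])
                    )
        for feat, n in counts.items():
            if n >= min_datasets:
                rows.append({
                    "feature": feat,
                    "direction": direction,
                    "n_datasets": n,
                    "r_values": ",".join(f"{v:.3f}" for v in hits.get(feat, [])),
                })
    table = pd.DataFrame(rows, columns=["feature", "direction", "n_datasets", "r_values"])
    table = table.sort_values(["direction", "n_datasets", "feature"],
                              ascending=[True, False, True]).reset_index(drop=True)

    ks = range(min_datasets, len(marker_calls) + 1)
    rec_rows = []
    for k in ks:
        row = {"k": k}
        for direction in ("low", "high"):
            sub = table[table["direction"] == direction]
            row[f"{direction}_markers"] = int((sub["n_datasets"] >= k).sum())
        rec_rows.append(row)
    rec = pd.DataFrame(rec_rows, columns=["k", "low_markers", "high_markers"])
    return MarkerCatalog(table=table, recurrence=rec, min_datasets=min_datasets,
                         feature_kind=feature_kind)


# ---------------------------------------------------------------------------
# ChIP-seq-like peak binning


@dataclass
class BinMatrix:
    """Per-bin, per-sample peak summaries on fixed-width genomic tiles.

    ``count`` holds the number of peaks overlapping each bin; ``mean_enr`` /
    ``min_enr`` / ``max_enr`` summarize the enrichment of contributing peaks
    (NaN where a bin has no peak in that sample). Bin ids are
    ``chrom:start-end`` at the stated width, 0-based half-open.
    """

    count: pd.DataFrame
    mean_enr: pd.DataFrame
    min_enr: pd.DataFrame
    max_enr: pd.DataFrame
    bin_width: int


def _peak_bins(start: int, end: int, bin_width: int) -> range:
    return range(start // bin_width, (end - 1) // bin_width + 1)


def bin_peaks(peaks: dict[str, pd.DataFrame], bin_width: int = 500) -> BinMatrix:
    """Assign peaks to fixed-width genomic bins.

    A peak contributes to every bin it overlaps (half-open interval
    overlap). ``peaks`` maps sample id to a BED-like DataFrame with columns
    chrom, start, end, enrichment.
    """
    records: dict[str, dict[str, list[float]]] = {}
    for sid, df in peaks.items():
        for chrom, start, end, enr in zip(df["chrom"], df["start"].astype(int),
                                          df["end"].astype(int),
                                          df["enrichment"].astype(float)):
            if start >= end:
                raise ValueError(f"malformed interval {chrom}:{start}-{end} in {sid}")
            if not np.isfinite(enr):
                raise ValueError(f"non-finite enrichment in {sid} at {chrom}:{start}")
            for b in _peak_bins(start, end, bin_width):
                bin_id = f"{chrom}:{b * bin_width}-{(b + 1) * bin_width}"
                records.setdefault(bin_id, {}).setdefault(sid, []).append(enr)

    def _key(bin_id: str):
        chrom, span = bin_id.rsplit(":", 1)
        return chrom, int(span.split("-")[0])

    bin_ids = sorted(records, key=_key)
    sample_ids = list(peaks)
    shape = (len(bin_ids), len(sample_ids))
    count = np.zeros(shape, dtype=int)
    mean_e = np.full(shape, np.nan)
    min_e = np.full(shape, np.nan)
    max_e = np.full(shape, np.nan)
    for i, bin_id in enumerate(bin_ids):
        for j, sid in enumerate(sample_ids):
            vals = records[bin_id].get(sid)
            if vals:
                count[i, j] = len(vals)
                mean_e[i, j] = np.mean(vals)
                min_e[i, j] = np.min(vals)
                max_e[i, j] = np.max(vals)
    idx = pd.Index(bin_ids, name="bin")
    return BinMatrix(
        count=pd.DataFrame(count, index=idx, columns=sample_ids),
        mean_enr=pd.DataFrame(mean_e, index=idx, columns=sample_ids),
        min_enr=pd.DataFrame(min_e, index=idx, columns=sample_ids),
        max_enr=pd.DataFrame(max_e, index=idx, columns=sample_ids),
        bin_width=bin_width,
    )


def bin_quality_correlations(
    bins: BinMatrix,
    samples: pd.DataFrame,
    min_samples_with_peak: int = 3,
    threshold: float = BIN_R_THRESHOLD,
    summary: str = "mean",
) -> tuple[pd.DataFrame, dict[str, set]]:
    """Correlate per-bin enrichment with P_low and call marker bins.

    Only bins with peaks in at least ``min_samples_with_peak`` samples are
    eligible; absent-peak cells contribute enrichment 0. Returns the per-bin
    r table (eligible bins) and the low/high marker-bin sets at the stated
    |r| threshold (strict).
    """
    samples = validate_sample_table(samples)
    enr = {"mean": bins.mean_enr, "min": bins.min_enr, "max": bins.max_enr}[summary]
    enr = enr[samples["sample_id"].tolist()]
    counts = bins.count[samples["sample_id"].tolist()]
    p_low = samples["p_low"].to_numpy(float)
    if np.ptp(p_low) == 0:
        raise DegenerateInputError("p_low is constant; correlations undefined")
    eligible = (counts > 0).sum(axis=1) >= min_samples_with_peak
    filled = enr.fillna(0.0).to_numpy(float)[eligible.to_numpy()]
    r, zero_var = _rowwise_pearson(filled, p_low)
    r_table = pd.DataFrame({"r": r, "excluded": zero_var},
                           index=enr.index[eligible])
    if r_table.empty:
        return r_table, {"low": set(), "high": set()}
    return r_table, call_markers(r_table, threshold=threshold)


def annotate_bins_to_genes(bin_ids, annotation: pd.DataFrame) -> pd.DataFrame:
    """Map each bin to the gene with the nearest TSS on the same chromosome.

    ``annotation`` needs columns gene_id, chrom, tss. Distance is from the
    bin midpoint; ties go to the smaller TSS coordinate, then to the
    lexicographically smaller gene id. Bins on chromosomes absent from the
    annotation are returned unmapped (``mapped`` = False).
    """
    if annotation["gene_id"].duplicated().any():
        raise ValueError("gene ids in the annotation must be unique")
    by_chrom = {
        chrom: grp.sort_values(["tss", "gene_id"]).reset_index(drop=True)
        for chrom, grp in annotation.groupby("chrom")
    }
    rows = []
    for bin_id in bin_ids:
        chrom, span = str(bin_id).rsplit(":", 1)
        start, end = map(int, span.split("-"))
        mid = (start + end) / 2.0
        genes = by_chrom.get(chrom)
        if genes is None:
            rows.append({"bin": bin_id, "gene_id": None, "distance": np.nan,
                         "mapped": False})
            continue
        dist = np.abs(genes["tss"].to_numpy(float) - mid)
        best = int(np.argmin(dist))  # argmin takes the first minimum: ties
        # resolve to the smaller TSS then smaller gene id via the sort above
        rows.append({"bin": bin_id, "gene_id": genes.loc[best, "gene_id"],
                     "distance": float(dist[best]), "mapped": True})
    return pd.DataFrame(rows, columns=["bin", "gene_id", "distance", "mapped"])
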