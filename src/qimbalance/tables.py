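"""Core tabular containers and their validation.

The package passes data around as plain pandas objects:

* **sample table** — one row per sample with columns ``sample_id`` (unique
  string), ``group`` (0 = control, 1 = disease), ``p_low`` (probability in
  [0, 1] that the sample is of low quality, as produced by an external
  quality classifier) and optional ``pair_id`` linking one control to one
  disease sample.
* **count matrix** — genes x samples DataFrame of non-negative integer
  counts whose columns match the sample table's ``sample_id`` values.

``validate_sample_table`` / ``validate_count_matrix`` are called at every
module boundary that consumes these objects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = ["sample_id", "group", "p_low", "pair_id"]


def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a sample table.

    Returns a copy with ``group`` coerced to int {0, 1} and a ``pair_id``
    column present (NaN/None where unpaired). Raises ``ValueError`` on any
    violated invariant.
    """
    required = {"sample_id", "group", "p_low"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")
    out = samples.copy()
    out["sample_id"] = out["sample_id"].astype(str)
    if out["sample_id"].duplicated().any():
        dupes = out.loc[out["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dupes}")
    out["group"] = out["group"].astype(int)
    if not out["group"].isin([0, 1]).all():
        raise ValueError("group must be coded 0 (control) or 1 (disease)")
    if (out["group"] == 0).sum() == 0 or (out["group"] == 1).sum() == 0:
        raise ValueError("both control and disease groups must be non-empty")
    p = out["p_low"].astype(float)
    if p.isna().any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p_low must lie in [0, 1] for every sample")
    out["p_low"] = p
    if "pair_id" not in out.columns:
        out["pair_id"] = pd.NA
    _validate_pairing(out)
    return out.reset_index(drop=True)


def _validate_pairing(samples: pd.DataFrame) -> None:
    paired = samples[samples["pair_id"].notna()]
    if paired.empty:
        return
    if len(paired) != len(samples):
        raise ValueError("pair_id must be set for all samples or none")
    for pid, grp in paired.groupby("pair_id"):
        if len(grp) != 2 or set(grp["group"]) != {0, 1}:
            raise ValueError(
                f"pair {pid!r} must link exactly one control to one disease sample"
            )


def validate_count_matrix(counts: pd.DataFrame, samples: pd.DataFrame | None = None) -> pd.DataFrame:
    """Validate a genes x samples count matrix, optionally against a sample table."""
    if counts.index.duplicated().any():
        raise ValueError("gene ids must be unique")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("counts must be numeric")
    if (values < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.allclose(values, np.round(values)):
        raise ValueError("counts must be integers")
    if samples is not None:
        expected = set(samples["sample_id"].astype(str))
        got = set(map(str, counts.columns))
        if expected != got:
            raise ValueError(
                "count matrix columns do not match sample table: "
                f"missing={sorted(expected - got)}, extra={sorted(got - expected)}"
            )
    return counts


def align_counts(counts: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Return counts with columns ordered as in the sample table."""
    validate_count_matrix(counts, samples)
    return counts[samples["sample_id"].tolist()]


def read_sample_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "pair_id": str})
    return validate_sample_table(df)


def write_sample_table(samples: pd.DataFrame, path) -> None:
    cols = [c for c in SAMPLE_COLUMNS if c in samples.columns]
    samples[cols].to_csv(path, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return validate_count_matrix(df)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")
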