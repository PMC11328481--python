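"""Quality-imbalance (QI) index of a case/control dataset.

The QI index quantifies how confounded per-sample quality is with the
case/control split. Quality enters as P_low, the probability that a sample
is of low quality (an upstream classifier's output, taken as given). Three
metrics are provided:

* ``pearson`` — |Pearson correlation| between P_low and the binary group
  code; for a dichotomous variable this is the point-biserial correlation.
  0 means quality and group are unconfounded, 1 means fully confounded.
* ``spearman`` — the rank-based analogue, invariant to monotone
  transformations of P_low.
* ``ctdiff`` — central tendency difference: |median(P_low | control) -
  median(P_low | disease)| divided by the mean absolute difference over all
  unordered sample pairs (pooled). Non-negative, no upper bound.

Datasets are classed low / intermediate / high. Default cutoffs: a
correlation-based index below 0.18 is low and above 0.30 high; CTDiff uses
0.5 and 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DegenerateInputError
from .tables import validate_sample_table

#: (low_cutoff, high_cutoff) per metric; strict inequalities on both sides.
DEFAULT_CUTOFFS: dict[str, tuple[float, float]] = {
    "pearson": (0.18, 0.30),
    "spearman": (0.18, 0.30),
    "ctdiff": (0.5, 1.0),
}


@dataclass(frozen=True)
class QIResult:
    """QI index of one dataset under one metric."""

    metric: str
    value: float
    qi_class: str
    n_samples: int


def classify_qi(value: float, metric: str, cutoffs: dict | None = None) -> str:
    """Class a QI value as ``low`` / ``intermediate`` / ``high``.

    Strict inequalities: a value exactly at a cutoff is intermediate.
    """
    if value < 0:
        raise ValueError("QI value must be non-negative")
    table = DEFAULT_CUTOFFS if cutoffs is None else cutoffs
    if metric not in table:
        raise ValueError(f"unknown QI metric {metric!r}; known: {sorted(table)}")
    low, high = table[metric]
    if value < low:
        return "low"
    if value > high:
        return "high"
    return "intermediate"


def _prepare(samples, min_per_group: int):
    samples = validate_sample_table(samples)
    p = samples["p_low"].to_numpy(float)
    g = samples["group"].to_numpy(int)
    n0, n1 = int((g == 0).sum()), int((g == 1).sum())
    if n0 < min_per_group or n1 < min_per_group:
        raise DegenerateInputError(
            f"need >= {min_per_group} samples per group, got {n0} control / {n1} disease"
        )
    return p, g


def qi_pearson(samples, cutoffs: dict | None = None) -> QIResult:
    """Point-biserial QI index: |Pearson r| between P_low and group code.

    Invariant under swapping which group is coded 1. Raises
    ``DegenerateInputError`` on constant P_low (correlation undefined).
    """
    p, g = _prepare(samples, min_per_group=2)
    if np.ptp(p) == 0:
        raise DegenerateInputError("p_low is constant; QI index undefined")
    value = abs(stats.pearsonr(p, g).statistic)
    return QIResult("pearson", float(value), classify_qi(value, "pearson", cutoffs), len(p))


def qi_spearman(samples, cutoffs: dict | None = None) -> QIResult:
    """Rank-based QI index: |Spearman rho| between P_low and group code."""
    p, g = _prepare(samples, min_per_group=2)
    if np.ptp(p) == 0:
        raise DegenerateInputError("p_low is constant; QI index undefined")
    value = abs(stats.spearmanr(p, g).statistic)
    return QIResult("spearman", float(value), classify_qi(value, "spearman", cutoffs), len(p))


def qi_ctdiff(samples, cutoffs: dict | None = None) -> QIResult:
    """Central tendency difference QI index.

    |difference of group medians of P_low| over the mean absolute difference
    of all unordered sample pairs in the pooled dataset.
    """
    p, g = _prepare(samples, min_per_group=1)
    if np.unique(p).size < 2:
        raise DegenerateInputError(
            "all p_low identical; CTDiff denominator is zero"
        )
    med_diff = abs(np.median(p[g == 0]) - np.median(p[g == 1]))
    # mean |p_i - p_j| over the n*(n-1)/2 unordered pairs
    diffs = np.abs(p[:, None] - p[None, :])
    denom = diffs[np.triu_indices(len(p), k=1)].mean()
    value = med_diff / denom
    return QIResult("ctdiff", float(value), classify_qi(value, "ctdiff", cutoffs), len(p))


_METRICS = {"pearson": qi_pearson, "spearman": qi_spearman, "ctdiff": qi_ctdiff}


def qi_index(samples, metric: str = "pearson", cutoffs: dict | None = None) -> QIResult:
    """Dispatch to the requested QI metric."""
    try:
        fn = _METRICS[metric]
    except KeyError:
        raise ValueError(f"unknown QI metric {metric!r}; known: {sorted(_METRICS)}") from None
    return fn(samples, cutoffs=cutoffs)


def detect_quality_outliers(samples, k: float = 1.5, interpolation: str = "linear") -> set[str]:
    """Samples whose P_low lies beyond Tukey fences of the pooled dataset.

    A sample is an outlier if p_low > Q3 + k*IQR or p_low < Q1 - k*IQR, with
    quartiles computed on both groups together using linear-interpolation
    quantiles (convention configurable via ``interpolation``).
    """
    samples = validate_sample_table(samples)
    if len(samples) < 4:
        raise DegenerateInputError("need >= 4 samples to define quartile fences")
    p = samples["p_low"].to_numpy(float)
    q1, q3 = np.quantile(p, [0.25, 0.75], method=interpolation)
    iqr = q3 - q1
    mask = (p > q3 + k * iqr) | (p < q1 - k * iqr)
    return set(samples.loc[mask, "sample_id"])
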