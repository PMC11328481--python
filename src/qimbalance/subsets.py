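"""Quality-stratified 20-sample subsets of a larger dataset.

To isolate the effect of quality imbalance on differential-gene counts from
the effect of sample size, fixed-size subsets (10 control + 10 disease) are
drawn from quality-extreme pools of a source dataset: per group, the
``pool_size`` samples with the lowest P_low (top quality) and the
``pool_size`` with the highest (bottom quality). Per iteration, one
10-sample group is drawn from each of the four pools and combined pairwise
into the four combos — BB, BT, TB, TT (control-pool x disease-pool,
B = bottom quality, T = top quality) — so each drawn group serves in
exactly two combos; three iterations yield 12 subsets spanning a range of
realized QI indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import de, qi
from .exceptions import DegenerateInputError, PipelineError
from .tables import validate_sample_table

COMBOS = ("BB", "BT", "TB", "TT")


@dataclass(frozen=True)
class SubsetSpec:
    """One 20-sample subset: its combo, member ids and realized QI."""

    source_dataset: str
    iteration: int
    combo: str
    control_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]
    qi_value: float


@dataclass(frozen=True)
class QualityPools:
    control_top: tuple[str, ...]
    control_bottom: tuple[str, ...]
    disease_top: tuple[str, ...]
    disease_bottom: tuple[str, ...]


def build_pools(samples: pd.DataFrame, pool_size: int = 15) -> QualityPools:
    """Per group, the ``pool_size`` lowest-P_low (top-quality) and highest-
    P_low (bottom-quality) samples. Pools of a group overlap when it has
    fewer than 2*pool_size samples. Ties in P_low break by sample id."""
    samples = validate_sample_table(samples)
    pools = {}
    for code, label in ((0, "control"), (1, "disease")):
        grp = samples[samples["group"] == code]
        if len(grp) < pool_size:
            raise ValueError(
                f"{label} group has {len(grp)} samples; pool_size={pool_size}"
            )
        asc = grp.sort_values(["p_low", "sample_id"], ascending=[True, True])
        desc = grp.sort_values(["p_low", "sample_id"], ascending=[False, True])
        pools[f"{label}_top"] = tuple(asc["sample_id"].head(pool_size))
        pools[f"{label}_bottom"] = tuple(desc["sample_id"].head(pool_size))
    return QualityPools(**pools)


def build_subsets(
    samples: pd.DataFrame,
    n_iterations: int = 3,
    seed: int = 0,
    pool_size: int = 15,
    group_size: int = 10,
    source_dataset: str = "dataset",
) -> list[SubsetSpec]:
    """Draw 4 x n_iterations quality-stratified subsets.

    Per iteration: one ``group_size`` draw (without replacement) from each
    of the four pools; the two control draws and two disease draws are
    combined into the BB, BT, TB and TT combos. Deterministic given
    ``seed``; each subset's QI index (point-biserial) is computed on its own
    20 samples.
    """
    samples = validate_sample_table(samples)
    if pool_size < group_size:
        raise ValueError(f"pool_size={pool_size} cannot supply groups of {group_size}")
    pools = build_pools(samples, pool_size=pool_size)
    by_id = samples.set_index("sample_id")
    rng = np.random.default_rng(seed)
    specs = []
    for it in range(1, n_iterations + 1):
        draws = {
            "control_B": rng.choice(pools.control_bottom, group_size, replace=False),
            "control_T": rng.choice(pools.control_top, group_size, replace=False),
            "disease_B": rng.choice(pools.disease_bottom, group_size, replace=False),
            "disease_T": rng.choice(pools.disease_top, group_size, replace=False),
        }
        for combo in COMBOS:
            ctrl = tuple(draws[f"control_{combo[0]}"])
            dis = tuple(draws[f"disease_{combo[1]}"])
            sub = by_id.loc[list(ctrl) + list(dis)].reset_index()
            qi_value = qi.qi_pearson(sub).value
            specs.append(SubsetSpec(
                source_dataset=source_dataset, iteration=it, combo=combo,
                control_ids=ctrl, disease_ids=dis, qi_value=qi_value,
            ))
    return specs


def subset_sample_table(spec: SubsetSpec, samples: pd.DataFrame) -> pd.DataFrame:
    """Sample table restricted to one subset's members."""
    samples = validate_sample_table(samples)
    by_id = samples.set_index("sample_id")
    sub = by_id.loc[list(spec.control_ids) + list(spec.disease_ids)].reset_index()
    # subsets ignore any pairing of the source dataset
    sub["pair_id"] = pd.NA
    return sub


def subset_response_curve(
    subsets: list[SubsetSpec],
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    fdr: float = 0.05,
    lfc: float = 1.0,
    use_lfc: bool = True,
) -> dict:
    """OLS of per-subset differential-gene count on subset QI.

    Runs the differential engine on every subset, counts significant genes,
    and fits DEG count ~ QI. Returns slope, intercept, R-squared and the
    per-subset table.
    """
    import statsmodels.api as sm

    qi_values = [s.qi_value for s in subsets]
    if len(set(np.round(qi_values, 12))) < 3 or len(subsets) < 3:
        raise DegenerateInputError(
            "need >= 3 subsets with distinct QI values for a response curve"
        )
    rows = []
    for spec in subsets:
        sub_samples = subset_sample_table(spec, samples)
        sub_counts = counts[list(spec.control_ids) + list(spec.disease_ids)]
        try:
            result = de.run_de(sub_counts, sub_samples)
        except Exception as exc:
            raise PipelineError(
                f"differential engine failed on subset "
                f"{spec.source_dataset}/it{spec.iteration}/{spec.combo}: {exc}"
            ) from exc
        n_deg = len(de.significant_genes(result, fdr=fdr, lfc=lfc, use_lfc=use_lfc))
        rows.append({"iteration": spec.iteration, "combo": spec.combo,
                     "qi_value": spec.qi_value, "n_deg": n_deg})
    table = pd.DataFrame(rows)
    X = sm.add_constant(table["qi_value"].to_numpy(float))
    fit = sm.OLS(table["n_deg"].to_numpy(float), X).fit()
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "r_squared": float(fit.rsquared),
        "table": table,
    }


def subsets_to_frame(subsets: list[SubsetSpec]) -> pd.DataFrame:
    """Serialize subset specs to one row each (id lists comma-joined)."""
    return pd.DataFrame([
        {
            "source_dataset": s.source_dataset,
            "iteration": s.iteration,
            "combo": s.combo,
            "control_ids": ",".join(s.control_ids),
            "disease_ids": ",".join(s.disease_ids),
            "qi_value": s.qi_value,
        }
        for s in subsets
    ])
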