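"""Over-representation analysis (ORA) of gene lists against gene sets.

One-sided hypergeometric test (equivalently Fisher's exact upper tail) of
the overlap between a query gene list and each annotated gene set, within a
stated gene universe. Sets are intersected with the universe and size-
filtered before testing; adjustment is Bonferroni by default (BH available).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSetCollection:
    """Named gene sets with optional per-set descriptions/categories."""

    sets: dict[str, frozenset]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self):
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (tab-separated: name, description, gene, gene, ...).

    Genes duplicated within a line are counted once. Lines with fewer than
    three fields are rejected with the offending line number.
    """
    sets: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields; "
                    "GMT needs name, description and at least one gene"
                )
            name, desc, *genes = fields
            if name in sets:
                raise ValueError(f"{path}: duplicate set name {name!r} at line {lineno}")
            sets[name] = frozenset(g for g in genes if g)
            if not sets[name]:
                raise ValueError(f"{path}: set {name!r} at line {lineno} has no genes")
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def ora(
    query,
    sets: GeneSetCollection,
    universe,
    min_size: int = 15,
    max_size: int = 500,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Hypergeometric over-representation test of ``query`` against each set.

    For a universe of M genes, a set of K genes (after intersection with the
    universe) and a query of N genes with overlap x, the p-value is
    P[X >= x] for X ~ Hypergeometric(M, K, N). Sets outside
    [min_size, max_size] after intersection are not tested. Returns a
    DataFrame sorted by p with columns set, overlap, set_size, query_size,
    universe_size, p, padj.
    """
    universe = set(universe)
    query = set(query)
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query")
    if not query <= universe:
        raise ValueError(
            f"{len(query - universe)} query genes are outside the universe"
        )
    m = len(universe)
    n_query = len(query)
    rows = []
    for name, genes in sets.sets.items():
        in_universe = genes & universe
        k = len(in_universe)
        if not min_size <= k <= max_size:
            continue
        overlap = len(in_universe & query)
        p = stats.hypergeom.sf(overlap - 1, m, k, n_query)
        rows.append({"set": name, "overlap": overlap, "set_size": k,
                     "query_size": n_query, "universe_size": m, "p": float(p)})
    result = pd.DataFrame(rows, columns=["set", "overlap", "set_size",
                                         "query_size", "universe_size", "p"])
    if result.empty:
        result["padj"] = pd.Series(dtype=float)
        return result
    if adjust == "bonferroni":
        result["padj"] = (result["p"] * len(result)).clip(upper=1.0)
    elif adjust == "bh":
        result["padj"] = multipletests(result["p"], method="fdr_bh")[1]
    else:
        raise ValueError(f"unknown adjustment {adjust!r} (use 'bonferroni' or 'bh')")
    return result.sort_values(["p", "set"]).reset_index(drop=True)


def significant_sets(result: pd.DataFrame, alpha: float = 0.05) -> set[str]:
    """Sets with adjusted p-value below ``alpha`` (strict)."""
    if result.empty:
        return set()
    return set(result.loc[result["padj"] < alpha, "set"])
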