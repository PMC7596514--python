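"""Over-representation and preranked gene-set enrichment analysis.

ORA is the one-sided hypergeometric upper tail.  Preranked GSEA uses the
weighted Kolmogorov-Smirnov running statistic with a gene-label permutation
null.  Results from the three query lists of the pipeline (DEGs, top-500
cascade, top-1500 cascade) are combined per gene set as the arithmetic mean
of their p-values ("average p") and ranked ascending; the top sets per
collection are reported, with significance at average p < alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ora",
    "ora_collection",
    "gsea_es",
    "gsea_preranked",
    "average_p_rank",
    "read_gmt",
    "write_gmt",
]


def ora(
    query: Iterable[str], gene_set: Iterable[str], universe: Iterable[str]
) -> Dict[str, float]:
    """Hypergeometric over-representation p-value.

    p = P(X >= overlap), X ~ Hypergeom(N=|universe|, K=|set ∩ universe|,
    n=|query ∩ universe|).  The query is intersected with the universe
    first; an empty intersection returns p = 1 with a warning.
    """
    universe = set(universe)
    gene_set = set(gene_set) & universe
    query = set(query) & universe
    n_universe, n_set, n_query = len(universe), len(gene_set), len(query)
    if n_universe < n_set:
        raise ValueError("universe smaller than gene set")
    overlap = len(query & gene_set)
    if n_query == 0:
        warnings.warn("query empty after universe intersection; p = 1")
        return {"p": 1.0, "overlap": 0, "gene_ratio": 0.0}
    p = float(stats.hypergeom.sf(overlap - 1, n_universe, n_set, n_query))
    return {
        "p": min(p, 1.0),
        "overlap": overlap,
        "gene_ratio": overlap / n_query,
    }


def ora_collection(
    query: Iterable[str],
    sets: Mapping[str, Sequence[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """ORA for every set in a collection, with BH q within the collection."""
    universe = set(universe)
    rows = []
    for name in sorted(sets):
        res = ora(query, sets[name], universe)
        rows.append({"set": name, **res})
    df = pd.DataFrame(rows)
    df["q"] = multipletests(df["p"].values, method="fdr_bh")[1]
    return df


def gsea_es(
    ranking: pd.Series, gene_set: Iterable[str], weight: float = 1.0
) -> float:
    """Weighted KS enrichment score for a preranked list.

    Genes sorted by score descending; hit steps increment proportionally to
    |score|^weight, miss steps decrement uniformly; ES is the running-sum
    deviation of maximal magnitude (signed), in [-1, 1].
    """
    order = ranking.sort_values(ascending=False, kind="mergesort")
    in_set = order.index.isin(set(gene_set))
    if not in_set.any():
        raise ValueError("gene set disjoint from the ranking")
    w = np.abs(order.to_numpy(dtype=float)) ** weight
    hit_w = np.where(in_set, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all hit scores zero: fall back to unweighted steps
        hit_w = in_set.astype(float)
        total = hit_w.sum()
    n_miss = (~in_set).sum()
    if n_miss == 0:
        return 1.0
    running = np.cumsum(hit_w / total - (~in_set) / n_miss)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


@dataclass
class GseaResult:
    set: str
    es: float
    p: float
    n_genes: int
    overlap: int


def gsea_preranked(
    ranking: pd.Series,
    sets: Mapping[str, Sequence[str]],
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked GSEA over a collection with a gene-label permutation null.

    For each set, the null redraws |set ∩ ranking| gene labels at random
    ``n_perm`` times; the p-value is one-tailed on the side of the observed
    ES sign (+1 smoothing), and BH q is computed within the collection.
    Sets disjoint from the ranking are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    order = ranking.sort_values(ascending=False, kind="mergesort")
    genes = list(order.index)
    rows = []
    for name in sorted(sets):
        members = set(sets[name]) & set(genes)
        if not members:
            warnings.warn(f"set {name!r} disjoint from ranking; skipped")
            continue
        es = gsea_es(order, members, weight=weight)
        k = len(members)
        null = np.empty(n_perm)
        for b in range(n_perm):
            random_set = rng.choice(genes, size=k, replace=False)
            null[b] = gsea_es(order, random_set, weight=weight)
        if es >= 0:
            side = null[null >= 0]
            p = (1 + (side >= es).sum()) / (1 + len(side))
        else:
            side = null[null < 0]
            p = (1 + (side <= es).sum()) / (1 + len(side))
        rows.append(
            {"set": name, "es": es, "p": float(min(p, 1.0)),
             "overlap": k, "n_genes": len(genes)}
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q"] = multipletests(df["p"].values, method="fdr_bh")[1]
    return df


def average_p_rank(
    records: pd.DataFrame,
    top_n: int = 5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank gene sets by the mean p-value across query lists.

    ``records`` is long-form with columns (collection, set, list, p); a
    missing (set, list) entry is imputed as p = 1 (conservative, and flagged
    via ``n_lists_observed``).  Within each collection sets are sorted by
    average p ascending (ties: set id) and the top ``top_n`` flagged.
    """
    required = {"collection", "set", "list", "p"}
    if not required <= set(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    lists = sorted(records["list"].unique())
    wide = records.pivot_table(
        index=["collection", "set"], columns="list", values="p", aggfunc="first"
    ).reindex(columns=lists)
    n_obs = wide.notna().sum(axis=1)
    filled = wide.fillna(1.0)
    out = filled.copy()
    out.columns = [f"p_{c}" for c in filled.columns]
    out["average_p"] = filled.mean(axis=1)
    out["n_lists_observed"] = n_obs
    out = out.reset_index().sort_values(
        ["collection", "average_p", "set"], kind="mergesort"
    )
    out["rank"] = out.groupby("collection").cumcount() + 1
    out["top"] = out["rank"] <= top_n
    out["significant"] = out["average_p"] < alpha
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# GMT interchange
# ---------------------------------------------------------------------------

def read_gmt(path) -> Dict[str, List[str]]:
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            fh.write("\t".join([name, description, *sets[name]]) + "\n")
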