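"""Temporal clustering of DEGs and hypergeometric gene-set enrichment.

DEG expression profiles (row z-scores of normalized log2 values) are
clustered by Ward's method on Euclidean distances; each cluster is tested
for gene-set over-representation with an upper-tail hypergeometric test and
BH FDR across the collection. The number of clusters can be chosen by
minimizing the redundancy (mean pairwise Jaccard) of the clusters'
enriched-set lists.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests


@dataclass
class ClusterResult:
    assignments: pd.Series  # gene -> cluster id (1..k)
    zscores: pd.DataFrame
    linkage: np.ndarray

    def cluster_sizes(self, biotypes: pd.Series | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"cluster": self.assignments})
        if biotypes is not None:
            df["biotype"] = biotypes.reindex(df.index)
            return df.groupby(["cluster", "biotype"]).size().unstack(fill_value=0)
        return df.groupby("cluster").size().to_frame("n")


def row_zscore(values: pd.DataFrame) -> pd.DataFrame:
    """Per-gene standardization across samples; constant rows become 0."""
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=0)
    z = values.sub(mean, axis=0).div(sd.replace(0, np.nan), axis=0)
    return z.fillna(0.0)


def ward_cluster(z: pd.DataFrame, k: int) -> ClusterResult:
    """Agglomerative Ward clustering on Euclidean distances, cut at k."""
    n = z.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of genes ({n})")
    link = hierarchy.ward(pdist(z.values, metric="euclidean"))
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    return ClusterResult(
        assignments=pd.Series(labels, index=z.index, name="cluster"),
        zscores=z,
        linkage=link,
    )


def read_gmt(path: str) -> dict[str, set]:
    """Read a GMT gene-set collection (set name, description, members)."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = set(g for g in fields[2:] if g)
    return sets


def write_gmt(sets: dict[str, set], path: str) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\tna\t{members}\n")


def hypergeom_enrich(
    cluster_genes,
    collection: dict[str, set],
    universe,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each gene set in the cluster.

    Sets are intersected with the universe before testing; BH FDR is computed
    across the whole collection and sets with q < ``fdr`` are flagged.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    cluster = set(cluster_genes) & universe
    rows = []
    for name in sorted(collection):
        members = collection[name] & universe
        if not members:
            continue
        overlap = len(cluster & members)
        # P(X >= overlap), X ~ Hypergeom(N, K, n)
        p = stats.hypergeom.sf(
            overlap - 1, len(universe), len(members), len(cluster)
        )
        rows.append(
            {
                "set": name,
                "overlap": overlap,
                "set_size": len(members),
                "cluster_size": len(cluster),
                "universe_size": len(universe),
                "p": float(p),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
        table["enriched"] = table["q"] < fdr
        table = table.sort_values(["p", "set"]).reset_index(drop=True)
    return table


def _redundancy(enriched_lists: list[set]) -> float:
    """Mean pairwise Jaccard similarity of clusters' enriched-set lists."""
    pairs = list(itertools.combinations(range(len(enriched_lists)), 2))
    if not pairs:
        return 0.0
    vals = []
    for i, j in pairs:
        a, b = enriched_lists[i], enriched_lists[j]
        union = a | b
        vals.append(len(a & b) / len(union) if union else 0.0)
    return float(np.mean(vals))


def choose_k(
    z: pd.DataFrame,
    k_range,
    collection: dict[str, set],
    universe,
    fdr: float = 0.05,
) -> tuple[int, pd.DataFrame]:
    """Pick k minimizing cross-cluster enrichment redundancy.

    For each candidate k the DEGs are Ward-clustered, each cluster enriched
    against the collection, and the redundancy score (mean pairwise Jaccard
    of enriched-set lists) recorded. The winner is the largest k attaining
    the minimal score: redundancy stays low while clusters still separate
    distinct programs and rises once they over-split, so the finest
    non-redundant clustering is returned.
    """
    k_range = sorted(k_range)
    if not k_range:
        raise ValueError("empty k range")
    scores = []
    for k in k_range:
        res = ward_cluster(z, k)
        lists = []
        for c in sorted(res.assignments.unique()):
            genes = res.assignments.index[res.assignments == c]
            table = hypergeom_enrich(genes, collection, universe, fdr=fdr)
            enriched = (
                set(table.loc[table["enriched"], "set"]) if len(table) else set()
            )
            lists.append(enriched)
        scores.append({"k": k, "redundancy": _redundancy(lists)})
    table = pd.DataFrame(scores)
    minimal = table[table["redundancy"] == table["redundancy"].min()]
    best = int(minimal["k"].max())
    return best, table
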