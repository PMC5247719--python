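"""Guilt-by-association function inference for DE lncRNAs.

For each lncRNA, protein-coding genes are ranked by the Pearson correlation
of their expression with the lncRNA's profile; a weighted Kolmogorov-Smirnov
running sum (GSEA-style, weight exponent p) scores each gene set on that
ranked list. Significance uses a gene-set permutation null: random same-size
sets drawn from the ranked universe give the NES normalization and the
FDR ratio estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class RankedList:
    """Protein-coding genes ordered by descending correlation with a lncRNA."""

    lnc_id: str
    genes: list[str]
    metric: np.ndarray  # correlation per gene, same order

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.metric):
            raise ValueError("genes and metric lengths differ")


def rank_by_correlation(
    lnc_profile: pd.Series, pcg_matrix: pd.DataFrame, lnc_id: str = ""
) -> RankedList:
    """Pearson-correlation ranking of PCGs against one lncRNA profile.

    Constant PCG rows are excluded with a warning; ties break by gene id.
    """
    if len(lnc_profile) < 3:
        raise ValueError("need >=3 samples for correlation ranking")
    x = lnc_profile.values.astype(float)
    if x.std() == 0:
        raise ValueError("constant lncRNA profile")
    m = pcg_matrix[lnc_profile.index].values.astype(float)
    sds = m.std(axis=1)
    constant = sds == 0
    if constant.any():
        logger.warning("excluding %d constant PCG profiles", int(constant.sum()))
    xc = x - x.mean()
    mc = m - m.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (mc @ xc) / (np.linalg.norm(mc, axis=1) * np.linalg.norm(xc))
    genes = np.asarray(pcg_matrix.index)
    keep = ~constant
    order = sorted(
        range(int(keep.sum())),
        key=lambda i: (-r[keep][i], genes[keep][i]),
    )
    return RankedList(
        lnc_id=lnc_id,
        genes=[str(g) for g in genes[keep][order]],
        metric=r[keep][order],
    )


def gsea_es(
    ranked: RankedList, gene_set: set, weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score and the full running-sum profile.

    Hits add |r_i|^p / sum_hits |r|^p, misses subtract 1/(N - N_hits); the ES
    is the running sum's maximum deviation from zero (sign retained).
    """
    hits = np.array([g in gene_set for g in ranked.genes])
    n = len(ranked.genes)
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValueError("gene set does not intersect the ranked list")
    w = np.abs(ranked.metric) ** weight
    hit_w = np.where(hits, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        # all hit correlations exactly zero: fall back to unweighted steps
        hit_w = hits.astype(float)
        denom = hit_w.sum()
    if n_hits == n:
        steps = hit_w / denom
    else:
        miss_pen = 1.0 / (n - n_hits)
        steps = hit_w / denom - np.where(hits, 0.0, miss_pen)
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), running


def _null_es(
    ranked: RankedList, set_size: int, n_perm: int, weight: float, rng
) -> np.ndarray:
    n = len(ranked.genes)
    out = np.empty(n_perm)
    genes = ranked.genes
    for b in range(n_perm):
        idx = rng.choice(n, size=set_size, replace=False)
        null_set = {genes[i] for i in idx}
        out[b], _ = gsea_es(ranked, null_set, weight)
    return out


def gsea_nes_fdr(
    ranked: RankedList,
    collection: dict[str, set],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    fdr: float = 0.25,
    min_size: int = 2,
) -> pd.DataFrame:
    """NES and permutation FDR over a gene-set collection for one ranked list.

    The null distribution per set size comes from random same-size sets drawn
    from the ranked universe. NES = ES / mean(|null ES| of the same sign);
    FDR follows the standard NES-ratio estimator. Fully reproducible for a
    fixed seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    universe = set(ranked.genes)
    rows = []
    null_by_size: dict[int, np.ndarray] = {}
    for name in sorted(collection):
        members = collection[name] & universe
        if len(members) < min_size:
            continue
        es, _ = gsea_es(ranked, members, weight)
        size = len(members)
        if size not in null_by_size:
            null_by_size[size] = _null_es(ranked, size, n_perm, weight, rng)
        null = null_by_size[size]
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        mean_mag = np.abs(same_sign).mean() if same_sign.size else np.nan
        nes = es / mean_mag if mean_mag and np.isfinite(mean_mag) else np.nan
        if same_sign.size:
            p = float(np.mean(np.abs(same_sign) >= abs(es)))
        else:
            p = 1.0
        rows.append(
            {"lnc_id": ranked.lnc_id, "set": name, "size": size, "es": es,
             "nes": nes, "p": p}
        )
    table = pd.DataFrame(rows)
    if not len(table):
        return table
    # NES-based FDR: for each observed NES*, the fraction of null NES at
    # least as extreme (same sign, normalized the same way) over the
    # fraction of observed NES at least as extreme
    null_nes = []
    for size, null in null_by_size.items():
        pos, neg = null[null >= 0], null[null < 0]
        if pos.size:
            null_nes.append(pos / np.abs(pos).mean())
        if neg.size:
            null_nes.append(neg / np.abs(neg).mean())
    null_nes = np.concatenate(null_nes) if null_nes else np.array([])
    obs = table["nes"].values
    qs = np.empty(len(table))
    for i, nes in enumerate(obs):
        if not np.isfinite(nes):
            qs[i] = 1.0
            continue
        if nes >= 0:
            num_pool = null_nes[null_nes >= 0]
            num = np.mean(num_pool >= nes) if num_pool.size else 1.0
            den_pool = obs[np.isfinite(obs) & (obs >= 0)]
            den = np.mean(den_pool >= nes) if den_pool.size else 1.0
        else:
            num_pool = null_nes[null_nes < 0]
            num = np.mean(num_pool <= nes) if num_pool.size else 1.0
            den_pool = obs[np.isfinite(obs) & (obs < 0)]
            den = np.mean(den_pool <= nes) if den_pool.size else 1.0
        qs[i] = min(1.0, num / den) if den > 0 else 1.0
    table["fdr"] = qs
    table["flagged"] = table["fdr"] < fdr
    return table.sort_values(["fdr", "p", "set"]).reset_index(drop=True)


def association_matrix(
    results: pd.DataFrame, categories: dict[str, str] | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """lncRNA x gene-set NES matrix with non-significant cells masked (NaN).

    ``categories`` maps set name to a category tag (e.g. S, IR, EM, N, ECM);
    unmapped sets get "uncategorized".
    """
    if not len(results):
        return pd.DataFrame(), pd.Series(dtype=object)
    mat = results.pivot_table(
        index="lnc_id", columns="set", values="nes", aggfunc="first"
    )
    sig = results.pivot_table(
        index="lnc_id", columns="set", values="flagged", aggfunc="first"
    ).fillna(False).astype(bool)
    masked = mat.where(sig.reindex_like(mat))
    cats = pd.Series(
        {
            s: (categories or {}).get(s, "uncategorized")
            for s in masked.columns
        },
        name="category",
    )
    return masked, cats
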