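"""Expression-matrix QC: FPKM flooring/filtering, log2 quantile
normalization, sample correlation, dendrogram, and outlier detection."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample group/batch metadata.

    ``mode`` is ``"fpkm"`` (non-negative reals) or ``"counts"`` (non-negative
    integers).
    """

    values: pd.DataFrame  # genes x samples
    groups: pd.Series  # sample -> group
    batches: pd.Series | None = None
    mode: str = "fpkm"

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing cells")
        if self.mode not in ("fpkm", "counts", "normalized"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode != "normalized" and (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group metadata: {sorted(missing)}")
        if self.mode == "counts":
            vals = self.values.values
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts mode requires integer values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, keep: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[keep],
            self.groups.loc[keep],
            None if self.batches is None else self.batches.loc[keep],
            self.mode,
        )

    @classmethod
    def from_tsv(
        cls, matrix_path: str, samples_path: str, mode: str = "fpkm"
    ) -> "ExpressionMatrix":
        """Load from a TSV matrix (first column gene_id) and a sample sheet
        with columns sample_id, group[, batch]."""
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        sheet = pd.read_csv(samples_path, sep="\t")
        sheet = sheet.set_index("sample_id")
        groups = sheet["group"]
        batches = sheet["batch"] if "batch" in sheet.columns else None
        return cls(values, groups, batches, mode)


@dataclass
class SampleSimilarity:
    correlation: pd.DataFrame
    linkage: np.ndarray
    groups: pd.Series
    within_group_mean: pd.Series
    outliers: list[str] = field(default_factory=list)


def floor_fpkm(m: ExpressionMatrix, floor: float = 0.1) -> ExpressionMatrix:
    """Raise every FPKM below ``floor`` to ``floor`` (ratio-inflation guard)."""
    if m.mode != "fpkm":
        raise TypeError("floor_fpkm requires an FPKM matrix")
    return ExpressionMatrix(m.values.clip(lower=floor), m.groups, m.batches, "fpkm")


def filter_expressed(m: ExpressionMatrix, threshold: float = 1.0) -> ExpressionMatrix:
    """Keep genes whose maximum FPKM over samples is strictly > ``threshold``."""
    if m.mode != "fpkm":
        raise TypeError("filter_expressed requires an FPKM matrix")
    keep = m.values.max(axis=1) > threshold
    return ExpressionMatrix(m.values.loc[keep], m.groups, m.batches, "fpkm")


def log2_quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2-transform, then mean-rank quantile normalization.

    After the transform each column's sorted values are identical (the mean of
    the per-column sorted log2 vectors); ties within a column receive the
    average of the target values at their ranks.
    """
    if m.mode != "fpkm":
        raise TypeError("log2_quantile_normalize requires an FPKM matrix")
    logged = np.log2(m.values.values)
    order = np.sort(logged, axis=0)
    target = order.mean(axis=1)
    out = np.empty_like(logged)
    for j in range(logged.shape[1]):
        col = logged[:, j]
        ranks = stats.rankdata(col, method="average")  # 1-based, ties averaged
        # interpolate target at fractional (tie-averaged) ranks
        out[:, j] = np.interp(ranks, np.arange(1, len(col) + 1), target)
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(values, m.groups, m.batches, "normalized")


def sample_correlation(m: ExpressionMatrix) -> SampleSimilarity:
    """Pairwise Pearson correlation between samples plus an average-linkage
    tree on Euclidean distances; values are taken as given (normalize first)."""
    if m.values.shape[1] < 2:
        raise ValueError("need >=2 samples")
    vals = m.values
    constant = vals.std(axis=0) == 0
    if constant.any():
        logger.warning(
            "constant sample profiles excluded from correlation means: %s",
            list(vals.columns[constant]),
        )
    corr = vals.corr(method="pearson")
    link = hierarchy.average(pdist(vals.values.T, metric="euclidean"))
    within = {}
    for s in vals.columns:
        peers = [
            t
            for t in vals.columns
            if t != s and m.groups[t] == m.groups[s] and not constant[t]
        ]
        within[s] = float(corr.loc[s, peers].mean()) if peers else np.nan
    return SampleSimilarity(
        correlation=corr,
        linkage=link,
        groups=m.groups.loc[vals.columns],
        within_group_mean=pd.Series(within),
    )


def detect_outliers(s: SampleSimilarity, k: float = 2.0) -> list[str]:
    """Flag samples whose mean within-group correlation falls more than
    ``k`` SD below the across-sample mean of that statistic."""
    counts = s.groups.value_counts()
    if (counts < 2).any():
        raise ValueError("every group needs >=2 replicates for outlier detection")
    w = s.within_group_mean.dropna()
    mean, sd = w.mean(), w.std(ddof=1)
    if sd == 0:
        return []
    flagged = sorted(w.index[w < mean - k * sd])
    s.outliers = list(flagged)
    return list(flagged)


def ks_compare(a, b) -> dict:
    """Two-sample Kolmogorov-Smirnov comparison (asymptotic p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return {"D": float(res.statistic), "p": float(res.pvalue)}
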