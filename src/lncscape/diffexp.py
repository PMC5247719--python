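"""Negative-binomial differential expression and the qPCR 2^-ddCt utility.

The test is the classic exact negative-binomial test for count data:
per-sample size factors by the median-of-ratios method, per-gene dispersion
by method of moments pooled within conditions with a parametric trend
alpha(mu) = a0/mu + a1 and a conservative max(raw, fitted) choice, and a
conditional exact test that, given the total count of a gene across both
conditions, sums the probabilities of all partitions no more likely than the
observed one.

Counts are modelled as K_ij ~ NB(mean = s_j q_i, variance = mu + alpha mu^2).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from lncscape.expression_qc import ExpressionMatrix

logger = logging.getLogger(__name__)

_MIN_DISP = 1e-8


@dataclass
class SizeFactors:
    factors: pd.Series  # sample -> s_j > 0

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("size factors must be positive")


@dataclass
class DispersionFit:
    raw: pd.Series  # per-gene method-of-moments dispersion (may be <= 0)
    trend_a0: float
    trend_a1: float
    fitted: pd.Series
    final: pd.Series  # max(raw, fitted), floored at a tiny positive value

    def trend(self, mu) -> np.ndarray:
        mu = np.asarray(mu, dtype=float)
        return self.trend_a0 / np.maximum(mu, 1e-12) + self.trend_a1


def size_factors(counts: ExpressionMatrix, pseudo_reference: bool = False) -> SizeFactors:
    """Median-of-ratios size factors.

    s_j = median over reference genes of K_ij / geometric-mean_i(K_i.). The
    reference set is the genes with nonzero counts in every sample; with
    ``pseudo_reference`` the geometric mean ignores zeros instead (fallback
    for sparse matrices).
    """
    if counts.mode != "counts":
        raise TypeError("size_factors requires a counts matrix")
    k = counts.values.values.astype(float)
    with np.errstate(divide="ignore"):
        logk = np.log(k)
    all_nonzero = np.all(k > 0, axis=1)
    if pseudo_reference:
        ref = np.any(k > 0, axis=1)
        loggeo = np.array(
            [row[row > -np.inf].mean() for row in logk[ref]]
        )
        logratios = logk[ref] - loggeo[:, None]
    else:
        if not all_nonzero.any():
            raise ValueError(
                "no gene has nonzero counts in all samples; "
                "re-run with pseudo_reference=True"
            )
        loggeo = logk[all_nonzero].mean(axis=1)
        logratios = logk[all_nonzero] - loggeo[:, None]
    logger.info("size factors use %d reference genes", logratios.shape[0])
    s = np.exp(np.nanmedian(np.where(np.isfinite(logratios), logratios, np.nan), axis=0))
    return SizeFactors(pd.Series(s, index=counts.values.columns))


def estimate_dispersion(
    counts: ExpressionMatrix, sf: SizeFactors, groups: pd.Series | None = None
) -> DispersionFit:
    """Method-of-moments dispersion pooled within groups plus parametric trend.

    raw_i = (w_i - z_i) / mu_i^2 where w_i is the pooled within-group variance
    of normalized counts, z_i = mu_i * mean(1/s_j) the sampling-noise term.
    The trend alpha(mu) = a0/mu + a1 is least-squares fit over genes with
    positive raw dispersion; the final value is max(raw, fitted).
    """
    if counts.mode != "counts":
        raise TypeError("estimate_dispersion requires a counts matrix")
    if groups is None:
        groups = counts.groups
    k = counts.values.values.astype(float)
    s = sf.factors.loc[counts.values.columns].values
    q = k / s[None, :]
    group_labels = groups.loc[counts.values.columns]
    # groups with >=2 replicates contribute to the pooled variance
    rep_groups = [
        g for g, n in group_labels.value_counts().items() if n >= 2
    ]
    if not rep_groups:
        raise ValueError("dispersion estimation needs >=2 replicates in >=1 group")
    cols_used = group_labels.isin(rep_groups).values
    n_used = int(cols_used.sum())
    n_groups = len(rep_groups)
    ss = np.zeros(k.shape[0])
    for g in rep_groups:
        sel = (group_labels == g).values
        sub = q[:, sel]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    w = ss / (n_used - n_groups)
    mu = q.mean(axis=1)
    z = mu * np.mean(1.0 / s)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (w - z) / mu**2
    raw = np.where(np.isfinite(raw), raw, np.nan)

    ok = np.isfinite(raw) & (raw > 0) & (mu > 0)
    if ok.sum() >= 2:
        X = np.column_stack([1.0 / mu[ok], np.ones(ok.sum())])
        coef, *_ = np.linalg.lstsq(X, raw[ok], rcond=None)
        a0, a1 = float(coef[0]), float(coef[1])
    else:
        a0, a1 = 0.0, float(np.nanmax(raw)) if np.isfinite(np.nanmax(raw)) else 0.0
        logger.warning("too few genes with positive dispersion for trend fit")
    with np.errstate(divide="ignore"):
        fitted = np.maximum(a0 / np.maximum(mu, 1e-12) + a1, _MIN_DISP)
    final = np.maximum(np.where(np.isnan(raw), -np.inf, raw), fitted)
    final = np.maximum(final, _MIN_DISP)
    idx = counts.values.index
    return DispersionFit(
        raw=pd.Series(raw, index=idx),
        trend_a0=a0,
        trend_a1=a1,
        fitted=pd.Series(fitted, index=idx),
        final=pd.Series(final, index=idx),
    )


def _nb_logpmf(x: np.ndarray, mean: float, variance: float) -> np.ndarray:
    """NB log-pmf parameterized by mean/variance; Poisson limit as var -> mean."""
    if variance <= mean * (1 + 1e-8):
        return stats.poisson.logpmf(x, mean)
    size = mean**2 / (variance - mean)
    prob = size / (size + mean)
    return stats.nbinom.logpmf(x, size, prob)


def nb_exact_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    sf_a: np.ndarray,
    sf_b: np.ndarray,
    dispersion: float,
) -> float:
    """Conditional exact NB test for one gene.

    Conditions on K_S = K_A + K_B (summed over replicates per condition) and
    sums the probabilities of all partitions (a, K_S - a) no more likely than
    the observed one, under NB laws whose means come from the pooled rate and
    whose variances follow mu + alpha q0^2 sum(s_j^2).
    """
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    sf_a = np.asarray(sf_a, dtype=float)
    sf_b = np.asarray(sf_b, dtype=float)
    if counts_a.size == 0 or counts_b.size == 0:
        raise ValueError("both conditions need >=1 sample")
    ka, kb = counts_a.sum(), counts_b.sum()
    ks = int(round(ka + kb))
    if ks == 0:
        return 1.0
    q0 = ks / (sf_a.sum() + sf_b.sum())
    mu_a = q0 * sf_a.sum()
    mu_b = q0 * sf_b.sum()
    var_a = mu_a + dispersion * q0**2 * (sf_a**2).sum()
    var_b = mu_b + dispersion * q0**2 * (sf_b**2).sum()
    a_grid = np.arange(ks + 1)
    logp = _nb_logpmf(a_grid, mu_a, var_a) + _nb_logpmf(ks - a_grid, mu_b, var_b)
    log_obs = _nb_logpmf(np.array([ka]), mu_a, var_a)[0] + _nb_logpmf(
        np.array([kb]), mu_b, var_b
    )[0]
    keep = logp <= log_obs + 1e-7
    # normalized in log space for numerical stability
    m = logp.max()
    total = np.exp(logp - m).sum()
    tail = np.exp(logp[keep] - m).sum()
    return float(min(1.0, tail / total))


def call_degs(
    counts: ExpressionMatrix,
    fpkm: ExpressionMatrix,
    comparison: tuple[str, str],
    biotypes: pd.Series | None = None,
    expressed_threshold: float = 1.0,
    fc_threshold: float = 2.0,
    fdr: float = 0.01,
    floor: float = 0.1,
) -> pd.DataFrame:
    """Differential-expression calls for one (treatment, control) comparison.

    A gene is a DEG when all three criteria hold: FPKM > ``expressed_threshold``
    in at least one sample, fold-change of mean normalized counts > ``fc_threshold``
    in either direction, and BH FDR < ``fdr``. BH is applied over the genes
    passing the expressed filter.
    """
    group, control = comparison
    for g in (group, control):
        if not (counts.groups == g).any():
            raise ValueError(f"comparison group {g!r} absent from sample sheet")
    if list(counts.values.index) != list(fpkm.values.index):
        raise ValueError("counts and FPKM matrices must share the gene set")

    sf = size_factors(counts)
    samples_a = [s for s in counts.sample_ids if counts.groups[s] == control]
    samples_b = [s for s in counts.sample_ids if counts.groups[s] == group]
    sub = counts.subset_samples(samples_a + samples_b)
    disp = estimate_dispersion(sub, sf)

    expressed = fpkm.values.max(axis=1) > expressed_threshold
    universe = counts.values.index[expressed]

    ka = counts.values[samples_a].values
    kb = counts.values[samples_b].values
    sa = sf.factors.loc[samples_a].values
    sb = sf.factors.loc[samples_b].values
    mean_a = (ka / sa[None, :]).mean(axis=1)
    mean_b = (kb / sb[None, :]).mean(axis=1)
    fc = np.maximum(mean_b, floor) / np.maximum(mean_a, floor)

    gene_pos = {g: i for i, g in enumerate(counts.values.index)}
    pvals = np.full(len(universe), np.nan)
    for n, g in enumerate(universe):
        i = gene_pos[g]
        pvals[n] = nb_exact_test(ka[i], kb[i], sa, sb, float(disp.final.iloc[i]))
    if len(universe):
        qvals = multipletests(pvals, method="fdr_bh")[1]
    else:
        qvals = np.array([])

    rows = pd.DataFrame(
        {
            "gene_id": list(counts.values.index),
            "mean_control": mean_a,
            "mean_treatment": mean_b,
            "fc": fc,
            "log2fc": np.log2(fc),
            "max_fpkm": fpkm.values.max(axis=1).values,
        }
    ).set_index("gene_id")
    rows["p"] = np.nan
    rows.loc[universe, "p"] = pvals
    rows["q"] = np.nan
    rows.loc[universe, "q"] = qvals
    rows["expressed"] = expressed.values
    fc_pass = (rows["fc"] > fc_threshold) | (rows["fc"] < 1.0 / fc_threshold)
    rows["deg"] = rows["expressed"] & fc_pass & (rows["q"] < fdr)
    rows["direction"] = np.where(rows["fc"] > 1, "up", "down")
    if biotypes is not None:
        rows["biotype"] = biotypes.reindex(rows.index)
    rows.attrs["comparison"] = f"{group}:vs:{control}"
    rows.attrs["fc_scale"] = "linear ratio, either direction"
    return rows.reset_index()


def deg_tally(deg_table: pd.DataFrame) -> pd.DataFrame:
    """Per-biotype up/down tallies in the layout of a summary DEG table."""
    if "biotype" not in deg_table.columns:
        raise ValueError("tally needs a biotype column")
    sub = deg_table[deg_table["deg"]]
    out = []
    for biotype, grp in sub.groupby("biotype"):
        out.append(
            {
                "biotype": biotype,
                "total": len(grp),
                "up": int((grp["direction"] == "up").sum()),
                "down": int((grp["direction"] == "down").sum()),
            }
        )
    return pd.DataFrame(out)


def venn_partition(deg_sets: dict[str, set]) -> dict[frozenset, int]:
    """Counts for every non-empty membership region across the sets."""
    if len(deg_sets) < 2:
        raise ValueError("need >=2 sets")
    names = sorted(deg_sets)
    out: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(deg_sets[n] for n in combo))
            outside = set.union(
                set(), *(deg_sets[n] for n in names if n not in combo)
            )
            out[frozenset(combo)] = len(inside - outside)
    return out


def ddct_rq(
    ct: pd.DataFrame, calibrator: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Relative qPCR quantification by the 2^-ddCt method.

    ``ct`` columns: sample, group, ct_target, ct_reference. dCt is target
    minus reference; ddCt subtracts the calibrator-group mean dCt; RQ =
    2^-ddCt. Per-group RQ mean +/- SD and a Welch t-test of dCt versus the
    calibrator group are reported.
    """
    required = {"sample", "group", "ct_target", "ct_reference"}
    if not required <= set(ct.columns):
        raise ValueError(f"ct table needs columns {sorted(required)}")
    ct = ct.copy()
    missing = ct["ct_reference"].isna() | ct["ct_target"].isna()
    if missing.any():
        logger.warning("dropping %d samples with missing Ct", int(missing.sum()))
        ct = ct[~missing]
    if not (ct["group"] == calibrator).any():
        raise ValueError(f"calibrator group {calibrator!r} absent")
    ct["dct"] = ct["ct_target"] - ct["ct_reference"]
    cal_mean = ct.loc[ct["group"] == calibrator, "dct"].mean()
    ct["ddct"] = ct["dct"] - cal_mean
    ct["rq"] = 2.0 ** (-ct["ddct"])
    cal_dct = ct.loc[ct["group"] == calibrator, "dct"]
    rows = []
    for g, grp in ct.groupby("group", sort=False):
        if g == calibrator or len(grp) < 2 or len(cal_dct) < 2:
            t = p = np.nan
        else:
            t, p = stats.ttest_ind(grp["dct"], cal_dct, equal_var=False)
        rows.append(
            {
                "group": g,
                "rq_mean": float(grp["rq"].mean()),
                "rq_sd": float(grp["rq"].std(ddof=1)) if len(grp) > 1 else np.nan,
                "t": float(t) if np.isfinite(t) else np.nan,
                "p": float(p) if np.isfinite(p) else np.nan,
                "significant": bool(np.isfinite(p) and p < alpha),
            }
        )
    summary = pd.DataFrame(rows)
    summary.attrs["per_sample"] = ct
    return summary
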