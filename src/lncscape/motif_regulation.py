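"""Regulatory-region extraction and PWM motif scanning with exact p-values.

Regulatory regions span 5 kb upstream to 1 kb downstream of each lncRNA TSS
(downstream capped at the transcript length for short transcripts). Regions
are scanned on both strands with log2 log-odds scores against a zero-order
background; per-window p-values are exact, computed from the full score
distribution under the background via dynamic programming on integerized
scores. BH FDR is applied across all (motif, window) tests of a run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from lncscape.annotation_io import GenomicInterval, TranscriptModel

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT_ORDER = [3, 2, 1, 0]  # A<->T, C<->G row swap


@dataclass
class PWM:
    """Position weight matrix: per-column base probabilities plus background."""

    motif_id: str
    tf_name: str
    probs: np.ndarray  # 4 x w, rows in A,C,G,T order
    background: np.ndarray  # length 4

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4 or self.probs.shape[1] < 1:
            raise ValueError(f"{self.motif_id}: PWM must be 4 x w with w >= 1")
        if (self.probs < 0).any():
            raise ValueError(f"{self.motif_id}: negative probabilities")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError(f"{self.motif_id}: columns must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError(f"{self.motif_id}: background must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    def log_odds(self, pseudocount: float = 1e-4) -> np.ndarray:
        """log2(p/b) per cell, with a small pseudocount to avoid -inf."""
        p = (self.probs + pseudocount) / (1 + 4 * pseudocount)
        b = (self.background + pseudocount) / (1 + 4 * pseudocount)
        return np.log2(p / b[:, None])

    def reverse_complement(self) -> "PWM":
        return PWM(
            self.motif_id,
            self.tf_name,
            self.probs[_COMPLEMENT_ORDER, ::-1],
            self.background[_COMPLEMENT_ORDER],
        )

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=0))


def read_meme(path: str) -> list[PWM]:
    """Read PWMs from MEME minimal format (matrices via Bio.motifs).

    The minimal parser discards the alternate (TF) name on MOTIF lines, so
    that field is recovered with a pre-scan; when absent the TF defaults to
    the first ``_``-separated token of the motif id (ENCODE convention).
    """
    from Bio import motifs as bio_motifs

    alt_names: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("MOTIF"):
                parts = line.split()
                if len(parts) >= 3:
                    alt_names[parts[1]] = parts[2]
    with open(path) as fh:
        record = bio_motifs.parse(fh, "minimal")
    out = []
    for m in record:
        probs = np.array([[m.pwm[b][j] for j in range(m.length)] for b in BASES])
        probs = probs / probs.sum(axis=0, keepdims=True)
        bg = np.array([m.background[b] for b in BASES])
        motif_id = m.name or ""
        tf = alt_names.get(motif_id) or motif_id.split("_")[0]
        out.append(PWM(motif_id, tf, probs, bg / bg.sum()))
    return out


def write_meme(pwms: list[PWM], path: str) -> None:
    """Write PWMs in MEME minimal format."""
    if not pwms:
        raise ValueError("no PWMs to write")
    bg = pwms[0].background
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{b} {f:.5f}" for b, f in zip(BASES, bg)) + "\n\n"
        )
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id} {pwm.tf_name}\n")
            # large nsites: readers that quantize probabilities to counts
            # keep 1e-6 precision
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 1000000 E= 0\n"
            )
            for j in range(pwm.width):
                fh.write(
                    " ".join(f"{pwm.probs[i, j]:.6f}" for i in range(4)) + "\n"
                )
            fh.write("\n")


@dataclass
class RegulatoryRegion:
    lnc_id: str
    interval: GenomicInterval
    truncated: bool = False


def regulatory_region(
    lnc: TranscriptModel,
    chrom_length: int,
    upstream: int = 5000,
    downstream: int = 1000,
) -> RegulatoryRegion:
    """5 kb upstream to 1 kb downstream of the TSS, strand-aware.

    A transcript shorter than the downstream extent caps it at its own span
    length; the region is truncated at chromosome ends (flagged).
    """
    span = lnc.span
    d = min(downstream, len(span))
    if lnc.strand == "+":
        start = span.start - upstream
        end = span.start + d
    else:
        start = span.end - d
        end = span.end + upstream
    truncated = start < 0 or end > chrom_length
    start = max(0, start)
    end = min(chrom_length, end)
    if truncated:
        logger.warning("%s: regulatory region truncated at chromosome edge", lnc.transcript_id)
    return RegulatoryRegion(
        lnc_id=lnc.gene_id,
        interval=GenomicInterval(span.chrom, start, end, lnc.strand),
        truncated=truncated,
    )


# ---------------------------------------------------------------------------
# Exact score distribution


def integer_scores(log_odds: np.ndarray, precision: float = 1e-3) -> np.ndarray:
    """Integerized score matrix (units of ``precision`` bits)."""
    return np.round(log_odds / precision).astype(np.int64)


def score_distribution(
    int_scores: np.ndarray, background: np.ndarray
) -> tuple[np.ndarray, int]:
    """Exact pmf of the window score under the zero-order background.

    Returns (pmf over integer scores, offset) where pmf[i] is the probability
    of integer score i + offset. Dynamic programming column by column.
    """
    w = int_scores.shape[1]
    mins = int_scores.min(axis=0)
    maxs = int_scores.max(axis=0)
    offset = int(mins.sum())
    size = int((maxs - mins).sum()) + 1
    pmf = np.zeros(size)
    pmf[0] = 1.0
    pos = 0  # current filled length - 1
    for j in range(w):
        col = int_scores[:, j] - mins[j]
        new = np.zeros(size)
        for b in range(4):
            shift = int(col[b])
            new[shift : pos + 1 + shift] += background[b] * pmf[: pos + 1]
        pmf = new
        pos += int(maxs[j] - mins[j])
    return pmf, offset


def exact_pvalues(
    int_scores: np.ndarray, background: np.ndarray
) -> tuple[np.ndarray, int]:
    """Survival function P(score >= s) over the integer score support."""
    pmf, offset = score_distribution(int_scores, background)
    sf = np.cumsum(pmf[::-1])[::-1]
    return np.minimum(sf, 1.0), offset


def scan(
    pwm: PWM,
    seq: str,
    precision: float = 1e-3,
    pseudocount: float = 1e-4,
    both_strands: bool = True,
) -> pd.DataFrame:
    """Score every window of ``seq`` against the PWM on both strands.

    Returns one row per (offset, strand) with the log2 log-odds score and its
    exact p-value under the PWM's background; windows containing N are
    skipped. Offsets always refer to the forward sequence.
    """
    seq = seq.upper()
    w = pwm.width
    if w > len(seq):
        return pd.DataFrame(columns=["offset", "strand", "score", "p"])
    codes = np.array(
        [_BASE_INDEX.get(c, -1) for c in seq], dtype=np.int64
    )
    lo_fwd = integer_scores(pwm.log_odds(pseudocount), precision)
    strands = [("+", lo_fwd, *exact_pvalues(lo_fwd, pwm.background))]
    if both_strands:
        # null distribution of the rc matrix under the same (sequence-side)
        # background; differs from the forward null unless bg is symmetric
        lo_rev = integer_scores(
            pwm.reverse_complement().log_odds(pseudocount), precision
        )
        strands.append(("-", lo_rev, *exact_pvalues(lo_rev, pwm.background)))
    n_win = len(seq) - w + 1
    valid = np.ones(n_win, dtype=bool)
    bad = codes < 0
    if bad.any():
        cum = np.cumsum(bad)
        window_bad = cum[w - 1 :] - np.concatenate([[0], cum[: n_win - 1]])
        valid &= window_bad == 0
    rows = []
    col_idx = np.arange(w)
    for strand, mat, sf, offset in strands:
        for i in np.nonzero(valid)[0]:
            window = codes[i : i + w]
            s = int(mat[window, col_idx].sum())
            rows.append(
                {
                    "offset": int(i),
                    "strand": strand,
                    "score": s * precision,
                    "p": float(sf[s - offset]),
                }
            )
    return pd.DataFrame(rows, columns=["offset", "strand", "score", "p"])


def scan_regions(
    pwms: list[PWM],
    region_seqs: dict[str, str],
    fdr: float = 0.05,
    precision: float = 1e-3,
    pseudocount: float = 1e-4,
) -> pd.DataFrame:
    """Scan every region with every PWM; BH across all (motif, window) tests.

    Returns the windows retained at q < ``fdr`` with columns motif_id,
    tf_name, region_id, offset, strand, score, p, q.
    """
    frames = []
    for pwm in pwms:
        for region_id, seq in region_seqs.items():
            hits = scan(pwm, seq, precision=precision, pseudocount=pseudocount)
            if len(hits):
                hits = hits.assign(
                    motif_id=pwm.motif_id, tf_name=pwm.tf_name, region_id=region_id
                )
                frames.append(hits)
    if not frames:
        return pd.DataFrame(
            columns=["motif_id", "tf_name", "region_id", "offset", "strand",
                     "score", "p", "q"]
        )
    all_hits = pd.concat(frames, ignore_index=True)
    all_hits["q"] = multipletests(all_hits["p"], method="fdr_bh")[1]
    kept = all_hits[all_hits["q"] < fdr].reset_index(drop=True)
    return kept[
        ["motif_id", "tf_name", "region_id", "offset", "strand", "score", "p", "q"]
    ]


def presence_matrix(
    retained_hits: pd.DataFrame,
    region_ids,
    tf_names,
    deg_tfs=(),
    highlight_threshold: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binary region x TF presence matrix plus per-TF region counts.

    A TF is present in a region when any of its motifs has a retained hit
    there. TFs present in more than ``highlight_threshold`` regions are
    highlighted; DE status comes from ``deg_tfs``.
    """
    region_ids = list(region_ids)
    tf_names = sorted(set(tf_names))
    mat = pd.DataFrame(0, index=region_ids, columns=tf_names, dtype=int)
    if len(retained_hits):
        present = retained_hits.groupby(["region_id", "tf_name"]).size()
        for (region, tf) in present.index:
            if region in mat.index and tf in mat.columns:
                mat.loc[region, tf] = 1
    counts = mat.sum(axis=0)
    deg_tfs = set(deg_tfs)
    summary = pd.DataFrame(
        {
            "tf": counts.index,
            "n_regions": counts.values,
            "highlighted": counts.values > highlight_threshold,
            "is_deg": [tf in deg_tfs for tf in counts.index],
        }
    ).sort_values("n_regions", ascending=False).reset_index(drop=True)
    return mat, summary


def tf_lnc_correlation(
    tf_expr: pd.DataFrame,
    lnc_expr: pd.DataFrame,
    r_min: float = 0.75,
    p_max: float = 0.01,
) -> dict:
    """Full Pearson matrix between TF and lncRNA expression, with a
    significance mask (|r| > r_min and p < p_max) and the positive/negative
    share among significant cells."""
    common = [s for s in tf_expr.columns if s in set(lnc_expr.columns)]
    if len(common) < 3:
        raise ValueError("need >=3 shared samples")
    t = tf_expr[common].values.astype(float)
    l = lnc_expr[common].values.astype(float)
    const_t = t.std(axis=1) == 0
    const_l = l.std(axis=1) == 0
    if const_t.any() or const_l.any():
        logger.warning(
            "excluding %d constant TF and %d constant lncRNA profiles",
            int(const_t.sum()), int(const_l.sum()),
        )
    tc = t - t.mean(axis=1, keepdims=True)
    lc = l - l.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (tc @ lc.T) / np.outer(
            np.linalg.norm(tc, axis=1), np.linalg.norm(lc, axis=1)
        )
    n = len(common)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
    rmat = pd.DataFrame(r, index=tf_expr.index, columns=lnc_expr.index)
    pmat = pd.DataFrame(p, index=tf_expr.index, columns=lnc_expr.index)
    mask = (rmat.abs() > r_min) & (pmat < p_max)
    mask.loc[tf_expr.index[const_t], :] = False
    mask.loc[:, lnc_expr.index[const_l]] = False
    n_sig = int(mask.values.sum())
    n_pos = int((mask & (rmat > 0)).values.sum())
    return {
        "r": rmat,
        "p": pmat,
        "mask": mask,
        "n_pairs": int(rmat.size),
        "n_significant": n_sig,
        "pct_significant": 100.0 * n_sig / rmat.size if rmat.size else np.nan,
        "pct_positive": 100.0 * n_pos / n_sig if n_sig else np.nan,
        "pct_negative": 100.0 * (n_sig - n_pos) / n_sig if n_sig else np.nan,
    }
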