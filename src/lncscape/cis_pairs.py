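"""DE lncRNA / DE protein-coding neighbor pairs and their co-expression.

A candidate pair is a DE lncRNA whose classified nearest/overlapping
protein-coding partner is itself a DEG; the pair's expression correlation is
evaluated across all retained samples and filtered on |r|, p and genomic
distance (overlap or < 5 kb by default).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def pair_neighbors(
    de_lncs,
    de_pcgs,
    classifications: pd.DataFrame,
    expression: pd.DataFrame,
) -> pd.DataFrame:
    """Candidate cis pairs: DE lncRNAs whose partner PCG is also a DEG.

    ``classifications`` is the classify_catalogue table (lnc_id, class,
    partner_pcg_id, distance_bp); ``expression`` is a genes x samples matrix
    holding both lncRNAs and PCGs.
    """
    de_lncs = set(de_lncs)
    de_pcgs = set(de_pcgs)
    cls = classifications.set_index("lnc_id")
    rows = []
    for lnc in sorted(de_lncs):
        if lnc not in cls.index:
            raise ValueError(f"no classification for DE lncRNA {lnc}")
        rec = cls.loc[lnc]
        partner = rec["partner_pcg_id"]
        if partner is None or (isinstance(partner, float) and np.isnan(partner)):
            logger.info("%s: no partner PCG; omitted", lnc)
            continue
        if partner not in de_pcgs:
            continue
        if lnc not in expression.index or partner not in expression.index:
            logger.info("%s/%s: expression missing; omitted", lnc, partner)
            continue
        x = expression.loc[lnc].values.astype(float)
        y = expression.loc[partner].values.astype(float)
        if x.std() == 0 or y.std() == 0:
            logger.warning("%s/%s: constant profile; omitted", lnc, partner)
            continue
        r, p = stats.pearsonr(x, y)
        rows.append(
            {
                "lnc_id": lnc,
                "pcg_id": partner,
                "class": rec["class"],
                "distance_bp": rec["distance_bp"],
                "orientation": (
                    "same-strand" if rec["class"] in ("IC", "GES", "GIS", "GOS")
                    else "antisense"
                ),
                "r": float(r),
                "p": float(p),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["lnc_id", "pcg_id", "class", "distance_bp", "orientation", "r", "p"],
    )


def filter_cis(
    pairs: pd.DataFrame,
    r_min: float = 0.75,
    p_max: float = 0.01,
    max_distance: int = 5000,
) -> tuple[pd.DataFrame, dict]:
    """Keep pairs with |r| > r_min, p < p_max and overlap or distance <
    ``max_distance`` (strict); return the kept table plus count summaries."""
    if not len(pairs):
        return pairs.copy(), {
            "n_candidates": 0, "n_pass": 0, "n_within_cutoff": 0,
            "n_antisense": 0, "n_positive_r": 0,
        }
    sig = (pairs["r"].abs() > r_min) & (pairs["p"] < p_max)
    sig_pairs = pairs[sig]
    within = sig_pairs["distance_bp"] < max_distance  # distance 0 = overlap
    kept = sig_pairs[within].copy()
    summary = {
        "n_candidates": int(len(pairs)),
        "n_pass": int(len(sig_pairs)),
        "n_within_cutoff": int(len(kept)),
        "pct_within_cutoff": (
            100.0 * len(kept) / len(sig_pairs) if len(sig_pairs) else np.nan
        ),
        "n_antisense": int((kept["orientation"] == "antisense").sum()),
        "n_positive_r": int((kept["r"] > 0).sum()),
        "pct_positive_r": (
            100.0 * float((kept["r"] > 0).sum()) / len(kept) if len(kept) else np.nan
        ),
    }
    return kept, summary
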