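"""Strand-aware positional classification of lncRNAs.

Each lncRNA gene is placed in one of eight classes relative to protein-coding
genes (PCGs):

* genic (gene spans intersect a PCG):
    - exonic   GES / GEAS — >=1 bp exon-exon overlap (same strand / antisense)
    - overlapping GOS / GOAS — an entire PCG lies within one lncRNA intron
    - intronic GIS / GIAS — the lncRNA falls in PCG intronic territory
* intergenic:
    - IC / ID — same strand / opposite strand relative to the nearest PCG

Precedence within genic is exonic > overlapping > intronic; a partial span
overlap with neither exon overlap nor containment falls through to the
intronic subtype. Intergenic lncRNAs inherit their strand label from the
nearest PCG on the chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from lncscape.annotation_io import AnnotationSet, GeneModel, GenomicInterval

logger = logging.getLogger(__name__)

CLASS_LABELS = ("IC", "ID", "GES", "GEAS", "GIS", "GIAS", "GOS", "GOAS")
GENIC_LABELS = ("GES", "GEAS", "GIS", "GIAS", "GOS", "GOAS")

_STRAND_FLIP = {
    "IC": "ID", "ID": "IC", "GES": "GEAS", "GEAS": "GES",
    "GIS": "GIAS", "GIAS": "GIS", "GOS": "GOAS", "GOAS": "GOS",
}


@dataclass(frozen=True)
class LncClassification:
    lnc_id: str
    label: str
    partner_pcg_id: str | None
    distance_bp: int | None


def _overlap_len(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _exonic_overlap(lnc: GeneModel, pcg: GeneModel) -> int:
    total = 0
    for e1 in lnc.exons():
        for e2 in pcg.exons():
            total += _overlap_len(e1, e2)
    return total


def _pcg_inside_lnc_intron(lnc: GeneModel, pcg: GeneModel) -> bool:
    span = pcg.span
    for tx in lnc.transcripts:
        for intron in tx.introns():
            if intron.start <= span.start and span.end <= intron.end:
                return True
    return False


def _tss(g: GeneModel) -> int:
    return g.span.start if g.strand == "+" else g.span.end - 1


def _pick_partner(lnc: GeneModel, candidates: list[GeneModel]) -> GeneModel:
    """Largest exonic overlap, then largest span overlap, then smallest TSS
    distance, then lexicographic gene_id."""
    def key(p: GeneModel):
        return (
            -_exonic_overlap(lnc, p),
            -_overlap_len(lnc.span, p.span),
            abs(_tss(lnc) - _tss(p)),
            p.gene_id,
        )
    return min(candidates, key=key)


def classify_lncrna(lnc: GeneModel, pcgs: AnnotationSet) -> LncClassification:
    """Classify one lncRNA gene against a protein-coding annotation."""
    if lnc.biotype != "lncRNA":
        raise ValueError(f"{lnc.gene_id}: not a lncRNA")
    overlapping = pcgs.overlapping(lnc.span)
    if overlapping:
        partner = _pick_partner(lnc, overlapping)
        same = partner.strand == lnc.strand
        if _exonic_overlap(lnc, partner) > 0:
            label = "GES" if same else "GEAS"
        elif _pcg_inside_lnc_intron(lnc, partner):
            label = "GOS" if same else "GOAS"
        else:
            label = "GIS" if same else "GIAS"
        return LncClassification(lnc.gene_id, label, partner.gene_id, 0)
    nearest = pcgs.nearest(lnc.span)
    if not nearest:
        logger.warning("%s: no protein-coding gene on %s", lnc.gene_id, lnc.chrom)
        return LncClassification(lnc.gene_id, "IC", None, None)
    if len(nearest) > 1:
        # equidistant tie: the PCG upstream of the lncRNA (relative to the
        # lncRNA's strand) wins
        def upstream_first(item):
            g, _ = item
            if lnc.strand == "+":
                is_up = g.span.end <= lnc.span.start
            else:
                is_up = g.span.start >= lnc.span.end
            return (0 if is_up else 1, g.gene_id)
        partner, dist = min(nearest, key=upstream_first)
    else:
        partner, dist = nearest[0]
    label = "IC" if partner.strand == lnc.strand else "ID"
    return LncClassification(lnc.gene_id, label, partner.gene_id, dist)


def nearest_pcg_distance(
    lnc_span: GenomicInterval, pcgs: AnnotationSet
) -> tuple[str, int]:
    """Nearest PCG by span gap; 0 when spans touch or overlap."""
    hits = pcgs.nearest(lnc_span)
    if not hits:
        raise ValueError(f"no protein-coding gene on {lnc_span.chrom}")
    gene, dist = hits[0]
    return gene.gene_id, dist


def classify_catalogue(
    lncs: AnnotationSet, pcgs: AnnotationSet
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every lncRNA gene; return (table, class-count summary).

    The summary reports counts and percentages per class at both gene and
    transcript level (a gene's transcripts all inherit its class).
    """
    if len(lncs) == 0 or len(pcgs) == 0:
        raise ValueError("classification needs non-empty lncRNA and PCG sets")
    rows = []
    for lnc in lncs.genes():
        c = classify_lncrna(lnc, pcgs)
        rows.append(
            {
                "lnc_id": c.lnc_id,
                "class": c.label,
                "partner_pcg_id": c.partner_pcg_id,
                "distance_bp": c.distance_bp,
                "n_transcripts": len(lncs[c.lnc_id].transcripts),
            }
        )
    table = pd.DataFrame(rows)
    summary_rows = []
    n_genes = len(table)
    n_tx = int(table["n_transcripts"].sum())
    for label in CLASS_LABELS:
        sub = table[table["class"] == label]
        g = len(sub)
        t = int(sub["n_transcripts"].sum())
        summary_rows.append(
            {
                "class": label,
                "n_genes": g,
                "pct_genes": 100.0 * g / n_genes,
                "n_transcripts": t,
                "pct_transcripts": 100.0 * t / n_tx,
            }
        )
    return table, pd.DataFrame(summary_rows)


def compare_class_distances(
    ic: "list[float] | np.ndarray",
    id_: "list[float] | np.ndarray",
    cutoff_bp: int = 5000,
) -> dict:
    """Fraction of each intergenic class within ``cutoff_bp`` of a PCG, with a
    Welch two-sample t-test on the distance distributions."""
    ic = np.asarray(ic, dtype=float)
    id_ = np.asarray(id_, dtype=float)
    if ic.size == 0 or id_.size == 0:
        raise ValueError("distance lists must be non-empty")
    t, p = stats.ttest_ind(ic, id_, equal_var=False)
    return {
        "frac_within_cutoff": {
            "IC": float(np.sum(ic < cutoff_bp) / ic.size),
            "ID": float(np.sum(id_ < cutoff_bp) / id_.size),
        },
        "median": {"IC": float(np.median(ic)), "ID": float(np.median(id_))},
        "t_statistic": float(t),
        "p_value": float(p),
        "cutoff_bp": cutoff_bp,
    }


def structural_summary(lncs: AnnotationSet, pcgs: AnnotationSet) -> dict:
    """Per-biotype exon-count histogram and spliced-length comparison."""
    if len(lncs) == 0 or len(pcgs) == 0:
        raise ValueError("structural summary needs non-empty inputs")

    def describe(annot: AnnotationSet) -> dict:
        exon_counts = np.array([len(t.exons) for t in annot.transcripts()])
        lengths = np.array([t.spliced_length for t in annot.transcripts()])
        hist: dict[int, int] = {}
        for c in exon_counts:
            hist[int(c)] = hist.get(int(c), 0) + 1
        return {
            "exon_count_hist": hist,
            "two_exon_fraction": float(np.mean(exon_counts == 2)),
            "median_length": float(np.median(lengths)),
            "lengths": lengths,
        }

    lnc_d, pcg_d = describe(lncs), describe(pcgs)
    t, p = stats.ttest_ind(lnc_d["lengths"], pcg_d["lengths"], equal_var=False)
    return {
        "lncRNA": {k: v for k, v in lnc_d.items() if k != "lengths"},
        "protein_coding": {k: v for k, v in pcg_d.items() if k != "lengths"},
        "length_t_statistic": float(t),
        "length_p_value": float(p),
    }


def strand_flipped_label(label: str) -> str:
    """Label after flipping the lncRNA's strand (genic/intergenic unchanged)."""
    return _STRAND_FLIP[label]
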