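import numpy as np
import pytest

from lncscape.annotation_io import (
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
)


def make_gene(
    gene_id,
    chrom,
    exon_coords,
    strand="+",
    biotype="lncRNA",
    source="sourceA",
):
    """One-transcript gene from a list of (start, end) exon tuples."""
    exons = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exon_coords)
    tx = TranscriptModel(f"{gene_id}.t1", gene_id, exons, biotype, source)
    return GeneModel(gene_id, (tx,))


def random_layout(rng, chrom_len=30_000):
    """Random lncRNA + PCG layout on one chromosome for oracle checks.

    Returns (lnc GeneModel, pcgs AnnotationSet); geometry is unconstrained,
    so any of the eight positional relations (or awkward partial overlaps)
    can arise.
    """
    def random_exons(start, strand, max_exons, max_exon, max_intron):
        n = int(rng.integers(1, max_exons + 1))
        exons = []
        pos = start
        for _ in range(n):
            length = int(rng.integers(50, max_exon))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(50, max_intron))
        return exons

    n_pcg = int(rng.integers(1, 4))
    pcgs = AnnotationSet()
    for i in range(n_pcg):
        start = int(rng.integers(0, chrom_len - 8000))
        strand = "+" if rng.random() < 0.5 else "-"
        pcgs.add(
            make_gene(
                f"P{i}", "chrZ",
                random_exons(start, strand, 4, 500, 2500),
                strand, "protein_coding",
            )
        )
    start = int(rng.integers(0, chrom_len - 8000))
    strand = "+" if rng.random() < 0.5 else "-"
    lnc = make_gene(
        "L0", "chrZ", random_exons(start, strand, 3, 400, 3000), strand, "lncRNA"
    )
    return lnc, pcgs


def brute_force_classify(lnc, pcgs):
    """Base-level enumeration classifier used as an independent oracle.

    Works entirely on explicit base-position sets: span intersection for
    genic membership, exon-base intersection for the exonic subtype,
    containment of the whole PCG span in an enumerated intron for the
    overlapping subtype; intergenic labels come from an O(n^2) scan over all
    PCG spans for the minimum boundary gap.
    """
    def span_bases(g):
        return set(range(g.span.start, g.span.end))

    def exon_bases(g):
        out = set()
        for e in g.exons():
            out.update(range(e.start, e.end))
        return out

    lnc_span = span_bases(lnc)
    overlapping = [p for p in pcgs.genes() if lnc_span & span_bases(p)]
    if overlapping:
        lnc_exons = exon_bases(lnc)

        def tss(g):
            return g.span.start if g.strand == "+" else g.span.end - 1

        def partner_key(p):
            return (
                -len(lnc_exons & exon_bases(p)),
                -len(lnc_span & span_bases(p)),
                abs(tss(lnc) - tss(p)),
                p.gene_id,
            )

        partner = min(overlapping, key=partner_key)
        same = partner.strand == lnc.strand
        if lnc_exons & exon_bases(partner):
            return "GES" if same else "GEAS"
        contained = False
        for tx in lnc.transcripts:
            for intron in tx.introns():
                if span_bases(partner) <= set(range(intron.start, intron.end)):
                    contained = True
        if contained:
            return "GOS" if same else "GOAS"
        return "GIS" if same else "GIAS"
    # intergenic: O(n^2) nearest scan
    best_d, best = None, []
    for p in pcgs.genes():
        d = max(lnc.span.start - p.span.end, p.span.start - lnc.span.end, 0)
        if best_d is None or d < best_d:
            best_d, best = d, [p]
        elif d == best_d:
            best.append(p)
    if not best:
        return "IC"
    if len(best) > 1:
        def upstream_first(g):
            if lnc.strand == "+":
                is_up = g.span.end <= lnc.span.start
            else:
                is_up = g.span.start >= lnc.span.end
            return (0 if is_up else 1, g.gene_id)
        partner = min(best, key=upstream_first)
    else:
        partner = best[0]
    return "IC" if partner.strand == lnc.strand else "ID"


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
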