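"""Annotation I/O and lncRNA catalogue construction.

Gene models are held as a three-level hierarchy (gene -> transcript -> exon)
with 0-based half-open coordinates internally; GTF/GFF3 emit and consume the
usual 1-based inclusive convention. An interval index per chromosome supports
the overlap and nearest-neighbor queries the positional classifier needs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

BIOTYPE_ALIASES = {
    "lincRNA": "lncRNA",
    "lincrna": "lncRNA",
    "lnc_RNA": "lncRNA",
    "lncrna": "lncRNA",
}


class AnnotationParseError(ValueError):
    """Raised when an annotation file cannot be parsed; names the line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """Distance between closest boundaries; 0 when touching or overlapping."""
        if self.chrom != other.chrom:
            raise ValueError("intervals on different chromosomes")
        return max(self.start - other.end, other.start - self.end, 0)


@dataclass(frozen=True)
class TranscriptModel:
    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    biotype: str
    # provenance label (catalogue of origin); not part of model identity
    source: str = dc_field(default="sourceA", compare=False)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >=1 exon")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"{self.transcript_id}: exons must share chrom and strand"
            )
        exons = sorted(self.exons, key=lambda e: e.start)
        for prev, nxt in zip(exons, exons[1:]):
            if nxt.start < prev.end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        object.__setattr__(self, "exons", tuple(exons))

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def tss(self) -> int:
        """Strand-aware 5' end (0-based position of the first transcribed base)."""
        return self.exons[0].start if self.strand == "+" else self.exons[-1].end - 1

    def introns(self) -> list[GenomicInterval]:
        out = []
        for prev, nxt in zip(self.exons, self.exons[1:]):
            if nxt.start > prev.end:
                out.append(
                    GenomicInterval(self.chrom, prev.end, nxt.start, self.strand)
                )
        return out


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    transcripts: tuple[TranscriptModel, ...]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"{self.gene_id}: gene needs >=1 transcript")
        biotypes = {t.biotype for t in self.transcripts}
        if len(biotypes) > 1:
            raise ValueError(f"{self.gene_id}: mixed biotypes {biotypes}")
        chroms = {t.chrom for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(f"{self.gene_id}: transcripts on mixed chrom/strand")
        object.__setattr__(
            self,
            "transcripts",
            tuple(sorted(self.transcripts, key=lambda t: (t.span.start, t.transcript_id))),
        )

    @property
    def biotype(self) -> str:
        return self.transcripts[0].biotype

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            min(t.span.start for t in self.transcripts),
            max(t.span.end for t in self.transcripts),
            self.strand,
        )

    def exons(self) -> list[GenomicInterval]:
        return [e for t in self.transcripts for e in t.exons]

    def canonical_transcript(self) -> TranscriptModel:
        """Longest spliced transcript (ties broken by id)."""
        return max(self.transcripts, key=lambda t: (t.spliced_length, t.transcript_id))


class AnnotationSet:
    """Collection of gene models with a per-chromosome interval index."""

    def __init__(self, genes: list[GeneModel] | tuple[GeneModel, ...] = ()):
        self._genes: dict[str, GeneModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        self._sorted: dict[str, list[GeneModel]] | None = None
        self.metadata: dict = {}
        for g in genes:
            self.add(g)

    def add(self, gene: GeneModel) -> None:
        if gene.gene_id in self._genes:
            raise ValueError(f"duplicate gene_id {gene.gene_id}")
        self._genes[gene.gene_id] = gene
        span = gene.span
        self._trees.setdefault(gene.chrom, IntervalTree()).addi(
            span.start, span.end, gene.gene_id
        )
        self._sorted = None

    def __len__(self) -> int:
        return len(self._genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._genes[gene_id]

    def __iter__(self):
        return iter(self.genes())

    def __eq__(self, other) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return {g.gene_id: g for g in self.genes()} == {
            g.gene_id: g for g in other.genes()
        }

    def genes(self) -> list[GeneModel]:
        return sorted(
            self._genes.values(), key=lambda g: (g.chrom, g.span.start, g.gene_id)
        )

    def transcripts(self) -> list[TranscriptModel]:
        return [t for g in self.genes() for t in g.transcripts]

    def chromosomes(self) -> list[str]:
        return sorted(self._trees)

    def genes_on(self, chrom: str) -> list[GeneModel]:
        if self._sorted is None:
            by_chrom: dict[str, list[GeneModel]] = {}
            for g in self._genes.values():
                by_chrom.setdefault(g.chrom, []).append(g)
            for lst in by_chrom.values():
                lst.sort(key=lambda g: (g.span.start, g.gene_id))
            self._sorted = by_chrom
        return self._sorted.get(chrom, [])

    def overlapping(self, interval: GenomicInterval) -> list[GeneModel]:
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        hits = tree.overlap(interval.start, interval.end)
        return sorted(
            (self._genes[h.data] for h in hits),
            key=lambda g: (g.span.start, g.gene_id),
        )

    def nearest(self, interval: GenomicInterval) -> list[tuple[GeneModel, int]]:
        """All genes on the chromosome at minimum gap from the interval.

        Gap is 0 for any overlap or abutment. Returns [] when the chromosome
        holds no genes.
        """
        genes = self.genes_on(interval.chrom)
        if not genes:
            return []
        overlaps = self.overlapping(interval)
        if overlaps:
            return [(g, 0) for g in overlaps]
        best: list[tuple[GeneModel, int]] = []
        best_d: int | None = None
        for g in genes:
            d = interval.gap_to(g.span)
            if best_d is None or d < best_d:
                best_d, best = d, [(g, d)]
            elif d == best_d:
                best.append((g, d))
        best.sort(key=lambda t: t[0].gene_id)
        return best

    def subset(self, gene_ids) -> "AnnotationSet":
        wanted = set(gene_ids)
        return AnnotationSet([g for g in self.genes() if g.gene_id in wanted])


# ---------------------------------------------------------------------------
# Parsing


def _norm_biotype(raw: str | None, default: str = "lncRNA") -> str:
    if raw is None:
        return default
    return BIOTYPE_ALIASES.get(raw, raw)


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if " " in part:
            key, _, val = part.partition(" ")
            out[key] = val.strip().strip('"')
    return out


def _parse_gff3_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().split(";"):
        if "=" in part:
            key, _, val = part.partition("=")
            out[key.strip()] = val.strip()
    return out


def _read_gxf(path: str, fmt: str, source: str | None) -> AnnotationSet:
    parse_attrs = _parse_gtf_attributes if fmt == "GTF" else _parse_gff3_attributes
    exons: dict[str, list[GenomicInterval]] = {}
    tx_meta: dict[str, dict] = {}
    rejected_mixed = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise AnnotationParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, src, ftype, start_s, end_s, _score, strand, _frame, attr = fields[:9]
            if ftype != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise AnnotationParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if strand not in ("+", "-"):
                raise AnnotationParseError(f"{path}:{lineno}: bad strand {strand!r}")
            attrs = parse_attrs(attr)
            tid = attrs.get("transcript_id") or attrs.get("Parent")
            gid = attrs.get("gene_id") or attrs.get("gene") or tid
            if tid is None:
                raise AnnotationParseError(
                    f"{path}:{lineno}: exon without transcript_id/Parent"
                )
            biotype = _norm_biotype(
                attrs.get("gene_biotype")
                or attrs.get("gene_type")
                or attrs.get("transcript_biotype")
                or attrs.get("biotype")
            )
            # GTF/GFF3 are 1-based inclusive
            iv = GenomicInterval(chrom, start1 - 1, end1, strand)
            exons.setdefault(tid, []).append(iv)
            tx_meta.setdefault(
                tid,
                {"gene_id": gid, "biotype": biotype, "source": source or src},
            )
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tid, ivs in exons.items():
        meta = tx_meta[tid]
        try:
            tx = TranscriptModel(
                tid, meta["gene_id"], tuple(ivs), meta["biotype"], meta["source"]
            )
        except ValueError as exc:
            rejected_mixed += 1
            logger.warning("rejected transcript %s: %s", tid, exc)
            continue
        by_gene.setdefault(meta["gene_id"], []).append(tx)
    if rejected_mixed:
        logger.warning("%d transcripts rejected during parse", rejected_mixed)
    annot = AnnotationSet()
    for gid, txs in by_gene.items():
        annot.add(GeneModel(gid, tuple(txs)))
    annot.metadata["rejected_transcripts"] = rejected_mixed
    return annot


def _read_bed12(path: str, source: str | None, default_biotype: str) -> AnnotationSet:
    cols = [
        "chrom", "start", "end", "name", "score", "strand",
        "thickStart", "thickEnd", "itemRgb", "blockCount",
        "blockSizes", "blockStarts",
    ]
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
    except Exception as exc:
        raise AnnotationParseError(f"{path}: cannot parse BED12: {exc}") from exc
    by_gene: dict[str, list[TranscriptModel]] = {}
    for lineno, row in enumerate(df.itertuples(index=False), start=1):
        if pd.isna(row.blockSizes):
            raise AnnotationParseError(f"{path}:{lineno}: missing block columns")
        sizes = [int(x) for x in str(row.blockSizes).rstrip(",").split(",")]
        offsets = [int(x) for x in str(row.blockStarts).rstrip(",").split(",")]
        if len(sizes) != int(row.blockCount) or len(offsets) != int(row.blockCount):
            raise AnnotationParseError(
                f"{path}:{lineno}: blockCount does not match block lists"
            )
        ivs = tuple(
            GenomicInterval(
                str(row.chrom),
                int(row.start) + off,
                int(row.start) + off + size,
                str(row.strand),
            )
            for off, size in zip(offsets, sizes)
        )
        name = str(row.name)
        if "|" in name:
            gid, tid, biotype = (name.split("|") + [default_biotype])[:3]
        else:
            gid = tid = name
            biotype = default_biotype
        tx = TranscriptModel(tid, gid, ivs, biotype, source or "BED")
        by_gene.setdefault(gid, []).append(tx)
    annot = AnnotationSet()
    for gid, txs in by_gene.items():
        annot.add(GeneModel(gid, tuple(txs)))
    return annot


def read_annotation(
    path: str,
    format: str = "GTF",
    source: str | None = None,
    default_biotype: str = "lncRNA",
) -> AnnotationSet:
    """Read a GTF/GFF3/BED12 annotation into an :class:`AnnotationSet`.

    1-based inclusive source coordinates (GTF/GFF3) are converted to 0-based
    half-open; BED12 is already 0-based. ``source`` overrides the per-record
    source label (used for catalogue-merging precedence).
    """
    fmt = format.upper()
    if fmt in ("GTF", "GFF3"):
        return _read_gxf(path, fmt, source)
    if fmt == "BED12":
        return _read_bed12(path, source, default_biotype)
    raise ValueError(f"unknown annotation format {format!r}")


# ---------------------------------------------------------------------------
# Writing


def _bed12_line(tx: TranscriptModel) -> str:
    span = tx.span
    sizes = ",".join(str(len(e)) for e in tx.exons) + ","
    offsets = ",".join(str(e.start - span.start) for e in tx.exons) + ","
    name = f"{tx.gene_id}|{tx.transcript_id}|{tx.biotype}"
    return "\t".join(
        [
            tx.chrom, str(span.start), str(span.end), name, "0", tx.strand,
            str(span.start), str(span.end), "0", str(len(tx.exons)),
            sizes, offsets,
        ]
    )


def _gtf_lines(gene: GeneModel) -> list[str]:
    lines = []
    span = gene.span
    attrs = f'gene_id "{gene.gene_id}"; gene_biotype "{gene.biotype}";'
    src = gene.transcripts[0].source
    lines.append(
        "\t".join(
            [gene.chrom, src, "gene", str(span.start + 1), str(span.end),
             ".", gene.strand, ".", attrs]
        )
    )
    for tx in gene.transcripts:
        tspan = tx.span
        tattrs = (
            f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}"; '
            f'gene_biotype "{gene.biotype}";'
        )
        lines.append(
            "\t".join(
                [tx.chrom, tx.source, "transcript", str(tspan.start + 1),
                 str(tspan.end), ".", tx.strand, ".", tattrs]
            )
        )
        for e in tx.exons:
            lines.append(
                "\t".join(
                    [tx.chrom, tx.source, "exon", str(e.start + 1), str(e.end),
                     ".", tx.strand, ".", tattrs]
                )
            )
    return lines


def write_catalogue(annot: AnnotationSet, path: str, format: str = "BED12") -> None:
    """Write the catalogue sorted by (chrom, start, id); output is bit-stable."""
    fmt = format.upper()
    if fmt == "BED12":
        txs = sorted(
            annot.transcripts(),
            key=lambda t: (t.chrom, t.span.start, t.transcript_id),
        )
        body = "\n".join(_bed12_line(t) for t in txs)
    elif fmt == "GTF":
        body = "\n".join(line for g in annot.genes() for line in _gtf_lines(g))
    else:
        raise ValueError(f"unknown output format {format!r}")
    with open(path, "w") as fh:
        if body:
            fh.write(body + "\n")


# ---------------------------------------------------------------------------
# Catalogue merging


def _exonic_overlap_same_strand(tx: TranscriptModel, others: AnnotationSet) -> bool:
    for gene in others.overlapping(tx.span):
        for other_tx in gene.transcripts:
            if other_tx.strand != tx.strand:
                continue
            for e1 in tx.exons:
                for e2 in other_tx.exons:
                    if e1.start < e2.end and e2.start < e1.end:
                        return True
    return False


def merge_lncrna_catalogues(
    a: AnnotationSet, b: AnnotationSet, min_length: int = 200
) -> AnnotationSet:
    """Merge two lncRNA catalogues with source-A precedence.

    Transcripts with spliced length < ``min_length`` are removed from both
    sources. A transcript from ``b`` sharing >=1 bp of same-strand exonic
    overlap with any retained ``a`` transcript is treated as redundant and
    dropped. Per-source retained counts land in ``result.metadata``.
    """
    if len(a) == 0 and len(b) == 0:
        logger.warning("merging two empty catalogues")

    def length_filter(annot: AnnotationSet) -> list[TranscriptModel]:
        return [t for t in annot.transcripts() if t.spliced_length >= min_length]

    kept_a = length_filter(a)
    retained = AnnotationSet()
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in kept_a:
        by_gene.setdefault(tx.gene_id, []).append(tx)
    for gid, txs in by_gene.items():
        retained.add(GeneModel(gid, tuple(txs)))

    kept_b: dict[str, list[TranscriptModel]] = {}
    n_b = 0
    for tx in length_filter(b):
        if _exonic_overlap_same_strand(tx, retained):
            continue
        kept_b.setdefault(tx.gene_id, []).append(tx)
        n_b += 1
    merged = AnnotationSet()
    for gid, txs in by_gene.items():
        merged.add(GeneModel(gid, tuple(txs)))
    for gid, txs in kept_b.items():
        if gid in merged:
            existing = merged[gid]
            raise ValueError(
                f"gene_id {gid} present in both catalogues "
                f"({existing.chrom}); disambiguate ids before merging"
            )
        merged.add(GeneModel(gid, tuple(txs)))
    merged.metadata["retained_counts"] = {
        "a": len(kept_a),
        "b": n_b,
        "total": len(kept_a) + n_b,
    }
    return merged
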