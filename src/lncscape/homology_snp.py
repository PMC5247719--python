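"""Chain-based coordinate lift-over and disease-SNP intersection.

A UCSC chain file describes blockwise alignments between a source and a
target assembly. Intervals are mapped base-by-base through the aligned
blocks of the best-scoring overlapping chain; an interval whose mapped-base
fraction falls below ``min_match``, or that overlaps several chains, is
reported unmapped with a reason. Mapped regions are then intersected with a
table of disease-associated SNPs (GWAS/ClinVar-style columns).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from lncscape.annotation_io import GenomicInterval

logger = logging.getLogger(__name__)


@dataclass
class ChainBlock:
    size: int
    dt: int  # gap on the source (reference) side after the block
    dq: int  # gap on the target (query) side after the block


@dataclass
class Chain:
    score: float
    t_name: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    chain_id: str
    blocks: list[ChainBlock] = field(default_factory=list)

    def validate(self) -> None:
        t_span = sum(b.size + b.dt for b in self.blocks)
        q_span = sum(b.size + b.dq for b in self.blocks)
        if t_span != self.t_end - self.t_start or q_span != self.q_end - self.q_start:
            raise ValueError(
                f"chain {self.chain_id}: block arithmetic does not match "
                f"header spans"
            )


@dataclass
class ChainMap:
    chains: list[Chain]

    def overlapping(self, interval: GenomicInterval) -> list[Chain]:
        return [
            c
            for c in self.chains
            if c.t_name == interval.chrom
            and c.t_start < interval.end
            and interval.start < c.t_end
        ]


@dataclass
class LiftResult:
    mapped: GenomicInterval | None
    fraction: float
    reason: str | None  # None on success; "no_chain", "split", "low_match"


def read_chain(path: str) -> ChainMap:
    """Parse a UCSC chain file; block arithmetic is validated per chain."""
    chains: list[Chain] = []
    current: Chain | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                parts = line.split()
                if len(parts) != 13:
                    raise ValueError(f"{path}:{lineno}: malformed chain header")
                current = Chain(
                    score=float(parts[1]),
                    t_name=parts[2], t_size=int(parts[3]), t_strand=parts[4],
                    t_start=int(parts[5]), t_end=int(parts[6]),
                    q_name=parts[7], q_size=int(parts[8]), q_strand=parts[9],
                    q_start=int(parts[10]), q_end=int(parts[11]),
                    chain_id=parts[12],
                )
                chains.append(current)
                continue
            if current is None:
                raise ValueError(f"{path}:{lineno}: data before chain header")
            parts = line.split()
            if len(parts) == 3:
                current.blocks.append(
                    ChainBlock(int(parts[0]), int(parts[1]), int(parts[2]))
                )
            elif len(parts) == 1:
                current.blocks.append(ChainBlock(int(parts[0]), 0, 0))
                current = None
            else:
                raise ValueError(f"{path}:{lineno}: malformed alignment line")
    for c in chains:
        c.validate()
    return ChainMap(chains)


def write_chain(chains: ChainMap, path: str) -> None:
    with open(path, "w") as fh:
        for c in chains.chains:
            fh.write(
                f"chain {c.score:g} {c.t_name} {c.t_size} {c.t_strand} "
                f"{c.t_start} {c.t_end} {c.q_name} {c.q_size} {c.q_strand} "
                f"{c.q_start} {c.q_end} {c.chain_id}\n"
            )
            for b in c.blocks[:-1]:
                fh.write(f"{b.size} {b.dt} {b.dq}\n")
            fh.write(f"{c.blocks[-1].size}\n\n")


def _map_through_chain(interval: GenomicInterval, chain: Chain):
    """Positions of the interval's bases on the target, via aligned blocks."""
    mapped_q: list[int] = []
    t = chain.t_start
    q = chain.q_start
    for block in chain.blocks:
        lo = max(t, interval.start)
        hi = min(t + block.size, interval.end)
        if lo < hi:
            mapped_q.extend(range(q + (lo - t), q + (hi - t)))
        t += block.size + block.dt
        q += block.size + block.dq
    return mapped_q


def liftover(
    interval: GenomicInterval, chains: ChainMap, min_match: float = 0.1
) -> LiftResult:
    """Map an interval to the target assembly through the chain map.

    The best-scoring chain overlapping the interval is used; when several
    chains overlap it, the mapping is conservatively refused ("split"). The
    result spans the mapped bases on the target; negative-strand chains are
    reflected into plus-strand target coordinates.
    """
    if not (0 < min_match <= 1):
        raise ValueError("min_match must be in (0, 1]")
    hits = chains.overlapping(interval)
    if not hits:
        return LiftResult(None, 0.0, "no_chain")
    chain = max(hits, key=lambda c: c.score)
    if len(hits) > 1 and not (
        chain.t_start <= interval.start and interval.end <= chain.t_end
    ):
        # query straddles chains: conservative refusal
        return LiftResult(None, 0.0, "split")
    mapped_q = _map_through_chain(interval, chain)
    frac = len(mapped_q) / len(interval)
    if frac < min_match or not mapped_q:
        return LiftResult(None, frac, "low_match")
    lo, hi = min(mapped_q), max(mapped_q) + 1
    if chain.q_strand == "-":
        lo, hi = chain.q_size - hi, chain.q_size - lo
    return LiftResult(
        GenomicInterval(chain.q_name, lo, hi, interval.strand), frac, None
    )


def liftover_regions(
    regions: dict[str, GenomicInterval],
    chains: ChainMap,
    min_match: float = 0.1,
) -> pd.DataFrame:
    rows = []
    for rid in sorted(regions):
        res = liftover(regions[rid], chains, min_match)
        rows.append(
            {
                "id": rid,
                "mapped": res.mapped is not None,
                "chrom": res.mapped.chrom if res.mapped else None,
                "start": res.mapped.start if res.mapped else None,
                "end": res.mapped.end if res.mapped else None,
                "fraction": res.fraction,
                "reason": res.reason,
            }
        )
    return pd.DataFrame(rows)


def read_snp_table(path: str) -> pd.DataFrame:
    """Read a GWAS-Catalog-style SNP table (CHR_ID, CHR_POS 1-based, SNPS,
    DISEASE/TRAIT, MAPPED_GENE, PUBMEDID[, SOURCE])."""
    df = pd.read_csv(path, sep="\t", dtype={"CHR_ID": str})
    required = {"CHR_ID", "CHR_POS", "SNPS", "DISEASE/TRAIT"}
    if not required <= set(df.columns):
        raise ValueError(f"SNP table needs columns {sorted(required)}")
    if (df["CHR_POS"] < 1).any():
        raise ValueError("CHR_POS must be 1-based (>= 1)")
    return df


def normalize_chrom(name: str) -> str:
    """Strip a 'chr' prefix so both naming conventions intersect."""
    return name[3:] if name.startswith("chr") else name


def intersect_snps(
    mapped: dict[str, GenomicInterval], snps: pd.DataFrame
) -> pd.DataFrame:
    """One row per (lncRNA, SNP) with the SNP inside the mapped interval.

    SNP positions are 1-based; a SNP at 1-based position P lies at 0-based
    point P-1 and is inside [start, end) when start <= P-1 < end (so a SNP at
    the interval start is included).
    """
    rows = []
    for lnc_id in sorted(mapped):
        iv = mapped[lnc_id]
        chrom = normalize_chrom(iv.chrom)
        for _, rec in snps.iterrows():
            if normalize_chrom(str(rec["CHR_ID"])) != chrom:
                continue
            pos0 = int(rec["CHR_POS"]) - 1
            if iv.start <= pos0 < iv.end:
                rows.append(
                    {
                        "lnc_id": lnc_id,
                        "target_region": f"{iv.chrom}:{iv.start}-{iv.end}",
                        "rsid": rec["SNPS"],
                        "trait": rec["DISEASE/TRAIT"],
                        "mapped_gene": rec.get("MAPPED_GENE", ""),
                        "pubmed_id": rec.get("PUBMEDID", ""),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["lnc_id", "target_region", "rsid", "trait", "mapped_gene", "pubmed_id"],
    )
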