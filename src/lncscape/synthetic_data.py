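"""Seeded synthetic-data generators with machine-readable planted truth.

Every generator is a pure function of (params, seed) and emulates one input
the pipeline consumes: a two-biotype genome annotation with known positional
classes, negative-binomial counts for a 4-group design (control, 1M, 3M, 6M;
n=3 each) with planted DE genes and temporal archetypes, co-expression
plantings (cis pairs, lncRNA-gene-set associations, TF-lncRNA pairs),
promoter sequences with planted motif occurrences, and a toy chain file plus
disease-SNP table. Planted truth is returned alongside the data so recovery
tests are well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lncscape.annotation_io import (
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
)
from lncscape.expression_qc import ExpressionMatrix
from lncscape.homology_snp import Chain, ChainBlock, ChainMap
from lncscape.lnc_classify import CLASS_LABELS
from lncscape.motif_regulation import BASES, PWM

GROUPS = ("control", "1M", "3M", "6M")

# temporal fold-change archetypes over (control, 1M, 3M, 6M); the five
# patterns mirror the cluster shapes a chronic-injury time course shows:
# gradual down, late up, gradual up, early transient up, early sustained up
ARCHETYPES = {
    1: (1.0, 0.6, 0.35, 0.2),
    2: (1.0, 1.1, 3.0, 5.0),
    3: (1.0, 2.0, 3.5, 5.0),
    4: (1.0, 5.0, 2.0, 1.0),
    5: (1.0, 5.0, 3.0, 3.0),
}


@dataclass
class SyntheticTruth:
    """Ground truth for every planted feature, keyed by generator."""

    lnc_classes: dict[str, str] = field(default_factory=dict)
    de_genes: pd.DataFrame | None = None
    cis_pairs: list[tuple[str, str]] = field(default_factory=list)
    lnc_set_associations: list[tuple[str, str]] = field(default_factory=list)
    tf_lnc_pairs: list[tuple[str, str]] = field(default_factory=list)
    expected_r: float | None = None
    motif_occurrences: pd.DataFrame | None = None
    snp_labels: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# Annotation with planted positional classes


def _make_pcg(
    gene_id: str, chrom: str, start: int, strand: str, rng,
    n_exons: int = 3, exon_len: int = 300, intron_len: int = 2000,
) -> GeneModel:
    exons = []
    pos = start
    for _ in range(n_exons):
        exons.append(GenomicInterval(chrom, pos, pos + exon_len, strand))
        pos += exon_len + intron_len
    tx = TranscriptModel(f"{gene_id}.t1", gene_id, tuple(exons), "protein_coding")
    return GeneModel(gene_id, (tx,))


def _lnc_exons_for_class(
    label: str, pcg: GeneModel, rng, two_exon: bool
) -> tuple[list[GenomicInterval], str]:
    """Geometric construction guaranteeing the requested class and no
    higher-precedence one."""
    chrom = pcg.chrom
    p_strand = pcg.strand
    span = pcg.span
    same = label in ("IC", "GES", "GIS", "GOS")
    strand = p_strand if same else ("-" if p_strand == "+" else "+")
    if label in ("IC", "ID"):
        gap = int(rng.integers(50, 9000))
        length = int(rng.integers(300, 1200))
        if rng.random() < 0.5 and span.start - gap - length > 0:
            start = span.start - gap - length
        else:
            start = span.end + gap
        if two_exon:
            # total span stays exactly `length` so the planted gap holds
            intron = min(200, length // 3)
            half = (length - intron) // 2
            exons = [
                GenomicInterval(chrom, start, start + half, strand),
                GenomicInterval(chrom, start + length - half, start + length, strand),
            ]
        else:
            exons = [GenomicInterval(chrom, start, start + length, strand)]
    elif label in ("GES", "GEAS"):
        # first lnc exon overlaps the PCG's first exon by >=1 bp
        anchor = pcg.transcripts[0].exons[0]
        ov = int(rng.integers(20, len(anchor)))
        start = anchor.start - 150
        exons = [GenomicInterval(chrom, start, anchor.start + ov, strand)]
        if two_exon:
            exons.append(
                GenomicInterval(chrom, start - 900, start - 500, strand)
            )
    elif label in ("GIS", "GIAS"):
        # lncRNA entirely inside the PCG's first intron, no exon overlap
        intron = pcg.transcripts[0].introns()[0]
        pad = 100
        length = min(int(rng.integers(300, 900)), len(intron) - 2 * pad)
        start = intron.start + pad
        if two_exon:
            half = length // 2
            exons = [
                GenomicInterval(chrom, start, start + half, strand),
                GenomicInterval(chrom, start + half + 50, start + length + 50, strand),
            ]
        else:
            exons = [GenomicInterval(chrom, start, start + length, strand)]
    elif label in ("GOS", "GOAS"):
        # whole PCG inside the lncRNA's single intron
        exons = [
            GenomicInterval(chrom, span.start - 1500, span.start - 1100, strand),
            GenomicInterval(chrom, span.end + 1100, span.end + 1500, strand),
        ]
    else:
        raise ValueError(f"unknown class {label}")
    return sorted(exons, key=lambda e: e.start), strand


def simulate_annotation(
    n_per_class: dict[str, int] | int = 10,
    seed: int = 0,
    two_exon_fraction: float = 0.4,
    cassette_spacing: int = 60_000,
) -> tuple[AnnotationSet, AnnotationSet, SyntheticTruth]:
    """Paired lncRNA / protein-coding annotation with known classes.

    Each planted lncRNA sits in an isolated cassette with one partner PCG so
    the constructed relation is also the nearest one. ``n_per_class`` may be
    a single integer applied to all eight classes.
    """
    if isinstance(n_per_class, int):
        n_per_class = {label: n_per_class for label in CLASS_LABELS}
    bad = set(n_per_class) - set(CLASS_LABELS)
    if bad:
        raise ValueError(f"unknown classes {sorted(bad)}")
    rng = np.random.default_rng(seed)
    lncs = AnnotationSet()
    pcgs = AnnotationSet()
    truth = SyntheticTruth()
    cursor = {"chr1": 10_000, "chr2": 10_000}
    i = 0
    for label in CLASS_LABELS:
        for _ in range(n_per_class.get(label, 0)):
            chrom = "chr1" if i % 2 == 0 else "chr2"
            start = cursor[chrom]
            p_strand = "+" if rng.random() < 0.5 else "-"
            pcg = _make_pcg(f"PCG{i:04d}", chrom, start + 20_000, p_strand, rng)
            two_exon = rng.random() < two_exon_fraction
            exons, strand = _lnc_exons_for_class(label, pcg, rng, two_exon)
            lnc_id = f"LNC{i:04d}"
            tx = TranscriptModel(
                f"{lnc_id}.t1", lnc_id, tuple(exons), "lncRNA", "sourceA"
            )
            lncs.add(GeneModel(lnc_id, (tx,)))
            pcgs.add(pcg)
            truth.lnc_classes[lnc_id] = label
            cursor[chrom] = start + cassette_spacing
            i += 1
    return lncs, pcgs, truth


# ---------------------------------------------------------------------------
# Counts


def simulate_counts(
    n_genes: int = 1000,
    n_lnc: int = 100,
    de_fraction: float = 0.1,
    fc: float = 4.0,
    dispersion: float = 0.1,
    mean_log2_expr: float = 6.0,
    log2_expr_sd: float = 1.5,
    temporal_profiles: bool = True,
    coexpressed_pairs: list[tuple[str, str]] = (),
    library_size_spread: tuple[float, float] = (0.7, 1.4),
    seed: int = 0,
    n_replicates: int = 3,
    gene_ids: list[str] | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SyntheticTruth]:
    """Negative-binomial counts + FPKM for the 4-group, n=3 design.

    A ``de_fraction`` of genes is planted as differentially expressed. With
    ``temporal_profiles`` each DE gene follows one of the five temporal
    archetypes scaled so the peak (or trough) fold-change is ``fc``; without,
    DE genes shift by ``fc`` (up or down, random sign) uniformly across the
    three injury groups — the flat condition used for recovery checks.
    Counts follow NB(mean = s_j q_i f_ig, variance = mu + alpha mu^2) via the
    gamma-Poisson mixture; dispersion 0 gives Poisson. FPKM is derived from
    the counts with planted transcript lengths. The last ``n_lnc`` genes are
    labelled lncRNA, the rest protein-coding.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"PCG{i:04d}" for i in range(n_genes - n_lnc)] + [
            f"LNC{i:04d}" for i in range(n_lnc)
        ]
    if len(gene_ids) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    samples = [f"{g}_{r+1}" for g in GROUPS for r in range(n_replicates)]
    groups = pd.Series(
        [g for g in GROUPS for _ in range(n_replicates)], index=samples
    )
    batches = pd.Series(
        [1 + (i % 2) for i in range(len(samples))], index=samples
    )
    q = 2.0 ** rng.normal(mean_log2_expr, log2_expr_sd, size=n_genes)
    s = rng.uniform(*library_size_spread, size=len(samples))
    lengths = rng.integers(500, 3000, size=n_genes)

    n_de = int(round(de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    archetype = np.zeros(n_genes, dtype=int)
    fold = np.ones((n_genes, len(GROUPS)))
    for i in de_idx:
        if temporal_profiles:
            a = int(rng.integers(1, 6))
            archetype[i] = a
            base = np.array(ARCHETYPES[a])
            # rescale so the extreme group hits the requested fold-change
            ratios = np.log(base[1:] / base[0])
            k = np.argmax(np.abs(ratios))
            scale = np.log(fc) / np.abs(ratios[k])
            fold[i, 1:] = np.exp(ratios * scale)
        else:
            archetype[i] = 2 if rng.random() < 0.5 else 1
            f = fc if archetype[i] == 2 else 1.0 / fc
            fold[i, 1:] = f

    # co-expressed pairs share a temporal fold profile, so both members are
    # DE and their expression is strongly positively correlated
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for a_id, b_id in coexpressed_pairs:
        for g in (a_id, b_id):
            if g not in gene_pos:
                raise ValueError(f"coexpressed pair member {g!r} not in gene_ids")
        a_i, b_i = gene_pos[a_id], gene_pos[b_id]
        arch = int(rng.integers(1, 6))
        base = np.array(ARCHETYPES[arch])
        ratios = np.log(base[1:] / base[0])
        scale = np.log(fc) / np.abs(ratios[np.argmax(np.abs(ratios))])
        for i in (a_i, b_i):
            archetype[i] = arch
            fold[i, 1:] = np.exp(ratios * scale)

    group_of = {g: gi for gi, g in enumerate(GROUPS)}
    mu = np.empty((n_genes, len(samples)))
    for j, sample in enumerate(samples):
        gi = group_of[groups.iloc[j]]
        mu[:, j] = s[j] * q * fold[:, gi]
    if dispersion == 0:
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, mu / shape)
        counts = rng.poisson(lam)
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=samples)
    lib = counts_df.sum(axis=0).values
    fpkm = counts / (lengths[:, None] / 1000.0) / (lib[None, :] / 1e6)
    fpkm_df = pd.DataFrame(fpkm, index=gene_ids, columns=samples)

    de_table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "biotype": ["lncRNA" if g.startswith("LNC") else "protein_coding"
                        for g in gene_ids],
            "archetype": archetype,
            "length": lengths,
        }
    )
    for gi, g in enumerate(GROUPS[1:], start=1):
        de_table[f"fc_{g}"] = fold[:, gi]
        de_table[f"de_{g}"] = (fold[:, gi] > 2.0) | (fold[:, gi] < 0.5)
    truth = SyntheticTruth(de_genes=de_table, cis_pairs=list(coexpressed_pairs))
    return (
        ExpressionMatrix(counts_df, groups, batches, "counts"),
        ExpressionMatrix(fpkm_df, groups, batches, "fpkm"),
        truth,
    )


# ---------------------------------------------------------------------------
# Co-expression plantings


def simulate_coexpression(
    base: pd.DataFrame,
    cis_pairs: list[tuple[str, str]] = (),
    lnc_set_associations: list[tuple[str, list[str]]] = (),
    tf_lnc_pairs: list[tuple[str, str]] = (),
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Overwrite planted rows of ``base`` with shared-latent profiles.

    Each planted group (a cis pair, a lncRNA with its associated set members,
    or a TF-lncRNA pair) gets profiles x = z + e with a common standardized
    latent z per group and independent N(0, noise_sd^2) noise, so the
    expected pairwise Pearson r is 1 / (1 + noise_sd^2).
    """
    rng = np.random.default_rng(seed)
    out = base.copy().astype(float)
    n = out.shape[1]
    truth = SyntheticTruth(expected_r=1.0 / (1.0 + noise_sd**2))

    def plant(members: list[str]) -> None:
        z = rng.standard_normal(n)
        z = (z - z.mean()) / z.std()
        for g in members:
            if g not in out.index:
                raise ValueError(f"planted id {g!r} absent from matrix")
            out.loc[g] = z + rng.normal(0, noise_sd, size=n)

    for a, b in cis_pairs:
        plant([a, b])
        truth.cis_pairs.append((a, b))
    for lnc, members in lnc_set_associations:
        plant([lnc] + list(members))
        for m in members:
            truth.lnc_set_associations.append((lnc, m))
    for tf, lnc in tf_lnc_pairs:
        plant([tf, lnc])
        truth.tf_lnc_pairs.append((tf, lnc))
    return out, truth


# ---------------------------------------------------------------------------
# Promoters and motifs


def make_sharp_pwm(
    motif_id: str, tf_name: str, width: int = 8, seed: int = 0,
    sharpness: float = 0.97, background: np.ndarray | None = None,
) -> PWM:
    """PWM with one dominant base per column (probability ``sharpness``)."""
    rng = np.random.default_rng(seed)
    if background is None:
        background = np.full(4, 0.25)
    probs = np.full((4, width), (1 - sharpness) / 3)
    for j in range(width):
        probs[rng.integers(0, 4), j] = sharpness
    return PWM(motif_id, tf_name, probs, background)


def simulate_promoters(
    n_regions: int = 50,
    region_length: int = 600,
    pwms: list[PWM] | None = None,
    plant_rate: float = 0.5,
    seed: int = 0,
    background: np.ndarray | None = None,
) -> tuple[dict[str, str], SyntheticTruth]:
    """Background promoter sequences with motif occurrences planted.

    Each region is i.i.d. from the zero-order background; with probability
    ``plant_rate`` one motif (uniformly chosen) is sampled base-by-base from
    its PWM columns and written at a random offset and strand. Occurrences
    are recorded in the truth table.
    """
    if not 0 <= plant_rate <= 1:
        raise ValueError("plant_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if background is None:
        background = np.full(4, 0.25)
    if pwms is None:
        pwms = [make_sharp_pwm(f"M{i}", f"TF{i}", seed=seed + i) for i in range(3)]
    regions: dict[str, str] = {}
    occ = []
    for r in range(n_regions):
        seq = rng.choice(list(BASES), size=region_length, p=background)
        rid = f"REG{r:04d}"
        if rng.random() < plant_rate:
            pwm = pwms[int(rng.integers(0, len(pwms)))]
            strand = "+" if rng.random() < 0.5 else "-"
            mat = pwm.probs if strand == "+" else pwm.reverse_complement().probs
            offset = int(rng.integers(0, region_length - pwm.width + 1))
            for j in range(pwm.width):
                seq[offset + j] = BASES[
                    rng.choice(4, p=mat[:, j] / mat[:, j].sum())
                ]
            occ.append(
                {"region_id": rid, "motif_id": pwm.motif_id, "offset": offset,
                 "strand": strand}
            )
        regions[rid] = "".join(seq)
    truth = SyntheticTruth(
        motif_occurrences=pd.DataFrame(
            occ, columns=["region_id", "motif_id", "offset", "strand"]
        )
    )
    return regions, truth


def write_fasta(regions: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for rid in sorted(regions):
            fh.write(f">{rid}\n")
            seq = regions[rid]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Chain + SNPs


def simulate_chain_and_snps(
    n_intervals: int = 6,
    interval_length: int = 2000,
    n_inside: int = 3,
    n_outside: int = 3,
    seed: int = 0,
) -> tuple[ChainMap, ChainMap, dict[str, GenomicInterval], pd.DataFrame, SyntheticTruth]:
    """Toy chain (source chrS -> target chrT), its inverse, source intervals,
    and a SNP table with known inside/outside labels.

    The chain is piecewise: blocks of 5 kb separated by source-side gaps of
    100 bp (target contiguous), so block arithmetic is easy to trace by hand.
    Returns (chain, inverse_chain, regions, snp_table, truth).
    """
    rng = np.random.default_rng(seed)
    block, gap, n_blocks = 5000, 100, max(4, n_intervals + 2)
    blocks = [ChainBlock(block, gap, 0) for _ in range(n_blocks - 1)]
    blocks.append(ChainBlock(block, 0, 0))
    t_span = n_blocks * block + (n_blocks - 1) * gap
    q_span = n_blocks * block
    chain = Chain(
        score=1000, t_name="chrS", t_size=t_span + 10_000, t_strand="+",
        t_start=0, t_end=t_span, q_name="chrT", q_size=q_span + 10_000,
        q_strand="+", q_start=0, q_end=q_span, chain_id="1", blocks=blocks,
    )
    inv_blocks = [ChainBlock(block, 0, gap) for _ in range(n_blocks - 1)]
    inv_blocks.append(ChainBlock(block, 0, 0))
    inverse = Chain(
        score=1000, t_name="chrT", t_size=q_span + 10_000, t_strand="+",
        t_start=0, t_end=q_span, q_name="chrS", q_size=t_span + 10_000,
        q_strand="+", q_start=0, q_end=t_span, chain_id="1", blocks=inv_blocks,
    )
    chain.validate()
    inverse.validate()

    regions: dict[str, GenomicInterval] = {}
    images: list[tuple[str, int, int]] = []
    for i in range(n_intervals):
        # place each interval fully inside block i so round-trips are exact
        b_start = i * (block + gap)
        off = int(rng.integers(0, block - interval_length))
        start = b_start + off
        regions[f"LNC{i:04d}"] = GenomicInterval("chrS", start, start + interval_length, "+")
        q_start = i * block + off
        images.append((f"LNC{i:04d}", q_start, q_start + interval_length))

    snp_rows = []
    labels = []
    for k in range(n_inside):
        name, lo, hi = images[k % len(images)]
        pos0 = int(rng.integers(lo, hi))
        snp_rows.append(
            {
                "CHR_ID": "chrT", "CHR_POS": pos0 + 1, "SNPS": f"rs{1000+k}",
                "DISEASE/TRAIT": f"trait_{k}", "MAPPED_GENE": f"GENE{k}",
                "PUBMEDID": 20000000 + k, "SOURCE": "GWAS",
            }
        )
        labels.append({"rsid": f"rs{1000+k}", "inside": True, "lnc_id": name})
    outside_start = q_span + 1000
    for k in range(n_outside):
        pos0 = outside_start + 37 * k
        snp_rows.append(
            {
                "CHR_ID": "chrT", "CHR_POS": pos0 + 1, "SNPS": f"rs{2000+k}",
                "DISEASE/TRAIT": f"trait_out_{k}", "MAPPED_GENE": f"GENE{100+k}",
                "PUBMEDID": 21000000 + k, "SOURCE": "ClinVar",
            }
        )
        labels.append({"rsid": f"rs{2000+k}", "inside": False, "lnc_id": None})
    snps = pd.DataFrame(snp_rows)
    truth = SyntheticTruth(snp_labels=pd.DataFrame(labels))
    return ChainMap([chain]), ChainMap([inverse]), regions, snps, truth
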