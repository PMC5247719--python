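"""End-to-end orchestration of the synthetic-data pipeline.

Runs every analysis stage in dependency order on a generated dataset and
writes deterministic result tables; re-running with the same configuration
and seed reproduces every table byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from lncscape import annotation_io, synthetic_data
from lncscape.cis_pairs import filter_cis, pair_neighbors
from lncscape.clustering_enrichment import (
    hypergeom_enrich,
    row_zscore,
    ward_cluster,
)
from lncscape.diffexp import call_degs, venn_partition
from lncscape.expression_qc import (
    detect_outliers,
    floor_fpkm,
    log2_quantile_normalize,
    sample_correlation,
)
from lncscape.gba_gsea import gsea_nes_fdr, rank_by_correlation
from lncscape.homology_snp import intersect_snps, liftover_regions
from lncscape.lnc_classify import classify_catalogue
from lncscape.motif_regulation import scan_regions

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds and sizes for a full synthetic run."""

    seed: int = 0
    n_genes: int = 600
    n_lnc: int = 60
    de_fraction: float = 0.1
    planted_fc: float = 4.0
    dispersion: float = 0.1
    n_per_class: int = 6
    fpkm_floor: float = 0.1
    expressed_threshold: float = 1.0
    fc_threshold: float = 2.0
    deg_fdr: float = 0.01
    n_clusters: int = 5
    enrich_fdr: float = 0.05
    gsea_fdr: float = 0.25
    gsea_permutations: int = 200
    motif_fdr: float = 0.05
    neighbor_max_distance: int = 5000
    r_min: float = 0.75
    p_max: float = 0.01
    presence_threshold: int = 100
    min_match: float = 0.1
    stages: tuple[str, ...] = (
        "qc", "classify", "de", "cluster", "gba", "cis", "motifs", "snps",
    )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: PipelineConfig
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    summaries: dict[str, dict] = field(default_factory=dict)

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        for name, table in sorted(self.tables.items()):
            table.to_csv(os.path.join(outdir, f"{name}.tsv"), sep="\t", index=False)
        manifest = {
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "summaries": _jsonable(self.summaries),
        }
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (set, frozenset)):
        return sorted(_jsonable(v) for v in obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def run(config: PipelineConfig) -> PipelineResult:
    """Run the full synthetic pipeline per the config's stage toggles."""
    rng_seed = config.seed
    result = PipelineResult(config=config)
    stage = "generate"
    try:
        lncs, pcgs, class_truth = synthetic_data.simulate_annotation(
            n_per_class=config.n_per_class, seed=rng_seed
        )
        # plant co-expressed DE neighbor pairs on a few intergenic cassettes
        planted_pairs = []
        for lnc in lncs.genes():
            if class_truth.lnc_classes[lnc.gene_id] in ("IC", "ID"):
                from lncscape.lnc_classify import classify_lncrna

                c = classify_lncrna(lnc, pcgs)
                if c.partner_pcg_id is not None:
                    planted_pairs.append((lnc.gene_id, c.partner_pcg_id))
            if len(planted_pairs) >= 4:
                break
        counts, fpkm, de_truth = synthetic_data.simulate_counts(
            n_genes=config.n_genes,
            n_lnc=config.n_lnc,
            de_fraction=config.de_fraction,
            fc=config.planted_fc,
            dispersion=config.dispersion,
            coexpressed_pairs=planted_pairs,
            seed=rng_seed,
        )
        biotypes = de_truth.de_genes.set_index("gene_id")["biotype"]

        if "qc" in config.stages:
            stage = "qc"
            floored = floor_fpkm(fpkm, config.fpkm_floor)
            norm = log2_quantile_normalize(floored)
            sim = sample_correlation(norm)
            outliers = detect_outliers(sim)
            result.summaries["qc"] = {
                "outliers": outliers,
                "mean_within_group_r": float(sim.within_group_mean.mean()),
            }
            if outliers:
                keep = [s for s in counts.sample_ids if s not in outliers]
                counts = counts.subset_samples(keep)
                fpkm = fpkm.subset_samples(keep)
                floored = floor_fpkm(fpkm, config.fpkm_floor)
                norm = log2_quantile_normalize(floored)
        else:
            floored = floor_fpkm(fpkm, config.fpkm_floor)
            norm = log2_quantile_normalize(floored)

        if "classify" in config.stages:
            stage = "classify"
            class_table, class_summary = classify_catalogue(lncs, pcgs)
            result.tables["classes"] = class_table
            result.tables["class_summary"] = class_summary
            agree = sum(
                class_truth.lnc_classes[row["lnc_id"]] == row["class"]
                for _, row in class_table.iterrows()
            )
            result.summaries["classify"] = {
                "agreement": agree / len(class_table),
            }

        deg_tables: dict[str, pd.DataFrame] = {}
        if "de" in config.stages:
            stage = "de"
            for group in ("1M", "3M", "6M"):
                table = call_degs(
                    counts,
                    fpkm,
                    (group, "control"),
                    biotypes=biotypes,
                    expressed_threshold=config.expressed_threshold,
                    fc_threshold=config.fc_threshold,
                    fdr=config.deg_fdr,
                    floor=config.fpkm_floor,
                )
                deg_tables[group] = table
                result.tables[f"deg_{group}"] = table
            sets = {
                g: set(t.loc[t["deg"], "gene_id"]) for g, t in deg_tables.items()
            }
            venn = venn_partition(sets)
            result.summaries["de"] = {
                "n_deg": {g: len(s) for g, s in sets.items()},
                "venn": {"|".join(sorted(k)): v for k, v in venn.items()},
            }

        if "cluster" in config.stages and deg_tables:
            stage = "cluster"
            all_degs = sorted(
                set().union(*(s for s in (
                    set(t.loc[t["deg"], "gene_id"]) for t in deg_tables.values()
                )))
            )
            if len(all_degs) >= config.n_clusters:
                z = row_zscore(norm.values.loc[all_degs])
                clusters = ward_cluster(z, config.n_clusters)
                ctable = clusters.assignments.rename("cluster").reset_index()
                ctable.columns = ["gene_id", "cluster"]
                ctable["biotype"] = biotypes.reindex(ctable["gene_id"]).values
                result.tables["clusters"] = ctable
                # gene sets built from planted archetypes give a nontrivial
                # enrichment target
                truth_sets = {
                    f"archetype_{a}": set(
                        de_truth.de_genes.loc[
                            de_truth.de_genes["archetype"] == a, "gene_id"
                        ]
                    )
                    for a in range(1, 6)
                }
                universe = list(norm.values.index)
                enrich_frames = []
                for c in sorted(clusters.assignments.unique()):
                    genes = clusters.assignments.index[clusters.assignments == c]
                    et = hypergeom_enrich(
                        genes, truth_sets, universe, fdr=config.enrich_fdr
                    )
                    if len(et):
                        et.insert(0, "cluster", c)
                        enrich_frames.append(et)
                if enrich_frames:
                    result.tables["cluster_enrichment"] = pd.concat(
                        enrich_frames, ignore_index=True
                    )

        if "gba" in config.stages and deg_tables:
            stage = "gba"
            lnc_ids = [g for g in norm.values.index if g.startswith("LNC")]
            pcg_ids = [g for g in norm.values.index if g.startswith("PCG")]
            de_lnc = sorted(
                set().union(*(
                    set(t.loc[t["deg"] & t["gene_id"].str.startswith("LNC"), "gene_id"])
                    for t in deg_tables.values()
                ))
            )[:3]
            gba_sets = {
                f"set_{i}": set(
                    np.random.default_rng(rng_seed + i).choice(
                        pcg_ids, size=min(30, len(pcg_ids)), replace=False
                    )
                )
                for i in range(4)
            }
            frames = []
            for lnc in de_lnc:
                if norm.values.loc[lnc].std() == 0:
                    logger.warning("%s: constant profile, skipped in GBA", lnc)
                    continue
                ranked = rank_by_correlation(
                    norm.values.loc[lnc], norm.values.loc[pcg_ids], lnc_id=lnc
                )
                frames.append(
                    gsea_nes_fdr(
                        ranked,
                        gba_sets,
                        n_perm=config.gsea_permutations,
                        seed=rng_seed,
                        fdr=config.gsea_fdr,
                    )
                )
            if frames:
                result.tables["gba"] = pd.concat(frames, ignore_index=True)

        if "cis" in config.stages and deg_tables and "classes" in result.tables:
            stage = "cis"
            de_all = set().union(*(
                set(t.loc[t["deg"], "gene_id"]) for t in deg_tables.values()
            ))
            classified = set(result.tables["classes"]["lnc_id"])
            pairs = pair_neighbors(
                {g for g in de_all if g.startswith("LNC")} & classified,
                {g for g in de_all if g.startswith("PCG")},
                result.tables["classes"],
                norm.values,
            )
            kept, summary = filter_cis(
                pairs,
                r_min=config.r_min,
                p_max=config.p_max,
                max_distance=config.neighbor_max_distance,
            )
            result.tables["cis_pairs"] = kept
            result.summaries["cis"] = summary

        if "motifs" in config.stages:
            stage = "motifs"
            # width-12, near-deterministic columns: the exact-p floor of a
            # PWM is 4^-w, so short motifs cannot clear a run-wide BH cut
            pwms = [
                synthetic_data.make_sharp_pwm(
                    f"M{i}", f"TF{i}", width=12, sharpness=0.99, seed=rng_seed + i
                )
                for i in range(3)
            ]
            regions, motif_truth = synthetic_data.simulate_promoters(
                n_regions=40, region_length=400, pwms=pwms,
                plant_rate=0.5, seed=rng_seed,
            )
            hits = scan_regions(pwms, regions, fdr=config.motif_fdr)
            result.tables["motif_hits"] = hits
            planted = set(motif_truth.motif_occurrences["region_id"])
            found = set(hits["region_id"]) if len(hits) else set()
            result.summaries["motifs"] = {
                "planted_regions": len(planted),
                "recalled": len(planted & found),
            }

        if "snps" in config.stages:
            stage = "snps"
            chain, _inv, regions, snps, snp_truth = (
                synthetic_data.simulate_chain_and_snps(seed=rng_seed)
            )
            lifted = liftover_regions(regions, chain, min_match=config.min_match)
            mapped = {
                row["id"]: annotation_io.GenomicInterval(
                    row["chrom"], int(row["start"]), int(row["end"])
                )
                for _, row in lifted.iterrows()
                if row["mapped"]
            }
            report = intersect_snps(mapped, snps)
            result.tables["snp_report"] = report
            n_inside = int(snp_truth.snp_labels["inside"].sum())
            result.summaries["snps"] = {
                "expected_rows": n_inside,
                "observed_rows": len(report),
            }
    except Exception:
        logger.exception("pipeline halted in stage %r", stage)
        raise
    return result
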