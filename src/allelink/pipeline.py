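"""End-to-end orchestration over a panel directory.

A panel directory holds the pipeline's inputs in their standard formats:
``panel.vcf`` (phased genotypes), ``counts.tsv`` (allelic depths),
``peaks_<mark>.bed``, ``interactions.bedpe``, ``genes.tsv``, ``tags.tsv``,
plus optional ``go.tsv``, ``affinity.tsv`` and trait matrices.  The runner
executes LD expansion, imbalance testing, pairing, the explanatory-power
curve, the QTL comparator and Random Forest rescue in order, writing one
TSV per stage and a manifest with seeds, stage counts and file hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import explanatory as expl
from . import qtl_compare as qtl
from .features import FeatureSpec, pair_id
from .genomic_io import (HISTONE_MARKS, AllelicDepth, read_allelic_counts,
                         read_bed_peaks,
                         read_bedpe_interactions, read_gene_models,
                         read_phased_vcf)
from .haplotype_ld import (four_gamete_blocks, ld_expand, merge_blocks,
                           read_block_definitions)
from .imbalance import ImbalanceConfig
from .pairing import TRUE_PAIR, UNTESTABLE, build_pairs
from .predictor import (ForestConfig, MappingInputs, partition_cases,
                        subsample_experiment, train_and_rescue,
                        validate_rescue)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    panel_dir: Path
    out_dir: Path
    imbalance: ImbalanceConfig = field(default_factory=ImbalanceConfig)
    forest: ForestConfig = field(default_factory=ForestConfig)
    subpanel_size: int | None = None   # None: train on the full panel
    subpanel_reps: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.panel_dir = Path(self.panel_dir)
        self.out_dir = Path(self.out_dir)


def _read_traits(path: Path) -> dict[str, dict[str, float]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return {trait: row.to_dict() for trait, row in df.iterrows()}


def load_panel_dir(panel_dir: str | Path) -> MappingInputs:
    """Read a panel directory into pairing/prediction inputs."""
    panel_dir = Path(panel_dir)
    for required in ("panel.vcf", "counts.tsv", "interactions.bedpe",
                     "genes.tsv", "tags.tsv"):
        if not (panel_dir / required).exists():
            raise FileNotFoundError(panel_dir / required)
    panel = read_phased_vcf(panel_dir / "panel.vcf")
    counts = read_allelic_counts(panel_dir / "counts.tsv")
    # the count table carries chrom:pos only; adopt the panel's SNP ids
    by_pos = {(s.chrom, s.pos): s for s in panel.snps}
    counts = [
        AllelicDepth(by_pos.get((c.snp.chrom, c.snp.pos), c.snp), c.sample,
                     c.assay, c.study_id, c.ref_depth, c.alt_depth)
        for c in counts]
    peaks = []
    tracks = {}
    for mark in HISTONE_MARKS:
        bed = panel_dir / f"peaks_{mark}.bed"
        if bed.exists():
            track = read_bed_peaks(bed, mark)
            peaks.extend(track)
            tracks[mark] = track
    interactions = read_bedpe_interactions(panel_dir / "interactions.bedpe", "file")
    genes = read_gene_models(panel_dir / "genes.tsv")
    tags = pd.read_csv(panel_dir / "tags.tsv", sep="\t", dtype=str)["tag_id"].tolist()

    go_sets: dict[str, set[str]] = {}
    if (panel_dir / "go.tsv").exists():
        go = pd.read_csv(panel_dir / "go.tsv", sep="\t", dtype=str)
        for row in go.itertuples(index=False):
            go_sets.setdefault(row.term, set()).add(row.gene_id)
    affinity: dict[tuple[str, str], float] = {}
    if (panel_dir / "affinity.tsv").exists():
        aff = pd.read_csv(panel_dir / "affinity.tsv", sep="\t",
                          dtype={"variant": str, "motif": str})
        for row in aff.itertuples(index=False):
            affinity[(row.variant, row.motif)] = float(row.score)

    specs = [FeatureSpec(m, "tf_affinity", m)
             for m in sorted({motif for _, motif in affinity})]
    specs += [FeatureSpec(t, "go_term", t) for t in sorted(go_sets)]
    specs.append(FeatureSpec("tss_distance", "tss_distance"))
    specs += [FeatureSpec(f"distal_{m}", "distal_peak", m) for m in sorted(tracks)]

    # LD expansion: GAB blocks from file when provided, merged with
    # four-gamete blocks built from the panel itself
    gam_by_chrom = {}
    for chrom in sorted({s.chrom for s in panel.snps}):
        gam_by_chrom[chrom] = four_gamete_blocks(panel, chrom, "panel")
    gam = [b for blocks in gam_by_chrom.values() for b in blocks]
    if (panel_dir / "blocks.tsv").exists():
        from dataclasses import replace as dc_replace

        gab_by_pop = read_block_definitions(panel_dir / "blocks.tsv")
        blocks_by_pop = {
            pop: merge_blocks(gab, [dc_replace(b, population=pop) for b in gam])
            for pop, gab in gab_by_pop.items()}
    else:
        blocks_by_pop = {"panel": gam}
    ld_expansion = {tag: ld_expand(tag, blocks_by_pop) for tag in tags}

    return MappingInputs(
        tags=tags, ld_expansion=ld_expansion, peaks=peaks,
        interactions=interactions, genes=genes, panel=panel, counts=counts,
        imbalance_cfg=ImbalanceConfig(), feature_specs=specs, tracks=tracks,
        go_sets=go_sets, affinity=affinity)


def read_peak_map(path: Path) -> dict[str, "object"]:
    """Read trait_id -> Peak mapping: trait_id, chrom, start, end, mark."""
    from .genomic_io import GenomicInterval, Peak

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {row.trait_id: Peak(GenomicInterval(row.chrom, int(row.start),
                                               int(row.end)), row.mark)
            for row in df.itertuples(index=False)}


def run_qtl_arm(inputs: MappingInputs, pairs, peaks_by_trait,
                peak_traits, expr_traits, alpha: float = 0.05,
                mark: str = "H3K27ac"):
    """hQTL/eQTL regressions over the pairing's candidate links."""
    reg_snps = sorted({p.reg_snp for p in pairs})
    hqtl_links: dict[str, list[str]] = {}
    eqtl_links: dict[str, list[str]] = {}
    for snp_id in reg_snps:
        snp = inputs.panel.snp(snp_id)
        hqtl_links[snp_id] = [
            tid for tid, pk in peaks_by_trait.items()
            if pk.interval.contains_position(snp.chrom, snp.pos)]
    for p in pairs:
        genes_for = eqtl_links.setdefault(p.reg_snp, [])
        if p.gene_id in expr_traits and p.gene_id not in genes_for:
            genes_for.append(p.gene_id)
    hqtl = qtl.map_qtls(inputs.panel, peak_traits, hqtl_links)
    eqtl = qtl.map_qtls(inputs.panel, expr_traits, eqtl_links)
    qtl_pairs = qtl.hqtl_eqtl_pairs(hqtl, eqtl, inputs.interactions,
                                    peaks_by_trait, inputs.genes, alpha, mark)
    return hqtl, eqtl, qtl_pairs


def report_funnel(stage_counts: dict[str, tuple[int, int]]) -> str:
    """Format the applicable -> imbalanced -> paired funnel per level.

    ``stage_counts`` maps stage name -> (n_snps, n_genes); stages are
    expected in pipeline order and must be non-increasing.
    """
    lines = ["stage\tn_snps\tn_genes"]
    prev = None
    for stage, (n_snps, n_genes) in stage_counts.items():
        if prev is not None and (n_snps > prev[0] or n_genes > prev[1]):
            raise ValueError(f"funnel not monotone at stage {stage!r}")
        prev = (n_snps, n_genes)
        lines.append(f"{stage}\t{n_snps}\t{n_genes}")
    return "\n".join(lines) + "\n"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def pairs_to_frame(pairs) -> pd.DataFrame:
    rows = []
    for p in pairs:
        rows.append({
            "pair_id": pair_id(p), "tag_snp": p.tag_snp, "reg_snp": p.reg_snp,
            "mark": p.reg_mark, "gene_id": p.gene_id, "tx_snp": p.tx_snp,
            "sources": ",".join(p.interaction_sources), "flipped": p.flipped,
            "n_obs": len(p.observations),
            "reg_p": p.reg_result.combined_p if p.reg_result else float("nan"),
            "tx_p": p.tx_result.combined_p if p.tx_result else float("nan"),
            "mean_reg_ratio": p.mean_reg_ratio if p.observations else float("nan"),
            "mean_tx_ratio": p.mean_tx_ratio if p.observations else float("nan"),
            "direction_ok": p.direction_ok, "label": p.label,
            "ld_distance": p.ld.distance if p.ld and p.ld.defined else float("nan"),
        })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a panel directory; returns the manifest dict."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}

    inputs = load_panel_dir(config.panel_dir)
    marks = sorted(inputs.tracks)

    # ---- pairing ---------------------------------------------------------
    pairs = build_pairs(inputs.tags, inputs.ld_expansion, inputs.peaks,
                        inputs.interactions, inputs.genes, inputs.panel,
                        inputs.counts, config.imbalance)
    frame = pairs_to_frame(pairs)
    frame.to_csv(out / "pairs.tsv", sep="\t", index=False)

    true_set, control_set, untestable_set = partition_cases(pairs)
    applicable_tags = {p.tag_snp for p in pairs}
    reg_imbalanced_tags = {p.tag_snp for p in pairs
                           if p.reg_result is not None
                           and p.reg_result.is_imbalanced}
    paired_tags = {p.tag_snp for p in true_set}
    applicable_genes = {p.gene_id for p in pairs}
    reg_imb_genes = {p.gene_id for p in pairs
                     if p.reg_result is not None and p.reg_result.is_imbalanced}
    paired_genes = {p.gene_id for p in true_set}
    funnel = {
        "applicable": (len(applicable_tags), len(applicable_genes)),
        "imbalanced": (len(reg_imbalanced_tags & applicable_tags),
                       len(reg_imb_genes & applicable_genes)),
        "paired": (len(paired_tags), len(paired_genes)),
    }
    (out / "funnel.tsv").write_text(report_funnel(funnel))
    manifest["stages"]["pairing"] = {
        "n_pairs": len(pairs), "n_true": len(true_set),
        "n_control": len(control_set), "n_untestable": len(untestable_set),
        "funnel": {k: list(v) for k, v in funnel.items()},
    }

    # ---- explanatory power ----------------------------------------------
    curves = []
    mapped = [p for p in pairs if p.label == TRUE_PAIR]
    for mark in marks:
        curve = expl.distance_curve(mapped, mark)
        for d, r2, n in zip(curve.grid, curve.mean_r2_at, curve.n_pairs_at):
            curves.append({"mark": mark, "threshold": d, "n_points": n,
                           "mean_r2": r2})
    pd.DataFrame(curves).to_csv(out / "explanatory_curve.tsv", sep="\t",
                                index=False)
    manifest["stages"]["explanatory"] = {"n_rows": len(curves)}

    # ---- QTL comparator --------------------------------------------------
    if (config.panel_dir / "peak_traits.tsv").exists() \
            and (config.panel_dir / "peak_map.tsv").exists():
        peak_traits = _read_traits(config.panel_dir / "peak_traits.tsv")
        expr_traits = _read_traits(config.panel_dir / "expr_traits.tsv")
        peaks_by_trait = read_peak_map(config.panel_dir / "peak_map.tsv")
        hqtl, eqtl, qtl_pairs = run_qtl_arm(
            inputs, pairs, peaks_by_trait, peak_traits, expr_traits,
            mark=marks[0] if marks else "H3K27ac")
        qtl_frame = pd.DataFrame(
            [{"snp": r.snp, "trait_id": r.trait_id, "beta": r.beta,
              "p_value": r.p_value, "kind": kind}
             for kind, results in (("hQTL", hqtl), ("eQTL", eqtl))
             for r in results])
        qtl_frame.to_csv(out / "qtl.tsv", sep="\t", index=False)
        allelic_tags = {p.tag_snp for p in true_set}
        qtl_snps = {q.snp for q in qtl_pairs}
        qtl_tags = {p.tag_snp for p in pairs if p.reg_snp in qtl_snps}
        report = qtl.sensitivity_report(allelic_tags, qtl_tags,
                                        set(inputs.tags))
        manifest["stages"]["qtl"] = {
            "n_hqtl": len(hqtl), "n_eqtl": len(eqtl),
            "n_qtl_pairs": len(qtl_pairs),
            "sensitivity": {"allelic": report.n_allelic, "qtl": report.n_qtl,
                            "overlap": report.n_overlap},
        }

    # ---- prediction ------------------------------------------------------
    if config.subpanel_size is None:
        run = train_and_rescue(inputs, config.forest)
        runs = [run]
    else:
        runs = subsample_experiment(inputs, config.subpanel_size,
                                    config.subpanel_reps, config.seed,
                                    config.forest)
    pred_rows = []
    for i, run in enumerate(runs):
        row = {"replicate": i, "n_true": run.n_true,
               "n_control": run.n_control, "n_untestable": run.n_untestable,
               "mean_auc": float("nan"), "n_positive": 0, "failure": run.failure or ""}
        if run.ensemble is not None:
            row["mean_auc"] = run.ensemble.mean_auc
            row["n_positive"] = len(run.ensemble.positives)
            validation = validate_rescue(run.ensemble.positives, pairs)
            row.update(n_predicted=validation.n_predicted,
                       n_tested=validation.n_tested,
                       n_confirmed=validation.n_confirmed,
                       percentage=validation.percentage)
        pred_rows.append(row)
    pd.DataFrame(pred_rows).to_csv(out / "prediction.tsv", sep="\t", index=False)
    manifest["stages"]["prediction"] = {"n_runs": len(runs)}

    manifest["files"] = {p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return manifest
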