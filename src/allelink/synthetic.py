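"""Synthetic reference panels with known ground truth.

Emulates the study design the pipeline targets: a panel of genetically
distinct cell lines with phased genotypes, histone ChIP-seq and RNA-seq
allelic read counts, peak calls, a chromatin interactome, gene models and
per-pair epigenomic feature tables.  Every emitted object carries planted
truth, so each pipeline stage can be checked against construction.

World layout: one chromosome carved into tag-SNP blocks 100 kb apart.  Each
block holds a GWAS tag SNP, a candidate regulatory SNP inside a ChIP-seq
peak, and a gene 50 kb away whose transcript contains RNA-readable SNPs; a
chromatin interaction links the peak anchor to the gene anchor (decoy
interactions link peaks to genes of other blocks).  Haplotypes are mosaics
of two founder haplotypes with a per-step recombination probability, giving
LD that decays with SNP separation.

Cis effects are planted at the haplotype level: in a sample heterozygous at
the regulatory SNP, the chromosome carrying the alternative allele produces
a planted per-block fraction of the reads — of the activating ChIP
marks and of the transcript — while homozygous samples stay balanced.  The
repressive mark's ChIP fraction is complemented.  Read counts are binomial
draws at Poisson depths, matching the balanced-binomial null of the
imbalance test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .features import FeatureSpec
from .genomic_io import (AllelicDepth, GeneModel, GenomicInterval,
                         HaplotypePanel, Interaction, Peak, Snp,
                         write_allelic_counts, write_bed_peaks,
                         write_bedpe_interactions, write_gene_models,
                         write_phased_vcf)
from .imbalance import ImbalanceConfig
from .pairing import MARK_POLARITY

BLOCK_SPAN = 100_000
SNP_SPACING = 500
GENE_OFFSET = 50_000
GENE_LENGTH = 5_000
PEAK_HALFWIDTH = 250


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic panel; defaults are the study conditions."""

    n_samples: int = 100
    n_tags: int = 20
    snps_per_block: int = 6      # tag + candidates, regulatory SNP at index 1
    n_tx_snps: int = 3           # RNA-readable SNPs inside the gene
    ld_decay: float = 0.02       # per-SNP-step founder-switch probability
    effect_fraction: float = 0.5  # fraction of blocks with a planted effect
    #: active-haplotype read fractions cycled over the effect blocks;
    #: real cis effects vary in strength across loci
    effect_hap_fractions: tuple[float, ...] = (0.65, 0.7, 0.75, 0.8, 0.85, 0.9)
    #: per-sample wobble of the active-haplotype fraction, shared between the
    #: ChIP and RNA readouts of a block (trans variation in enhancer output)
    effect_sample_sd: float = 0.05
    mark: str = "H3K27ac"
    chip_depth: float = 50.0     # mean read depth per het site (Poisson)
    rna_depth: float = 50.0
    n_studies: int = 1
    founder_freq: float = 0.5    # frequency of founder-1 haplotypes
    n_rare_blocks: int = 0       # trailing blocks get the rare frequency
    rare_founder_freq: float = 0.08
    n_decoys: int = 8            # random peak -> wrong-gene interactions
    qtl_beta: float = 0.5        # additive effect in the trait matrices
    trait_noise_sd: float = 1.0
    n_var_features: int = 10     # variant-level binary features
    n_go_features: int = 10      # gene-level GO membership features
    feature_signal: tuple[float, float] = (0.9, 0.1)  # bit rate true vs control
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(0 < f < 1 for f in self.effect_hap_fractions):
            raise ValueError("effect_hap_fractions must lie in (0, 1)")
        if self.chip_depth < 1 or self.rna_depth < 1:
            raise ValueError("mean depths must be >= 1")
        if self.mark not in MARK_POLARITY:
            raise ValueError(f"unknown mark {self.mark!r}")


@dataclass
class BlockTruth:
    block: int
    tag_id: str
    reg_snp_id: str
    gene_id: str
    mark: str
    effect: bool
    hap_fraction: float
    founder_freq: float
    snp_ids: list[str] = field(default_factory=list)
    tx_snp_ids: list[str] = field(default_factory=list)


@dataclass
class GroundTruth:
    blocks: list[BlockTruth]
    decoys: list[tuple[int, int]]          # (peak block, gene block)
    qtl_betas: dict[str, float]            # trait id -> planted beta
    feature_bits: dict[str, dict[str, int]]  # feature name -> {key: bit}
    seed: int = 0

    def effect_blocks(self) -> list[BlockTruth]:
        return [b for b in self.blocks if b.effect]

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "decoys": self.decoys,
            "qtl_betas": self.qtl_betas,
            "blocks": [vars(b) for b in self.blocks],
            "feature_bits": self.feature_bits,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _block_positions(cfg: SimConfig, b: int) -> tuple[list[int], list[int]]:
    """1-based positions of a block's candidate SNPs and transcript SNPs."""
    base = b * BLOCK_SPAN
    cand = [base + 1001 + SNP_SPACING * j for j in range(cfg.snps_per_block)]
    tx = [base + GENE_OFFSET + 501 + SNP_SPACING * j for j in range(cfg.n_tx_snps)]
    return cand, tx


def simulate_haplotypes(cfg: SimConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[HaplotypePanel, GroundTruth]:
    """Mosaic-of-two-founders haplotype panel with per-block LD structure."""
    rng = rng or np.random.default_rng(cfg.seed)
    n_effect = int(round(cfg.n_tags * cfg.effect_fraction))
    snps: list[Snp] = []
    blocks: list[BlockTruth] = []
    columns: list[np.ndarray] = []
    n_hap = 2 * cfg.n_samples
    for b in range(cfg.n_tags):
        cand_pos, tx_pos = _block_positions(cfg, b)
        rare = b >= cfg.n_tags - cfg.n_rare_blocks
        freq = cfg.rare_founder_freq if rare else cfg.founder_freq
        cand_ids = [f"tag{b}"] + [f"b{b}s{j}" for j in range(1, cfg.snps_per_block)]
        tx_ids = [f"b{b}tx{j}" for j in range(cfg.n_tx_snps)]
        all_pos = cand_pos + tx_pos
        all_ids = cand_ids + tx_ids
        founder = np.empty((n_hap, len(all_pos)), dtype=np.uint8)
        state = (rng.random(n_hap) < freq).astype(np.uint8)
        founder[:, 0] = state
        for j in range(1, len(all_pos)):
            switch = rng.random(n_hap) < cfg.ld_decay
            state = np.where(switch, 1 - state, state)
            founder[:, j] = state
        # founder identity is the allele: founder 1 carries alt everywhere
        for vid, pos, col in zip(all_ids, all_pos, founder.T):
            snps.append(Snp(vid, cfg.chrom, int(pos), "A", "G"))
            columns.append(col.reshape(cfg.n_samples, 2))
        blocks.append(BlockTruth(
            block=b, tag_id=cand_ids[0], reg_snp_id=cand_ids[1],
            gene_id=f"gene{b}", mark=cfg.mark, effect=False,
            hap_fraction=0.5, founder_freq=freq,
            snp_ids=all_ids, tx_snp_ids=tx_ids))
    # plant effects: alternate over blocks so common and rare strata both
    # contain effect and non-effect members; effect strengths cycle through
    # the configured fractions
    quota = n_effect
    planted = 0
    for start in (0, 1):
        for b in range(start, cfg.n_tags, 2):
            if quota:
                blocks[b].effect = True
                blocks[b].hap_fraction = cfg.effect_hap_fractions[
                    planted % len(cfg.effect_hap_fractions)]
                planted += 1
                quota -= 1
    haps = np.stack(columns, axis=1)
    panel = HaplotypePanel([f"S{i:03d}" for i in range(cfg.n_samples)], snps, haps)
    truth = GroundTruth(blocks, [], {}, {}, cfg.seed)
    return panel, truth


def _sample_fractions(cfg: SimConfig, panel: HaplotypePanel,
                      block: BlockTruth,
                      rng: np.random.Generator) -> dict[str, float]:
    """Per-sample active-haplotype fraction for one block.

    The fraction wobbles around the planted value per sample (shared by the
    block's ChIP and RNA readouts); non-effect blocks sit at 0.5.
    """
    out: dict[str, float] = {}
    for sample in panel.samples:
        if block.effect and panel.genotype(block.reg_snp_id, sample).is_het:
            out[sample] = float(np.clip(
                block.hap_fraction + rng.normal(0, cfg.effect_sample_sd),
                0.05, 0.95))
        else:
            out[sample] = 0.5
    return out


def _read_fractions(panel: HaplotypePanel, block: BlockTruth, snp_id: str,
                    assay: str,
                    sample_f: dict[str, float]) -> dict[str, float]:
    """Expected reference-read fraction per heterozygous sample."""
    out: dict[str, float] = {}
    repressive = MARK_POLARITY.get(assay) == "repressive"
    for sample in panel.het_samples(snp_id):
        reg_gt = panel.genotype(block.reg_snp_id, sample)
        gt = panel.genotype(snp_id, sample)
        f = sample_f[sample]
        if not reg_gt.is_het:
            ref_fraction = 0.5
        else:
            # chromosome carrying the regulatory ALT allele yields fraction f
            alt_hap = 0 if reg_gt.hap1_allele == 1 else 1
            f_assay = (1 - f) if (repressive and assay != "RNA") else f
            ref_on_alt_hap = (gt.hap1_allele == 0) == (alt_hap == 0)
            ref_fraction = f_assay if ref_on_alt_hap else 1 - f_assay
        out[sample] = ref_fraction
    return out


def simulate_allelic_counts(cfg: SimConfig, panel: HaplotypePanel,
                            truth: GroundTruth,
                            rng: np.random.Generator | None = None
                            ) -> list[AllelicDepth]:
    """Binomial read counts at regulatory (ChIP) and transcript (RNA) SNPs."""
    rng = rng or np.random.default_rng(cfg.seed + 1)
    records: list[AllelicDepth] = []
    for block in truth.blocks:
        sample_f = _sample_fractions(cfg, panel, block, rng)
        sites = [(block.reg_snp_id, block.mark, cfg.chip_depth)] + \
                [(tx, "RNA", cfg.rna_depth) for tx in block.tx_snp_ids]
        for snp_id, assay, mean_depth in sites:
            snp = panel.snp(snp_id)
            fractions = _read_fractions(panel, block, snp_id, assay, sample_f)
            for sample, ref_fraction in fractions.items():
                for study in range(cfg.n_studies):
                    depth = int(rng.poisson(mean_depth))
                    if depth == 0:
                        continue
                    ref = int(rng.binomial(depth, ref_fraction))
                    records.append(AllelicDepth(
                        snp, sample, assay, f"study{study}", ref, depth - ref))
    return records


def simulate_trait_matrices(cfg: SimConfig, panel: HaplotypePanel,
                            truth: GroundTruth,
                            rng: np.random.Generator | None = None
                            ) -> tuple[dict, dict]:
    """Per-sample peak-intensity and expression matrices with additive QTLs.

    trait = baseline + beta * dosage + N(0, noise); beta is the planted
    effect for effect blocks and 0 otherwise.
    """
    rng = rng or np.random.default_rng(cfg.seed + 2)
    peak_traits: dict[str, dict[str, float]] = {}
    expr_traits: dict[str, dict[str, float]] = {}
    for block in truth.blocks:
        beta = cfg.qtl_beta if block.effect else 0.0
        truth.qtl_betas[f"peak{block.block}"] = beta
        truth.qtl_betas[block.gene_id] = beta
        dosages = np.array([panel.genotype(block.reg_snp_id, s).dosage
                            for s in panel.samples], dtype=float)
        base = 10.0
        chip = base + beta * dosages + rng.normal(0, cfg.trait_noise_sd,
                                                  cfg.n_samples)
        expr = base + beta * dosages + rng.normal(0, cfg.trait_noise_sd,
                                                  cfg.n_samples)
        peak_traits[f"peak{block.block}"] = dict(zip(panel.samples, chip.tolist()))
        expr_traits[block.gene_id] = dict(zip(panel.samples, expr.tolist()))
    return peak_traits, expr_traits


def _simulate_features(cfg: SimConfig, truth: GroundTruth,
                       rng: np.random.Generator) -> tuple[dict, dict]:
    """Binary feature tables with class signal tied to planted effects.

    Variant-level bits go into the TF-affinity table keyed by the regulatory
    SNP; gene-level bits become GO-term memberships.  Effect blocks draw
    bits at the "true" rate, others at the "control" rate.
    """
    rate_true, rate_ctrl = cfg.feature_signal
    affinity: dict[tuple[str, str], float] = {}
    go_sets: dict[str, set[str]] = {f"GO{j}": set() for j in range(cfg.n_go_features)}
    for block in truth.blocks:
        rate = rate_true if block.effect else rate_ctrl
        for j in range(cfg.n_var_features):
            bit = int(rng.random() < rate)
            affinity[(block.reg_snp_id, f"feat{j}")] = float(bit)
            truth.feature_bits.setdefault(f"feat{j}", {})[block.reg_snp_id] = bit
        for j in range(cfg.n_go_features):
            bit = int(rng.random() < rate)
            if bit:
                go_sets[f"GO{j}"].add(block.gene_id)
            truth.feature_bits.setdefault(f"GO{j}", {})[block.gene_id] = bit
    return affinity, go_sets


def default_feature_specs(cfg: SimConfig) -> list[FeatureSpec]:
    specs = [FeatureSpec(f"feat{j}", "tf_affinity", f"feat{j}")
             for j in range(cfg.n_var_features)]
    specs += [FeatureSpec(f"GO{j}", "go_term", f"GO{j}")
              for j in range(cfg.n_go_features)]
    specs.append(FeatureSpec("tss_distance", "tss_distance"))
    specs.append(FeatureSpec(f"distal_{cfg.mark}", "distal_peak", cfg.mark))
    return specs


@dataclass
class Scenario:
    """In-memory synthetic world: pipeline inputs plus the planted truth."""

    cfg: SimConfig
    panel: HaplotypePanel
    truth: GroundTruth
    tags: list[str]
    ld_expansion: dict[str, set[str]]
    peaks: list[Peak]
    interactions: list[Interaction]
    genes: list[GeneModel]
    counts: list[AllelicDepth]
    peak_traits: dict[str, dict[str, float]]
    expr_traits: dict[str, dict[str, float]]
    affinity: dict[tuple[str, str], float]
    go_sets: dict[str, set[str]]
    feature_specs: list[FeatureSpec]
    peaks_by_trait: dict[str, Peak]

    def mapping_inputs(self, imbalance_cfg: ImbalanceConfig | None = None):
        from .predictor import MappingInputs

        return MappingInputs(
            tags=self.tags, ld_expansion=self.ld_expansion, peaks=self.peaks,
            interactions=self.interactions, genes=self.genes, panel=self.panel,
            counts=self.counts, imbalance_cfg=imbalance_cfg or ImbalanceConfig(),
            feature_specs=self.feature_specs,
            tracks={self.cfg.mark: self.peaks}, go_sets=self.go_sets,
            affinity=self.affinity)


def build_scenario(cfg: SimConfig) -> Scenario:
    """Generate the full synthetic world for one configuration."""
    rng = np.random.default_rng(cfg.seed)
    panel, truth = simulate_haplotypes(cfg, rng)
    counts = simulate_allelic_counts(cfg, panel, truth, rng)
    peak_traits, expr_traits = simulate_trait_matrices(cfg, panel, truth, rng)
    affinity, go_sets = _simulate_features(cfg, truth, rng)

    peaks, genes, interactions = [], [], []
    peaks_by_trait: dict[str, Peak] = {}
    for block in truth.blocks:
        reg = panel.snp(block.reg_snp_id)
        peak = Peak(GenomicInterval(cfg.chrom, reg.pos - 1 - PEAK_HALFWIDTH,
                                    reg.pos - 1 + PEAK_HALFWIDTH), block.mark)
        peaks.append(peak)
        peaks_by_trait[f"peak{block.block}"] = peak
        gene_start = block.block * BLOCK_SPAN + GENE_OFFSET
        genes.append(GeneModel(
            block.gene_id,
            GenomicInterval(cfg.chrom, gene_start, gene_start + GENE_LENGTH),
            gene_start + 1, "+"))
        interactions.append(Interaction(
            peak.interval,
            GenomicInterval(cfg.chrom, gene_start, gene_start + 2000),
            "sim"))
    for _ in range(cfg.n_decoys):
        i = int(rng.integers(cfg.n_tags))
        j = int(rng.integers(cfg.n_tags))
        if i == j:
            continue
        gene_start = j * BLOCK_SPAN + GENE_OFFSET
        interactions.append(Interaction(
            peaks[i].interval,
            GenomicInterval(cfg.chrom, gene_start, gene_start + 2000),
            "decoy"))
        truth.decoys.append((i, j))

    tags = [b.tag_id for b in truth.blocks]
    ld_expansion = {b.tag_id: set(b.snp_ids) for b in truth.blocks}
    return Scenario(cfg, panel, truth, tags, ld_expansion, peaks, interactions,
                    genes, counts, peak_traits, expr_traits, affinity, go_sets,
                    default_feature_specs(cfg), peaks_by_trait)


def emit_panel(cfg: SimConfig, outdir: str | Path) -> tuple[Scenario, dict[str, Path]]:
    """Write the synthetic world to disk in the pipeline's input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sc = build_scenario(cfg)
    paths = {
        "vcf": outdir / "panel.vcf",
        "counts": outdir / "counts.tsv",
        "peaks": outdir / f"peaks_{cfg.mark}.bed",
        "interactions": outdir / "interactions.bedpe",
        "genes": outdir / "genes.tsv",
        "tags": outdir / "tags.tsv",
        "go": outdir / "go.tsv",
        "affinity": outdir / "affinity.tsv",
        "peak_map": outdir / "peak_map.tsv",
        "peak_traits": outdir / "peak_traits.tsv",
        "expr_traits": outdir / "expr_traits.tsv",
        "truth": outdir / "truth.json",
    }
    write_phased_vcf(sc.panel, paths["vcf"])
    write_allelic_counts(sc.counts, paths["counts"])
    write_bed_peaks(sc.peaks, paths["peaks"])
    write_bedpe_interactions(sc.interactions, paths["interactions"])
    write_gene_models(sc.genes, paths["genes"])
    with open(paths["tags"], "w") as fh:
        fh.write("tag_id\tchrom\tpos\n")
        for b in sc.truth.blocks:
            snp = sc.panel.snp(b.tag_id)
            fh.write(f"{b.tag_id}\t{snp.chrom}\t{snp.pos}\n")
    with open(paths["go"], "w") as fh:
        fh.write("term\tgene_id\n")
        for term in sorted(sc.go_sets):
            for g in sorted(sc.go_sets[term]):
                fh.write(f"{term}\t{g}\n")
    with open(paths["affinity"], "w") as fh:
        fh.write("variant\tmotif\tallele\tscore\n")
        for (variant, motif), score in sorted(sc.affinity.items()):
            fh.write(f"{variant}\t{motif}\talt\t{score:.1f}\n")
    with open(paths["peak_map"], "w") as fh:
        fh.write("trait_id\tchrom\tstart\tend\tmark\n")
        for trait_id in sorted(sc.peaks_by_trait):
            pk = sc.peaks_by_trait[trait_id]
            fh.write(f"{trait_id}\t{pk.interval.chrom}\t{pk.interval.start}\t"
                     f"{pk.interval.end}\t{pk.mark}\n")
    for key, traits in (("peak_traits", sc.peak_traits),
                        ("expr_traits", sc.expr_traits)):
        with open(paths[key], "w") as fh:
            fh.write("trait_id\t" + "\t".join(sc.panel.samples) + "\n")
            for trait_id in sorted(traits):
                row = traits[trait_id]
                fh.write(trait_id + "\t" +
                         "\t".join(f"{row[s]:.6f}" for s in sc.panel.samples)
                         + "\n")
    paths["truth"].write_text(sc.truth.to_json())
    return sc, paths


def simulate_ratio_pairs(n_pairs: int, r_squared: float,
                         ld_abs_r: np.ndarray | float,
                         phased: bool,
                         rng: np.random.Generator
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Oriented (regulatory, transcript) ratio pairs with planted R^2.

    A latent haplotype effect x shifts both ratios off 0.5; the transcript
    adds independent noise sized so that the regression of transcript on
    regulatory ratio has expected coefficient of determination
    ``r_squared``.  Reference/alternative labelling is random: the two SNPs'
    reference alleles share a chromosome with probability (1 + |r|) / 2.
    With ``phased`` the flip is corrected (as phased genotypes allow);
    without, discordantly labelled pairs enter complemented, which erodes
    the correlation as |r| falls.  Returns (reg, tx, distance) arrays with
    distance = 1 - |r|.
    """
    if not 0 < r_squared < 1:
        raise ValueError("r_squared must be in (0, 1)")
    ld = np.broadcast_to(np.asarray(ld_abs_r, dtype=float), (n_pairs,))
    sx = 0.12
    se = sx * np.sqrt((1 - r_squared) / r_squared)
    x = rng.normal(0, sx, n_pairs)
    e = rng.normal(0, se, n_pairs)
    reg = np.clip(0.5 - x, 0.001, 0.999)
    tx_frame = np.clip(0.5 - x - e, 0.001, 0.999)  # reg-reference frame
    same_label = rng.random(n_pairs) < (1 + ld) / 2
    if phased:
        tx = tx_frame
    else:
        tx = np.where(same_label, tx_frame, 1 - tx_frame)
    return reg, tx, 1 - ld
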