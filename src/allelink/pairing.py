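"""Pairing of regulatory and transcript allelic imbalance across chromatin loops.

A GWAS tag SNP is expanded to its LD proxies; proxies falling inside a
histone ChIP-seq peak are candidate cis-regulatory variants.  Peaks are
mapped to target genes through chromatin interactions (one anchor overlaps
the peak, the other the gene body or its promoter window), and heterozygous
SNPs inside the gene's transcript provide the allele-specific expression
readout.

Because reference/alternative labels come from the reference genome, the
two SNPs of a pair are in an arbitrary relative orientation once they fall
out of LD.  Phased genotypes fix this: in each doubly heterozygous sample
the transcript ratio is flipped when the two alternative alleles reside on
different chromosomes, putting both ratios in the frame of the chromosome
that carries the regulatory SNP's reference allele.  Activating marks
(H3K27ac, H3K36me3, H3K4me1, H3K4me3) must then show the major regulatory
allele and the major transcript allele on the same chromosome; the
repressive mark H3K27me3 on opposite chromosomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genomic_io import (AllelicDepth, GeneModel, HaplotypePanel, Interaction,
                         Peak, PhasedGenotype, Snp)
from .haplotype_ld import LdStat, pearson_r
from .imbalance import ImbalanceConfig, MetaResult, reference_ratio, test_site

logger = logging.getLogger(__name__)

#: Regulatory polarity of each supported histone mark.
MARK_POLARITY: dict[str, str] = {
    "H3K27ac": "activating",
    "H3K36me3": "activating",
    "H3K4me1": "activating",
    "H3K4me3": "activating",
    "H3K27me3": "repressive",
}

TRUE_PAIR = "true_pair"
CONTROL_PAIR = "control_pair"
UNTESTABLE = "untestable"


class NoMajorAlleleError(ValueError):
    """A ratio of exactly 0.5 carries no major-allele direction."""


@dataclass(frozen=True)
class OrientedObservation:
    """Per-sample oriented ratio pair for one candidate pairing."""

    sample: str
    reg_ratio: float        # reference-allele fraction at the regulatory SNP
    tx_ratio: float         # transcript fraction flipped into the reg-ref frame
    flipped: bool


@dataclass(frozen=True)
class AllelicPair:
    tag_snp: str
    reg_snp: str
    reg_mark: str
    tx_snp: str
    gene_id: str
    interaction_sources: tuple[str, ...]
    flipped: bool
    reg_result: MetaResult | None
    tx_result: MetaResult | None
    direction_ok: bool
    label: str
    observations: tuple[OrientedObservation, ...] = ()
    ld: LdStat | None = None

    @property
    def mean_reg_ratio(self) -> float:
        return float(np.mean([o.reg_ratio for o in self.observations]))

    @property
    def mean_tx_ratio(self) -> float:
        return float(np.mean([o.tx_ratio for o in self.observations]))


def map_peak_to_genes(peak: Peak, interactions: Sequence[Interaction],
                      genes: Sequence[GeneModel],
                      promoter_windows: Mapping[str, "object"] | None = None,
                      ) -> list[tuple[str, tuple[str, ...]]]:
    """Target genes of a peak through chromatin interactions.

    A gene is a target iff some interaction has one anchor overlapping the
    peak and the other anchor overlapping the gene body or its promoter
    window; the contributing dataset labels are collected per gene.
    """
    from .features import promoter_window

    hits: dict[str, set[str]] = {}
    for gene in genes:
        if gene.interval.chrom != peak.interval.chrom:
            continue
        promo = (promoter_windows[gene.gene_id] if promoter_windows
                 else promoter_window(gene))
        for ia in interactions:
            for peak_anchor, gene_anchor in ((ia.anchor1, ia.anchor2),
                                             (ia.anchor2, ia.anchor1)):
                if peak_anchor.overlaps(peak.interval) and (
                        gene_anchor.overlaps(gene.interval)
                        or gene_anchor.overlaps(promo)):
                    hits.setdefault(gene.gene_id, set()).add(ia.source)
                    break
    return [(g, tuple(sorted(srcs))) for g, srcs in sorted(hits.items())]


def is_flipped(reg_gt: PhasedGenotype, tx_gt: PhasedGenotype) -> bool:
    """Whether the two alternative alleles lie on different chromosomes."""
    if not reg_gt.is_het or not tx_gt.is_het:
        raise ValueError("flipping requires both genotypes heterozygous")
    if reg_gt.sample != tx_gt.sample:
        raise ValueError("flipping is defined within one sample")
    return reg_gt.hap1_allele != tx_gt.hap1_allele


def orient_ratio(ratio: float, flipped: bool) -> float:
    """Flip a reference-allele ratio into the partner SNP's frame."""
    if not 0.0 <= ratio <= 1.0:
        raise ValueError(f"ratio {ratio} outside [0, 1]")
    return 1.0 - ratio if flipped else ratio


def direction_match(reg_ratio: float, tx_ratio: float, polarity: str) -> bool:
    """Major-allele direction matching between oriented ratios.

    Activating marks require the major regulatory and transcript alleles on
    the same chromosome (ratios on the same side of 0.5); the repressive
    mark requires opposite sides.  A ratio of exactly 0.5 has no major
    allele and raises :class:`NoMajorAlleleError`.
    """
    if reg_ratio == 0.5 or tx_ratio == 0.5:
        raise NoMajorAlleleError("ratio exactly 0.5: no major allele")
    if polarity not in ("activating", "repressive"):
        raise ValueError(f"unknown polarity {polarity!r}")
    same_side = (reg_ratio > 0.5) == (tx_ratio > 0.5)
    return same_side if polarity == "activating" else not same_side


def _index_counts(counts: Iterable[AllelicDepth]) -> dict[tuple[str, str], list[AllelicDepth]]:
    idx: dict[tuple[str, str], list[AllelicDepth]] = {}
    for ad in counts:
        idx.setdefault((ad.snp.id, ad.assay), []).append(ad)
    return idx


def _oriented_observations(reg: Snp, tx: Snp, panel: HaplotypePanel,
                           reg_counts: Sequence[AllelicDepth],
                           tx_counts: Sequence[AllelicDepth],
                           cfg: ImbalanceConfig,
                           phased: bool = True) -> list[OrientedObservation]:
    """Per-sample (reg, tx) oriented ratio pairs over doubly het samples.

    Uses study-averaged, filter-passing counts on both sides; with
    ``phased=False`` the flip is skipped (reference orientation throughout),
    which models pairing without phase information.
    """
    from .imbalance import _averaged_by_sample

    reg_by = _averaged_by_sample(reg_counts)
    tx_by = _averaged_by_sample(tx_counts)
    het_both = set(panel.het_samples(reg.id)) & set(panel.het_samples(tx.id))
    out = []
    for sample in sorted(het_both & set(reg_by) & set(tx_by)):
        rad, tad = reg_by[sample], tx_by[sample]
        if rad.total == 0 or tad.total == 0:
            continue
        from .imbalance import passes_site_filter
        if not (passes_site_filter(rad, cfg) and passes_site_filter(tad, cfg)):
            continue
        flip = is_flipped(panel.genotype(reg.id, sample),
                          panel.genotype(tx.id, sample)) if phased else False
        out.append(OrientedObservation(
            sample,
            reference_ratio(rad),
            orient_ratio(reference_ratio(tad), flip),
            flip,
        ))
    return out


def build_pairs(tags: Sequence[str],
                ld_expansion: Mapping[str, set[str]],
                peaks: Sequence[Peak],
                interactions: Sequence[Interaction],
                genes: Sequence[GeneModel],
                panel: HaplotypePanel,
                counts: Sequence[AllelicDepth],
                cfg: ImbalanceConfig = ImbalanceConfig(),
                gene_linker: Mapping[str, set[str]] | None = None,
                phased: bool = True,
                with_ld: bool = True) -> list[AllelicPair]:
    """Construct and label all candidate allele-specific pairs.

    For each tag SNP: LD proxies inside peaks -> linked genes -> transcript
    SNPs; every (regulatory SNP, mark, gene, transcript SNP) combination is
    one candidate pair.  Labels partition the candidates:

    * ``true_pair`` — both sites imbalanced (Fisher-combined P below the
      threshold) and the oriented major alleles match the mark's polarity;
    * ``control_pair`` — testable but failing imbalance or direction;
    * ``untestable`` — no sample is doubly heterozygous with both sites
      passing the depth/ratio filters.

    ``gene_linker`` substitutes a direct snp -> genes mapping (e.g. from
    significant eQTL-gene pairs) for the chromatin-interaction mapping.
    """
    count_idx = _index_counts(counts)
    gene_by_id = {g.gene_id: g for g in genes}
    # transcript SNPs per gene: any panel SNP inside the gene body
    tx_snps_by_gene: dict[str, list[Snp]] = {g.gene_id: [] for g in genes}
    for snp in panel.snps:
        for g in genes:
            if g.interval.contains_position(snp.chrom, snp.pos):
                tx_snps_by_gene[g.gene_id].append(snp)

    pairs: list[AllelicPair] = []
    meta_cache: dict[tuple[str, str], MetaResult | None] = {}

    def cached_test(snp: Snp, assay: str) -> MetaResult | None:
        key = (snp.id, assay)
        if key not in meta_cache:
            meta_cache[key] = test_site(snp, assay, panel,
                                        count_idx.get(key, []), cfg)
        return meta_cache[key]

    tags_paired: set[str] = set()
    genes_paired: set[str] = set()
    for tag in tags:
        proxies = ld_expansion.get(tag, {tag})
        for snp_id in sorted(proxies):
            if not panel.has_snp(snp_id):
                continue  # SNPs without phased genotype are excluded
            reg = panel.snp(snp_id)
            for peak in peaks:
                if not peak.interval.contains_position(reg.chrom, reg.pos):
                    continue
                mark = peak.mark
                if gene_linker is not None:
                    linked = [(g, ("eqtl",)) for g in sorted(
                        gene_linker.get(reg.id, set())) if g in gene_by_id]
                else:
                    linked = map_peak_to_genes(peak, interactions, genes)
                for gene_id, sources in linked:
                    for tx in tx_snps_by_gene[gene_id]:
                        if tx.id == reg.id:
                            continue
                        pair = _label_pair(tag, reg, mark, tx, gene_id, sources,
                                           panel, count_idx, cfg, phased, with_ld)
                        pairs.append(pair)
                        if pair.label == TRUE_PAIR:
                            tags_paired.add(tag)
                            genes_paired.add(gene_id)

    logger.info("build_pairs: %d tags in, %d tags paired, %d genes paired, "
                "%d candidate pairs", len(tags), len(tags_paired),
                len(genes_paired), len(pairs))
    # keep one record per (reg, mark, gene, tx, tag): multiple peaks may repeat it
    seen: dict[tuple, AllelicPair] = {}
    for p in pairs:
        seen.setdefault((p.tag_snp, p.reg_snp, p.reg_mark, p.gene_id, p.tx_snp), p)
    return list(seen.values())


def _label_pair(tag: str, reg: Snp, mark: str, tx: Snp, gene_id: str,
                sources: tuple[str, ...], panel: HaplotypePanel,
                count_idx: Mapping[tuple[str, str], list[AllelicDepth]],
                cfg: ImbalanceConfig, phased: bool,
                with_ld: bool) -> AllelicPair:
    reg_counts = count_idx.get((reg.id, mark), [])
    tx_counts = count_idx.get((tx.id, "RNA"), [])
    obs = _oriented_observations(reg, tx, panel, reg_counts, tx_counts,
                                 cfg, phased)
    ld = pearson_r(panel, reg.id, tx.id) if with_ld else None
    if not obs:
        return AllelicPair(tag, reg.id, mark, tx.id, gene_id, sources, False,
                           None, None, False, UNTESTABLE, (), ld)
    reg_result = test_site(reg, mark, panel, reg_counts, cfg)
    tx_result = test_site(tx, "RNA", panel, tx_counts, cfg)
    mean_reg = float(np.mean([o.reg_ratio for o in obs]))
    mean_tx = float(np.mean([o.tx_ratio for o in obs]))
    try:
        direction_ok = direction_match(mean_reg, mean_tx, MARK_POLARITY[mark])
    except NoMajorAlleleError:
        logger.debug("pair %s-%s: oriented ratio exactly 0.5, direction excluded",
                     reg.id, tx.id)
        direction_ok = False
    flipped = sum(o.flipped for o in obs) * 2 > len(obs)
    both_imbalanced = (reg_result is not None and reg_result.is_imbalanced
                       and tx_result is not None and tx_result.is_imbalanced)
    label = TRUE_PAIR if (both_imbalanced and direction_ok) else CONTROL_PAIR
    return AllelicPair(tag, reg.id, mark, tx.id, gene_id, sources, flipped,
                       reg_result, tx_result, direction_ok, label,
                       tuple(obs), ld)
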