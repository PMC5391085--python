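"""QTL-based mapping arm: hQTL and eQTL linear regression on genotype dosage.

The comparator to allelic mapping: per-sample peak intensities (hQTL) or
gene expression levels (eQTL) are regressed on the additive genotype dosage
(0/1/2 alternative alleles); significant hQTLs are linked to genes through
chromatin interactions, and a pair is kept when the linked gene's eQTL is
also significant and the two effect sizes agree with the mark's polarity
(same sign for activating marks, opposite for the repressive mark).
Unadjusted P < 0.05 thresholds on both sides, as in plain QTL screens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .genomic_io import GeneModel, Interaction, Peak, PhasedGenotype
from .pairing import MARK_POLARITY, map_peak_to_genes

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QtlResult:
    snp: str
    trait_id: str
    beta: float
    p_value: float


@dataclass(frozen=True)
class QtlPair:
    snp: str
    peak_trait: str
    gene_id: str
    beta_h: float
    beta_e: float


def genotype_dosage(gt: PhasedGenotype) -> int:
    """Additive coding: number of alternative alleles (0, 1 or 2)."""
    return gt.dosage


def fit_qtl(dosages: Sequence[int], traits: Sequence[float],
            snp: str = "", trait_id: str = "") -> QtlResult:
    """Simple OLS of trait on dosage with a two-sided t-test on the slope."""
    d = np.asarray(dosages, dtype=float)
    t = np.asarray(traits, dtype=float)
    if len(d) < 3:
        raise ValueError("need at least 3 samples for a QTL fit")
    if np.ptp(d) == 0:
        raise ValueError(f"monomorphic dosage for {snp or 'SNP'}: fit undefined")
    res = stats.linregress(d, t)
    p = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    return QtlResult(snp, trait_id, float(res.slope), p)


def map_qtls(panel, trait_matrix: Mapping[str, Mapping[str, float]],
             snp_trait_links: Mapping[str, Sequence[str]]) -> list[QtlResult]:
    """Fit one QTL regression per (snp, trait) link.

    ``trait_matrix`` maps trait_id -> {sample: value}; monomorphic SNPs are
    skipped with a log message.
    """
    results = []
    for snp_id, trait_ids in snp_trait_links.items():
        if not panel.has_snp(snp_id):
            continue
        dosages = [panel.genotype(snp_id, s).dosage for s in panel.samples]
        if max(dosages) == min(dosages):
            logger.debug("map_qtls: %s monomorphic, skipped", snp_id)
            continue
        for trait_id in trait_ids:
            values = trait_matrix[trait_id]
            pairs = [(d, values[s]) for d, s in zip(dosages, panel.samples)
                     if s in values]
            if len(pairs) < 3:
                continue
            results.append(fit_qtl([p[0] for p in pairs], [p[1] for p in pairs],
                                   snp_id, trait_id))
    return results


def hqtl_eqtl_pairs(hqtl_results: Sequence[QtlResult],
                    eqtl_results: Sequence[QtlResult],
                    interactions: Sequence[Interaction],
                    peaks_by_trait: Mapping[str, Peak],
                    genes: Sequence[GeneModel],
                    alpha: float = 0.05,
                    mark: str = "H3K27ac") -> list[QtlPair]:
    """Pair significant hQTLs with significant eQTLs of interaction-linked genes.

    A pair is kept iff hQTL P < alpha, the gene eQTL (same SNP) P < alpha,
    and the effect signs agree with the mark's polarity.
    """
    polarity = MARK_POLARITY[mark]
    eqtl_idx = {(r.snp, r.trait_id): r for r in eqtl_results}
    gene_link_cache: dict[str, list[str]] = {}
    out = []
    for h in hqtl_results:
        if h.p_value >= alpha:
            continue
        peak = peaks_by_trait.get(h.trait_id)
        if peak is None:
            continue
        if h.trait_id not in gene_link_cache:
            gene_link_cache[h.trait_id] = [
                g for g, _src in map_peak_to_genes(peak, interactions, genes)]
        for gene_id in gene_link_cache[h.trait_id]:
            e = eqtl_idx.get((h.snp, gene_id))
            if e is None or e.p_value >= alpha:
                continue
            same_sign = np.sign(h.beta) == np.sign(e.beta)
            if (polarity == "activating") == bool(same_sign):
                out.append(QtlPair(h.snp, h.trait_id, gene_id, h.beta, e.beta))
    return out


@dataclass(frozen=True)
class SensitivityReport:
    n_allelic: int
    n_qtl: int
    n_overlap: int


def sensitivity_report(allelic_detected: set[str], qtl_detected: set[str],
                       common_start_set: set[str]) -> SensitivityReport:
    """Tag-SNP detection counts per arm, restricted to a common candidate set."""
    a = allelic_detected & common_start_set
    q = qtl_detected & common_start_set
    return SensitivityReport(len(a), len(q), len(a & q))
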