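"""Allelic-imbalance testing at heterozygous sites.

The unit of evidence is the pair of reference/alternative read depths at a
heterozygous SNP in one sample and one assay.  Sites are kept when total
depth exceeds 8 reads and the reference-allele ratio lies in [0.15, 0.85]
(extreme ratios are typically mapping artefacts rather than cis effects).
Each surviving site is tested with an exact two-sided binomial test against
a balanced null (p = 0.5); when a locus is observed in several samples the
per-sample P values are combined with Fisher's method and the chi-square
combined P is thresholded at 0.05.

When the same sample was assayed by more than one study, depths are averaged
across studies (component-wise, rounded half-up to keep integer counts)
before filtering and testing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .genomic_io import AllelicDepth, HaplotypePanel, Snp

logger = logging.getLogger(__name__)

_TINY_P = float(np.finfo(float).tiny)


@dataclass(frozen=True)
class ImbalanceConfig:
    """Thresholds of the site filter and the meta-analysis."""

    min_total_depth_exclusive: int = 8
    ratio_low: float = 0.15
    ratio_high: float = 0.85
    per_sample_alpha: float = 0.05
    meta_alpha: float = 0.05
    null_p: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.ratio_low < self.ratio_high <= 1):
            raise ValueError("require 0 <= ratio_low < ratio_high <= 1")
        if self.min_total_depth_exclusive < 0:
            raise ValueError("depth threshold must be non-negative")


@dataclass(frozen=True)
class SiteTest:
    """Per-sample binomial test of one site."""

    snp: Snp
    assay: str
    sample: str
    ref_depth: int
    alt_depth: int
    p_value: float

    @property
    def ratio(self) -> float:
        return self.ref_depth / (self.ref_depth + self.alt_depth)


@dataclass(frozen=True)
class MetaResult:
    """Fisher-combined imbalance result for one SNP in one assay."""

    snp: Snp
    assay: str
    per_sample_tests: tuple[SiteTest, ...]
    chi_sq: float
    dof: int
    combined_p: float
    mean_ratio: float
    is_imbalanced: bool


def reference_ratio(ad: AllelicDepth) -> float:
    """Reference-allele read fraction, ref / (ref + alt)."""
    if ad.total == 0:
        raise ValueError(f"undefined ratio at {ad.snp.id}/{ad.sample}: zero depth")
    return ad.ref_depth / ad.total


def passes_site_filter(ad: AllelicDepth, cfg: ImbalanceConfig = ImbalanceConfig()) -> bool:
    """Depth and ratio filter: total > 8 and ratio in [0.15, 0.85] (inclusive)."""
    if ad.total <= cfg.min_total_depth_exclusive:
        return False
    ratio = reference_ratio(ad)
    if ratio in (cfg.ratio_low, cfg.ratio_high):
        logger.debug("site %s/%s at ratio boundary %.3f", ad.snp.id, ad.sample, ratio)
    return cfg.ratio_low <= ratio <= cfg.ratio_high


def average_across_studies(ads: Sequence[AllelicDepth]) -> AllelicDepth:
    """Average depths component-wise over studies for one snp/sample/assay.

    Rounds half-up to integers (the binomial test needs integer counts).
    A single study is returned unchanged.
    """
    if not ads:
        raise ValueError("average_across_studies: empty input")
    keys = {(a.snp.id, a.sample, a.assay) for a in ads}
    if len(keys) > 1:
        raise ValueError(f"mixed snp/sample/assay in study averaging: {keys}")
    if len(ads) == 1:
        return ads[0]
    n = len(ads)
    ref = math.floor(sum(a.ref_depth for a in ads) / n + 0.5)
    alt = math.floor(sum(a.alt_depth for a in ads) / n + 0.5)
    first = ads[0]
    return AllelicDepth(first.snp, first.sample, first.assay,
                        "+".join(sorted(a.study_id for a in ads)), ref, alt)


def binomial_two_sided(k: int, n: int, null_p: float = 0.5) -> float:
    """Exact two-sided binomial P: min(1, 2 * min(P(X<=k), P(X>=k))).

    For the symmetric null p = 0.5 this equals the minimum-likelihood
    two-sided test; it is symmetric in k <-> n-k.
    """
    if not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if n < 1:
        raise ValueError("n must be >= 1")
    lower = stats.binom.cdf(k, n, null_p)
    upper = stats.binom.sf(k - 1, n, null_p)
    return float(min(1.0, 2.0 * min(lower, upper)))


def fisher_combine(ps: Sequence[float]) -> tuple[float, int, float]:
    """Fisher's method: chi_sq = -2 * sum(ln p_i), dof = 2k, upper-tail P."""
    if not len(ps):
        raise ValueError("fisher_combine: empty p-value list")
    ps = np.asarray(ps, dtype=float)
    if np.any(ps > 1) or np.any(ps < 0):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(ps == 0):
        logger.warning("fisher_combine: clamping %d zero p-values", int((ps == 0).sum()))
        ps = np.maximum(ps, _TINY_P)
    chi_sq = float(-2.0 * np.log(ps).sum())
    dof = 2 * len(ps)
    combined_p = float(stats.chi2.sf(chi_sq, dof))
    return chi_sq, dof, combined_p


def benjamini_hochberg(ps: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values, for optional FDR control over meta results.

    The screening design thresholds raw P values by default; this helper
    lets callers layer FDR control over a set of combined P values.
    """
    return stats.false_discovery_control(np.asarray(ps, dtype=float))


def _averaged_by_sample(counts: Iterable[AllelicDepth]) -> dict[str, AllelicDepth]:
    by_sample: dict[str, list[AllelicDepth]] = {}
    for ad in counts:
        by_sample.setdefault(ad.sample, []).append(ad)
    return {s: average_across_studies(ads) for s, ads in by_sample.items()}


def test_site(snp: Snp, assay: str, panel: HaplotypePanel,
              counts: Iterable[AllelicDepth],
              cfg: ImbalanceConfig = ImbalanceConfig()) -> MetaResult | None:
    """Meta-analytic imbalance test of one SNP in one assay.

    Restricts counts to samples heterozygous in the panel, averages across
    studies, applies the depth/ratio filter, runs per-sample binomial tests
    and Fisher-combines them.  Returns None when no sample survives the
    filters (the site is untestable).
    """
    het = set(panel.het_samples(snp.id)) if panel.has_snp(snp.id) else set()
    relevant = [ad for ad in counts
                if ad.snp.id == snp.id and ad.assay == assay and ad.sample in het]
    averaged = _averaged_by_sample(relevant)
    tests = []
    for sample in sorted(averaged):
        ad = averaged[sample]
        if ad.total == 0 or not passes_site_filter(ad, cfg):
            continue
        p = binomial_two_sided(ad.ref_depth, ad.total, cfg.null_p)
        tests.append(SiteTest(snp, assay, sample, ad.ref_depth, ad.alt_depth, p))
    if not tests:
        return None
    chi_sq, dof, combined_p = fisher_combine([t.p_value for t in tests])
    mean_ratio = float(np.mean([t.ratio for t in tests]))
    return MetaResult(snp, assay, tuple(tests), chi_sq, dof, combined_p,
                      mean_ratio, combined_p < cfg.meta_alpha)
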