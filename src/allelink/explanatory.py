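"""Explanatory power of regulatory imbalance for allele-specific expression.

Transcript allele ratios are regressed on their paired cis-regulatory
allele ratios by ordinary least squares; the coefficient of determination
R^2 measures how much of the expression imbalance the regulatory imbalance
explains.  Plotting the average R^2 for all pairs within a given genetic
distance (1 - |r|) between the two SNPs shows whether the association
survives outside LD — with phasing it should, without phasing it decays.

Two controls accompany the curve: replacing chromatin interactions with
significant eQTL-gene links, and randomly permuting the interactome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .genomic_io import Interaction
from .pairing import AllelicPair

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegressionFit:
    n_pairs: int
    slope: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class DistanceCurve:
    mark: str
    grid: tuple[float, ...]
    mean_r2_at: tuple[float, ...]  # NaN where fewer than 3 pairs
    n_pairs_at: tuple[int, ...]


DEFAULT_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 10))


def fit_ratio_regression(points: Sequence[tuple[float, float]]) -> RegressionFit:
    """OLS of transcript ratio on regulatory ratio; reports R^2."""
    if len(points) < 3:
        raise ValueError("need at least 3 ratio pairs for a regression")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("regulatory ratios are constant: fit undefined")
    res = stats.linregress(x, y)
    return RegressionFit(len(points), float(res.slope), float(res.intercept),
                         float(res.rvalue ** 2))


def pair_ratio_points(pairs: Sequence[AllelicPair],
                      per_pair_average: bool = False) -> list[tuple[float, float]]:
    """Pooled per-sample oriented (reg, tx) ratio observations.

    With ``per_pair_average`` each pair contributes one averaged point
    instead of one point per sample.
    """
    points = []
    for p in pairs:
        if not p.observations:
            continue
        if per_pair_average:
            points.append((p.mean_reg_ratio, p.mean_tx_ratio))
        else:
            points.extend((o.reg_ratio, o.tx_ratio) for o in p.observations)
    return points


def distance_curve(pairs: Sequence[AllelicPair], mark: str,
                   grid: Sequence[float] = DEFAULT_GRID,
                   per_pair_average: bool = False) -> DistanceCurve:
    """Cumulative R^2 over pairs within each genetic-distance threshold."""
    grid = tuple(grid)
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("distance grid must be strictly increasing")
    usable = [p for p in pairs
              if p.reg_mark == mark and p.observations
              and p.ld is not None and p.ld.defined]
    r2s, ns = [], []
    for d in grid:
        within = [p for p in usable if p.ld.distance <= d]
        points = pair_ratio_points(within, per_pair_average)
        if len(points) < 3:
            r2s.append(float("nan"))
            ns.append(len(points))
            continue
        try:
            fit = fit_ratio_regression(points)
            r2s.append(fit.r_squared)
        except ValueError:
            r2s.append(float("nan"))
        ns.append(len(points))
    return DistanceCurve(mark, grid, tuple(r2s), tuple(ns))


def permute_interactions(interactions: Sequence[Interaction],
                         seed: int) -> list[Interaction]:
    """Randomly rewire anchor2 among same-chromosome interactions.

    Preserves the interaction count and the per-chromosome multisets of
    anchor1 and anchor2 exactly; deterministic under the seed.
    """
    if len(interactions) < 2:
        raise ValueError("need at least 2 interactions to permute")
    rng = np.random.default_rng(seed)
    by_chrom: dict[str, list[int]] = {}
    for i, ia in enumerate(interactions):
        by_chrom.setdefault(ia.anchor1.chrom, []).append(i)
    out: list[Interaction | None] = [None] * len(interactions)
    for chrom, idxs in by_chrom.items():
        perm = rng.permutation(len(idxs))
        for slot, src in zip(idxs, (idxs[k] for k in perm)):
            out[slot] = Interaction(interactions[slot].anchor1,
                                    interactions[src].anchor2,
                                    interactions[slot].source)
    return out  # type: ignore[return-value]


def read_eqtl_table(path) -> dict[str, set[str]]:
    """Read snp_id -> gene_id significant eQTL links (TSV with header)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"snp_id", "gene_id"}.issubset(df.columns):
        raise ValueError(f"{path}: eQTL table needs snp_id and gene_id columns")
    links: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        links.setdefault(row.snp_id, set()).add(row.gene_id)
    return links


def eqtl_pairing_alternative(tags, ld_expansion, peaks, eqtl_links: Mapping[str, set[str]],
                             genes, panel, counts, cfg=None, **kwargs):
    """Re-run pairing with eQTL snp->gene links replacing interactions."""
    from .imbalance import ImbalanceConfig
    from .pairing import build_pairs

    return build_pairs(tags, ld_expansion, peaks, [], genes, panel, counts,
                       cfg or ImbalanceConfig(),
                       gene_linker=dict(eqtl_links), **kwargs)
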