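"""Per-pair feature construction for the Random Forest classifier.

Each candidate variant-gene pair is described by binary epigenomic overlap
bits (does a ChIP-seq track cover the distal variant; does it cover at
least half of the target gene's promoter), binary GO-membership bits for
the gene, the unsigned bp distance from the variant to the gene's TSS, and
precomputed transcription-factor binding-affinity scores for the variant.
The promoter is 1.5 kb upstream to 0.5 kb downstream of the TSS,
strand-aware and clamped at the chromosome start.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_io import GeneModel, GenomicInterval, Peak, Snp
from .pairing import AllelicPair

PROMOTER_UPSTREAM = 1500
PROMOTER_DOWNSTREAM = 500

FEATURE_KINDS = ("distal_peak", "promoter_peak", "go_term", "tss_distance",
                 "tf_affinity")


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    kind: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")


class FeatureMatrix:
    """Pairs x features table; bits for overlap/GO, floats for the rest."""

    def __init__(self, pair_ids: Sequence[str], feature_names: Sequence[str],
                 values: np.ndarray) -> None:
        if len(set(pair_ids)) != len(pair_ids):
            raise ValueError("duplicate pair ids in feature matrix")
        self.frame = pd.DataFrame(np.asarray(values, dtype=float),
                                  index=list(pair_ids),
                                  columns=list(feature_names))

    @property
    def pair_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()


def promoter_window(gene: GeneModel) -> GenomicInterval:
    """Strand-aware promoter: 1.5 kb upstream to 0.5 kb downstream of TSS.

    Always 2000 bp before clamping at position 0.  The TSS base itself is
    the first "downstream" base.
    """
    tss0 = gene.tss - 1  # 0-based coordinate of the TSS base
    if gene.strand == "+":
        start, end = tss0 - PROMOTER_UPSTREAM, tss0 + PROMOTER_DOWNSTREAM
    else:
        start, end = tss0 - PROMOTER_DOWNSTREAM + 1, tss0 + PROMOTER_UPSTREAM + 1
    return GenomicInterval(gene.interval.chrom, max(0, start), end)


def distal_peak_bit(variant: Snp, track: Sequence[Peak]) -> int:
    """1 iff any peak of the track covers the variant position."""
    return int(any(p.interval.contains_position(variant.chrom, variant.pos)
                   for p in track))


def _union_coverage(window: GenomicInterval, track: Sequence[Peak]) -> int:
    """Total bp of the window covered by the union of the track's peaks."""
    segments = sorted(
        (max(p.interval.start, window.start), min(p.interval.end, window.end))
        for p in track
        if p.interval.chrom == window.chrom and p.interval.overlaps(window)
    )
    covered, cur_start, cur_end = 0, None, None
    for s, e in segments:
        if cur_end is None or s > cur_end:
            if cur_end is not None:
                covered += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        covered += cur_end - cur_start
    return covered


def promoter_peak_bit(gene: GeneModel, track: Sequence[Peak]) -> int:
    """1 iff peaks cover at least half of the gene's promoter window."""
    window = promoter_window(gene)
    return int(2 * _union_coverage(window, track) >= window.length)


def go_bit(gene_id: str, term_members: set[str]) -> int:
    return int(gene_id in term_members)


def tss_distance_feature(variant: Snp, gene: GeneModel) -> int:
    """Unsigned bp distance from the variant to the gene's TSS."""
    if variant.chrom != gene.interval.chrom:
        raise ValueError(
            f"{variant.id} and {gene.gene_id} on different chromosomes")
    return abs(variant.pos - gene.tss)


def build_feature_matrix(pairs: Sequence[AllelicPair],
                         specs: Sequence[FeatureSpec],
                         tracks: Mapping[str, Sequence[Peak]],
                         go_sets: Mapping[str, set[str]],
                         affinity: Mapping[tuple[str, str], float],
                         snps: Mapping[str, Snp],
                         genes: Mapping[str, GeneModel]) -> FeatureMatrix:
    """Assemble the pairs x features matrix in stable spec order.

    ``affinity`` maps (variant id, motif source) -> score; absent evidence
    of any kind becomes 0.  Pair ids are "reg_snp|mark|gene|tx_snp".
    """
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names")
    pair_ids = [pair_id(p) for p in pairs]
    rows = np.zeros((len(pairs), len(specs)), dtype=float)
    for i, p in enumerate(pairs):
        variant = snps[p.reg_snp]
        gene = genes[p.gene_id]
        for j, spec in enumerate(specs):
            if spec.kind == "distal_peak":
                rows[i, j] = distal_peak_bit(variant, tracks[spec.source])
            elif spec.kind == "promoter_peak":
                rows[i, j] = promoter_peak_bit(gene, tracks[spec.source])
            elif spec.kind == "go_term":
                rows[i, j] = go_bit(p.gene_id, go_sets.get(spec.source, set()))
            elif spec.kind == "tss_distance":
                rows[i, j] = tss_distance_feature(variant, gene)
            elif spec.kind == "tf_affinity":
                rows[i, j] = affinity.get((p.reg_snp, spec.source), 0.0)
    return FeatureMatrix(pair_ids, names, rows)


def pair_id(p: AllelicPair) -> str:
    return f"{p.reg_snp}|{p.reg_mark}|{p.gene_id}|{p.tx_snp}"
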