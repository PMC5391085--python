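"""Linkage-disequilibrium statistics, haplotype blocks, and LD expansion.

LD is measured on phased haplotypes (2N chromosomes, not genotype dosages)
as the Pearson correlation r of the 0/1 allele indicators; the genetic
distance between two loci is 1 - |r|, which is 0 under perfect LD.

Blocks come from two constructions: confidence-interval ("GAB") blocks are
consumed from a precomputed definition file, while four-gamete ("GAM")
blocks are built here with a greedy left-to-right scan.  Blocks of the same
population are merged by transitive closure, and a tag SNP is expanded to
the variants sharing its merged block in every population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genomic_io import HaplotypePanel, Snp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LdStat:
    snp_a: str
    snp_b: str
    r: float
    defined: bool = True

    @property
    def distance(self) -> float:
        """Genetic distance 1 - |r|."""
        return 1.0 - abs(self.r)


@dataclass(frozen=True)
class LdBlock:
    population: str
    chrom: str
    member_snps: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.member_snps:
            raise ValueError("LdBlock must be non-empty")

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.member_snps


def pearson_r(panel: HaplotypePanel, snp_a: str, snp_b: str) -> LdStat:
    """Pearson correlation of haplotype allele indicators at two SNPs.

    Computed over all 2N haplotypes.  If either SNP is monomorphic the
    correlation is undefined and a flagged stat (r = 0, defined = False)
    is returned.
    """
    a = panel.allele_column(snp_a).astype(float)
    b = panel.allele_column(snp_b).astype(float)
    if a.std() == 0 or b.std() == 0:
        return LdStat(snp_a, snp_b, 0.0, defined=False)
    r = float(np.corrcoef(a, b)[0, 1])
    return LdStat(snp_a, snp_b, max(-1.0, min(1.0, r)))


def _n_gametes(col_a: np.ndarray, col_b: np.ndarray) -> int:
    """Number of distinct gametes (00/01/10/11) observed across haplotypes."""
    return len(set(zip(col_a.tolist(), col_b.tolist())))


def four_gamete_blocks(panel: HaplotypePanel, chrom: str,
                       population: str = "panel") -> list[LdBlock]:
    """Greedy left-to-right four-gamete-rule partition of a chromosome.

    A SNP joins the current block iff every SNP already in the block shows
    at most 3 of the 4 possible gametes with it (no evidence of historical
    recombination); otherwise it starts a new block.  Monomorphic SNPs show
    at most 2 gametes with anything and therefore always join.
    """
    snps = sorted((s for s in panel.snps if s.chrom == chrom), key=lambda s: s.pos)
    blocks: list[list[str]] = []
    current: list[str] = []
    cols = {s.id: panel.allele_column(s.id) for s in snps}
    for snp in snps:
        col = cols[snp.id]
        if current and all(_n_gametes(cols[m], col) <= 3 for m in current):
            current.append(snp.id)
        else:
            if current:
                blocks.append(current)
            current = [snp.id]
    if current:
        blocks.append(current)
    return [LdBlock(population, chrom, tuple(b)) for b in blocks]


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        self.parent[self.find(a)] = self.find(b)


def merge_blocks(gab: Sequence[LdBlock], gam: Sequence[LdBlock]) -> list[LdBlock]:
    """Merge two block partitions by transitive closure of co-membership.

    Two SNPs land in one merged block iff they co-occur in any GAB block or
    any GAM block, closed transitively.  Both inputs must come from the same
    population.
    """
    pops = {b.population for b in list(gab) + list(gam)}
    if len(pops) > 1:
        raise ValueError(f"population mismatch in merge_blocks: {sorted(pops)}")
    if not gab and not gam:
        return []
    population = next(iter(pops))
    uf = _UnionFind()
    order: dict[str, int] = {}
    chrom_of: dict[str, str] = {}
    for block in list(gab) + list(gam):
        for snp_id in block.member_snps:
            order.setdefault(snp_id, len(order))
            chrom_of.setdefault(snp_id, block.chrom)
        first = block.member_snps[0]
        for snp_id in block.member_snps[1:]:
            uf.union(first, snp_id)
    groups: dict[str, list[str]] = {}
    for snp_id in order:
        groups.setdefault(uf.find(snp_id), []).append(snp_id)
    merged = [
        LdBlock(population, chrom_of[members[0]],
                tuple(sorted(members, key=order.__getitem__)))
        for members in groups.values()
    ]
    merged.sort(key=lambda b: order[b.member_snps[0]])
    n_in, n_out = len(gab) + len(gam), len(merged)
    logger.info("merge_blocks: %d input blocks -> %d merged", n_in, n_out)
    return merged


def ld_expand(tag: Snp | str,
              blocks_by_population: Mapping[str, Sequence[LdBlock]]) -> set[str]:
    """Expand a tag SNP to variants sharing its block in every population.

    Returns the intersection over populations of the member set of the block
    containing the tag.  The tag is always included; if the tag is blockless
    in any population the expansion degenerates to {tag}.
    """
    if not blocks_by_population:
        raise ValueError("ld_expand: empty population mapping")
    tag_id = tag.id if isinstance(tag, Snp) else tag
    result: set[str] | None = None
    for population, blocks in blocks_by_population.items():
        members = None
        for block in blocks:
            if tag_id in block:
                members = set(block.member_snps)
                break
        if members is None:
            return {tag_id}
        result = members if result is None else (result & members)
    result = result if result is not None else set()
    result.add(tag_id)
    return result


def read_block_definitions(path: str | Path) -> dict[str, list[LdBlock]]:
    """Read a block definition TSV: population, chrom, block_id, snp_id.

    Returns blocks grouped by population, preserving file order of members.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"population", "chrom", "block_id", "snp_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: block file needs columns {sorted(required)}")
    out: dict[str, list[LdBlock]] = {}
    for (pop, chrom, _bid), grp in df.groupby(
            ["population", "chrom", "block_id"], sort=False):
        out.setdefault(pop, []).append(
            LdBlock(pop, chrom, tuple(grp["snp_id"]))
        )
    return out


def write_block_definitions(blocks_by_population: Mapping[str, Sequence[LdBlock]],
                            path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("population\tchrom\tblock_id\tsnp_id\n")
        for pop, blocks in blocks_by_population.items():
            for i, block in enumerate(blocks):
                for snp_id in block.member_snps:
                    fh.write(f"{pop}\t{block.chrom}\tB{i}\t{snp_id}\n")
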