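"""Core genomic domain types and readers/writers for the standard formats.

Coordinate conventions: VCF positions are 1-based; BED/BEDPE intervals are
0-based half-open.  Conversion between the two happens in exactly one place,
:meth:`GenomicInterval.contains_position`, so every containment query in the
package shares the same off-by-one-free predicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

#: Histone marks with supported allelic-imbalance semantics, plus RNA.
HISTONE_MARKS = ("H3K27ac", "H3K4me1", "H3K4me3", "H3K27me3", "H3K36me3")
ASSAYS = HISTONE_MARKS + ("RNA",)


class FormatError(ValueError):
    """A record in an input file violates its format contract."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a chromosome, 0-based."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains_position(self, chrom: str, pos_1based: int) -> bool:
        """Whether a 1-based position (VCF convention) falls in the interval.

        The single point where 1-based positions meet 0-based half-open
        intervals: pos p is inside iff start <= p-1 < end.
        """
        return chrom == self.chrom and self.start <= pos_1based - 1 < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Snp:
    """A biallelic SNP; pos is 1-based (VCF convention)."""

    id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"SNP {self.id}: ref == alt ({self.ref_allele})")


@dataclass(frozen=True)
class PhasedGenotype:
    """One sample's two phased alleles at one SNP (0 = ref, 1 = alt)."""

    snp: Snp
    sample: str
    hap1_allele: int
    hap2_allele: int

    @property
    def is_het(self) -> bool:
        return self.hap1_allele != self.hap2_allele

    @property
    def dosage(self) -> int:
        return self.hap1_allele + self.hap2_allele


class HaplotypePanel:
    """Phased biallelic genotypes: samples x SNPs x 2 haplotypes.

    Haplotype alleles are stored as a (n_samples, n_snps, 2) uint8 array of
    0/1 values; SNPs are kept in input (positional) order.
    """

    def __init__(
        self,
        samples: Sequence[str],
        snps: Sequence[Snp],
        haplotypes: np.ndarray,
    ) -> None:
        haplotypes = np.asarray(haplotypes, dtype=np.uint8)
        if haplotypes.shape != (len(samples), len(snps), 2):
            raise ValueError(
                f"haplotype array shape {haplotypes.shape} does not match "
                f"({len(samples)}, {len(snps)}, 2)"
            )
        if haplotypes.size and haplotypes.max() > 1:
            raise ValueError("haplotype alleles must be 0/1")
        self.samples = list(samples)
        self.snps = list(snps)
        self.haplotypes = haplotypes
        self._sample_idx = {s: i for i, s in enumerate(self.samples)}
        self._snp_idx = {s.id: i for i, s in enumerate(self.snps)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp(self, snp_id: str) -> Snp:
        try:
            return self.snps[self._snp_idx[snp_id]]
        except KeyError:
            raise KeyError(f"SNP {snp_id!r} not in panel") from None

    def has_snp(self, snp_id: str) -> bool:
        return snp_id in self._snp_idx

    def genotype(self, snp_id: str, sample: str) -> PhasedGenotype:
        i = self._sample_idx[sample]
        try:
            j = self._snp_idx[snp_id]
        except KeyError:
            raise KeyError(f"SNP {snp_id!r} not in panel") from None
        h1, h2 = self.haplotypes[i, j]
        return PhasedGenotype(self.snps[j], sample, int(h1), int(h2))

    def allele_column(self, snp_id: str) -> np.ndarray:
        """All 2N haplotype alleles at a SNP, sample-major order."""
        j = self._snp_idx[snp_id]
        return self.haplotypes[:, j, :].reshape(-1)

    def het_samples(self, snp_id: str) -> list[str]:
        j = self._snp_idx[snp_id]
        mask = self.haplotypes[:, j, 0] != self.haplotypes[:, j, 1]
        return [s for s, m in zip(self.samples, mask) if m]

    def subset_samples(self, samples: Sequence[str]) -> "HaplotypePanel":
        idx = [self._sample_idx[s] for s in samples]
        return HaplotypePanel(list(samples), self.snps, self.haplotypes[idx])


@dataclass(frozen=True)
class AllelicDepth:
    """Reference/alternative read counts for one SNP in one sample+assay."""

    snp: Snp
    sample: str
    assay: str
    study_id: str
    ref_depth: int
    alt_depth: int

    def __post_init__(self) -> None:
        if self.ref_depth < 0 or self.alt_depth < 0:
            raise ValueError(
                f"negative depth at {self.snp.id}/{self.sample}/{self.assay}"
            )
        if self.assay not in ASSAYS:
            raise ValueError(
                f"unknown assay {self.assay!r}; allowed: {', '.join(ASSAYS)}"
            )

    @property
    def total(self) -> int:
        return self.ref_depth + self.alt_depth


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    mark: str

    def __post_init__(self) -> None:
        if self.mark not in HISTONE_MARKS:
            raise ValueError(f"unsupported mark {self.mark!r}")


@dataclass(frozen=True)
class Interaction:
    """An intrachromosomal chromatin contact between two anchors."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    source: str

    def __post_init__(self) -> None:
        if self.anchor1.chrom != self.anchor2.chrom:
            raise ValueError("interactions must be intrachromosomal")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    interval: GenomicInterval
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not (self.interval.start <= self.tss - 1 <= self.interval.end):
            raise ValueError(f"gene {self.gene_id}: TSS outside gene body")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_phased_vcf(path: str | Path, region: GenomicInterval | None = None) -> HaplotypePanel:
    """Load phased biallelic SNPs from a VCF into a HaplotypePanel.

    Multiallelic sites and records that are unphased in any sample are
    skipped (the skip count is logged); the panel keeps positional order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snps: list[Snp] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1 or len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
            n_skipped += 1
            continue
        if region is not None and not region.contains_position(variant.CHROM, variant.POS):
            continue
        gts = variant.genotypes  # [hap1, hap2, phased] per sample
        if any((not g[2]) or g[0] < 0 or g[1] < 0 for g in gts):
            n_skipped += 1
            continue
        vid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        snps.append(Snp(vid, variant.CHROM, variant.POS, variant.REF, variant.ALT[0]))
        columns.append(np.array([[g[0], g[1]] for g in gts], dtype=np.uint8))
    if n_skipped:
        logger.info("read_phased_vcf: skipped %d unphased/multiallelic records", n_skipped)
    if not snps:
        logger.warning("read_phased_vcf: no phased biallelic records in %s", path)
        return HaplotypePanel(samples, [], np.zeros((len(samples), 0, 2), np.uint8))
    haps = np.stack(columns, axis=1)  # (n_samples, n_snps, 2)
    return HaplotypePanel(samples, snps, haps)


def read_bed_peaks(path: str | Path, mark: str) -> list[Peak]:
    """Read BED3+ peak intervals, tagging each with a histone mark."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end <= start")
            peaks.append(Peak(GenomicInterval(chrom, start, end), mark))
    return peaks


def read_bedpe_interactions(path: str | Path, source: str) -> list[Interaction]:
    """Read BEDPE contacts; interchromosomal lines are dropped (logged)."""
    out: list[Interaction] = []
    n_inter = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected >= 6 BEDPE fields")
            c1, s1, e1, c2, s2, e2 = fields[:6]
            if c1 != c2:
                n_inter += 1
                continue
            out.append(
                Interaction(
                    GenomicInterval(c1, int(s1), int(e1)),
                    GenomicInterval(c2, int(s2), int(e2)),
                    source,
                )
            )
    if n_inter:
        logger.info("read_bedpe_interactions: dropped %d interchromosomal lines", n_inter)
    return out


_COUNT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "sample", "assay", "study_id",
    "ref_depth", "alt_depth",
]


def read_allelic_counts(path: str | Path) -> list[AllelicDepth]:
    """Read the tab-separated per-sample allelic depth table."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str, "study_id": str})
    missing = [c for c in _COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        snp = Snp(f"{row.chrom}:{row.pos}", row.chrom, int(row.pos), row.ref, row.alt)
        records.append(
            AllelicDepth(snp, row.sample, row.assay, row.study_id,
                         int(row.ref_depth), int(row.alt_depth))
        )
    return records


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read the gene table: gene_id, chrom, start, end, tss, strand (TSV)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneModel(row.gene_id,
                      GenomicInterval(row.chrom, int(row.start), int(row.end)),
                      int(row.tss), row.strand)
        )
    return genes


# ---------------------------------------------------------------------------
# Writers (round-trip partners of the readers; used by the simulator)
# ---------------------------------------------------------------------------

def write_phased_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(s.chrom for s in panel.snps):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.samples) + "\n")
        for j, snp in enumerate(panel.snps):
            gts = "\t".join(
                f"{panel.haplotypes[i, j, 0]}|{panel.haplotypes[i, j, 1]}"
                for i in range(panel.n_samples)
            )
            fh.write(f"{snp.chrom}\t{snp.pos}\t{snp.id}\t{snp.ref_allele}\t"
                     f"{snp.alt_allele}\t.\tPASS\t.\tGT\t{gts}\n")


def write_bed_peaks(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\n")


def write_bedpe_interactions(interactions: Iterable[Interaction], path: str | Path) -> None:
    with open(path, "w") as fh:
        for x in interactions:
            fh.write("\t".join(map(str, (
                x.anchor1.chrom, x.anchor1.start, x.anchor1.end,
                x.anchor2.chrom, x.anchor2.start, x.anchor2.end,
            ))) + "\n")


def write_allelic_counts(records: Iterable[AllelicDepth], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_COUNT_COLUMNS) + "\n")
        for r in records:
            fh.write("\t".join(map(str, (
                r.snp.chrom, r.snp.pos, r.snp.ref_allele, r.snp.alt_allele,
                r.sample, r.assay, r.study_id, r.ref_depth, r.alt_depth,
            ))) + "\n")


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\ttss\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.interval.chrom}\t{g.interval.start}\t"
                     f"{g.interval.end}\t{g.tss}\t{g.strand}\n")
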