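"""Phase flipping, direction matching, peak-gene mapping, pair labelling."""

import itertools

import numpy as np
import pytest

from allelink.genomic_io import (GeneModel, GenomicInterval, HaplotypePanel,
                                 Interaction, Peak, PhasedGenotype, Snp)
from allelink.pairing import (CONTROL_PAIR, TRUE_PAIR, UNTESTABLE,
                              NoMajorAlleleError, build_pairs,
                              direction_match, is_flipped,
                              map_peak_to_genes, orient_ratio)
from allelink.synthetic import SimConfig, build_scenario

REG = Snp("reg", "chr1", 150, "A", "G")
TX = Snp("tx", "chr1", 5060, "A", "G")


def gt(snp, h1, h2, sample="S1"):
    return PhasedGenotype(snp, sample, h1, h2)


class TestMapPeakToGenes:
    PEAK = Peak(GenomicInterval("chr1", 100, 200), "H3K27ac")
    GENE = GeneModel("g1", GenomicInterval("chr1", 5050, 8000), 5051, "+")

    def test_anchor_overlap_maps_gene(self):
        ia = Interaction(GenomicInterval("chr1", 150, 250),
                         GenomicInterval("chr1", 5000, 5100), "d1")
        out = map_peak_to_genes(self.PEAK, [ia], [self.GENE])
        assert out == [("g1", ("d1",))]

    def test_other_chromosome_unmapped(self):
        ia = Interaction(GenomicInterval("chr2", 150, 250),
                         GenomicInterval("chr2", 5000, 5100), "d1")
        assert map_peak_to_genes(self.PEAK, [ia], [self.GENE]) == []

    def test_multi_source_support(self):
        ias = [Interaction(GenomicInterval("chr1", 150, 250),
                           GenomicInterval("chr1", 5000, 5100), d)
               for d in ("chiapet", "capture_hic")]
        out = map_peak_to_genes(self.PEAK, ias, [self.GENE])
        assert out == [("g1", ("capture_hic", "chiapet"))]

    def test_promoter_anchor_counts(self):
        # anchor upstream of the gene body but inside the promoter window
        ia = Interaction(GenomicInterval("chr1", 150, 250),
                         GenomicInterval("chr1", 3600, 3700), "d1")
        assert map_peak_to_genes(self.PEAK, [ia], [self.GENE]) == [("g1", ("d1",))]


class TestFlipAndOrient:
    @pytest.mark.parametrize("reg,tx,expected", [
        ((0, 1), (0, 1), False),
        ((0, 1), (1, 0), True),
        ((1, 0), (1, 0), False),
        ((1, 0), (0, 1), True),
    ])
    def test_is_flipped(self, reg, tx, expected):
        assert is_flipped(gt(REG, *reg), gt(TX, *tx)) is expected

    def test_homozygous_rejected(self):
        with pytest.raises(ValueError, match="heterozygous"):
            is_flipped(gt(REG, 1, 1), gt(TX, 0, 1))

    def test_orient_basic(self):
        assert orient_ratio(0.8, True) == pytest.approx(0.2)
        assert orient_ratio(0.8, False) == pytest.approx(0.8)

    def test_orient_involution(self):
        for x in np.linspace(0, 1, 11):
            assert orient_ratio(orient_ratio(x, True), True) == pytest.approx(x)
            assert orient_ratio(orient_ratio(x, False), False) == pytest.approx(x)


class TestDirectionMatch:
    @pytest.mark.parametrize("reg,tx,polarity,expected", [
        (0.8, 0.7, "activating", True),
        (0.8, 0.3, "repressive", True),
        (0.8, 0.3, "activating", False),
        (0.2, 0.3, "activating", True),
        (0.2, 0.7, "repressive", True),
    ])
    def test_polarity_rules(self, reg, tx, polarity, expected):
        assert direction_match(reg, tx, polarity) is expected

    def test_no_major_allele(self):
        with pytest.raises(NoMajorAlleleError):
            direction_match(0.5, 0.7, "activating")

    def test_truth_table_oracle(self):
        """Pipeline decisions equal a brute-force chromosome-side evaluator.

        Enumerates all four het-het phase configurations, both polarities
        and a grid of read fractions; the oracle works directly on per-
        haplotype read fractions without the flip/orient machinery.
        """
        grid = [0.1, 0.3, 0.45, 0.55, 0.7, 0.9]
        for (r1, r2), (t1, t2), polarity, reg_f, tx_f in itertools.product(
                [(0, 1), (1, 0)], [(0, 1), (1, 0)],
                ["activating", "repressive"], grid, grid):
            reg_gt, tx_gt = gt(REG, r1, r2), gt(TX, t1, t2)
            # reg_f / tx_f: reference-allele read fractions
            flip = is_flipped(reg_gt, tx_gt)
            decision = direction_match(reg_f, orient_ratio(tx_f, flip),
                                       polarity)
            # oracle: fraction of reads from haplotype 1 at each SNP
            reg_h1 = reg_f if r1 == 0 else 1 - reg_f
            tx_h1 = tx_f if t1 == 0 else 1 - tx_f
            same_hap = (reg_h1 > 0.5) == (tx_h1 > 0.5)
            expected = same_hap if polarity == "activating" else not same_hap
            assert decision is expected, (r1, r2, t1, t2, polarity, reg_f, tx_f)


class TestBuildPairsOnPlantedTruth:
    def test_true_pairs_are_exactly_planted_effects(self, small_scenario,
                                                    small_pairs):
        effect_genes = {b.gene_id for b in small_scenario.truth.effect_blocks()}
        true_genes = {p.gene_id for p in small_pairs if p.label == TRUE_PAIR}
        assert true_genes == effect_genes
        # real-link true pairs carry oriented ratios near 1 - f per block
        f_by_gene = {b.gene_id: b.hap_fraction
                     for b in small_scenario.truth.blocks}
        for p in small_pairs:
            if p.label == TRUE_PAIR and "sim" in p.interaction_sources:
                f = f_by_gene[p.gene_id]
                assert p.mean_reg_ratio == pytest.approx(1 - f, abs=0.12)
                assert p.mean_tx_ratio == pytest.approx(1 - f, abs=0.12)

    def test_balanced_transcript_is_control(self, small_pairs, small_scenario):
        nulls = {b.gene_id for b in small_scenario.truth.blocks if not b.effect}
        for p in small_pairs:
            if p.gene_id in nulls and p.interaction_sources == ("sim",) \
                    and p.label != UNTESTABLE:
                assert p.label == CONTROL_PAIR

    def test_label_partition_is_exhaustive(self, small_pairs):
        assert all(p.label in (TRUE_PAIR, CONTROL_PAIR, UNTESTABLE)
                   for p in small_pairs)

    def test_unmatchable_reg_snp_untestable(self, small_scenario):
        """Removing every ChIP count makes all pairs untestable."""
        inputs = small_scenario.mapping_inputs()
        rna_only = [c for c in inputs.counts if c.assay == "RNA"]
        pairs = build_pairs(inputs.tags, inputs.ld_expansion, inputs.peaks,
                            inputs.interactions, inputs.genes, inputs.panel,
                            rna_only, inputs.imbalance_cfg)
        assert pairs and all(p.label == UNTESTABLE for p in pairs)


class TestPhaseConsistency:
    def test_oriented_ratios_match_haplotype_truth(self):
        """Oriented ratios recovered from counts equal the planted fraction
        regardless of the per-sample phase configuration."""
        cfg = SimConfig(n_samples=40, n_tags=6, ld_decay=0.25,
                        effect_hap_fractions=(0.8,), effect_sample_sd=0.0,
                        chip_depth=400, rna_depth=400, seed=3)
        sc = build_scenario(cfg)
        pairs = sc.mapping_inputs().build()
        f = 0.8
        checked = 0
        for p in pairs:
            # decoy links can join two independently imbalanced blocks;
            # the planted fraction applies to the real links only
            if p.label != TRUE_PAIR or "sim" not in p.interaction_sources:
                continue
            flips = {o.flipped for o in p.observations}
            for o in p.observations:
                assert o.reg_ratio == pytest.approx(1 - f, abs=0.08)
                assert o.tx_ratio == pytest.approx(1 - f, abs=0.08)
            checked += 1
            if len(flips) == 2:
                # mixed phase configurations still give consistent ratios
                checked += 1
        assert checked > 0
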