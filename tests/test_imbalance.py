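"""Binomial imbalance test, site filters, study averaging, Fisher meta."""

import math

import numpy as np
import pytest

from allelink.genomic_io import AllelicDepth, HaplotypePanel, Snp
from allelink.imbalance import (ImbalanceConfig, average_across_studies,
                                binomial_two_sided, fisher_combine,
                                passes_site_filter, reference_ratio)
from allelink.imbalance import test_site as site_meta_test

SNP = Snp("rs9", "chr1", 500, "A", "G")


def ad(ref, alt, sample="S1", assay="H3K27ac", study="st0", snp=SNP):
    return AllelicDepth(snp, sample, assay, study, ref, alt)


class TestRatioAndFilter:
    @pytest.mark.parametrize("ref,alt,expected", [
        (5, 5, 0.5), (9, 3, 0.75), (0, 10, 0.0)])
    def test_reference_ratio(self, ref, alt, expected):
        assert reference_ratio(ad(ref, alt)) == pytest.approx(expected)

    def test_zero_total_undefined(self):
        with pytest.raises(ValueError, match="zero depth"):
            reference_ratio(ad(0, 0))

    @pytest.mark.parametrize("ref,alt,expected", [
        (5, 4, True),     # total 9 > 8, ratio 0.556
        (8, 0, False),    # total exactly 8 fails the strict depth rule
        (20, 2, False),   # ratio 0.909 above 0.85
        (2, 20, False),   # mirror below 0.15
        (3, 17, True),    # ratio exactly 0.15 is inclusive
        (17, 3, True),    # ratio exactly 0.85 is inclusive
    ])
    def test_depth_and_ratio_filter(self, ref, alt, expected):
        assert passes_site_filter(ad(ref, alt)) is expected


class TestStudyAveraging:
    def test_component_wise_mean(self):
        out = average_across_studies([ad(10, 6, study="a"), ad(12, 8, study="b")])
        assert (out.ref_depth, out.alt_depth) == (11, 7)

    def test_single_study_identity(self):
        rec = ad(7, 7)
        assert average_across_studies([rec]) is rec

    def test_half_up_rounding(self):
        out = average_across_studies([ad(3, 3, study="a"), ad(4, 4, study="b")])
        assert (out.ref_depth, out.alt_depth) == (4, 4)

    def test_mixed_keys_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            average_across_studies([ad(1, 1), ad(1, 1, sample="S2")])


class TestBinomialTwoSided:
    def test_balanced_capped_at_one(self):
        assert binomial_two_sided(5, 10) == 1.0

    def test_extreme_tail(self):
        assert binomial_two_sided(0, 9) == pytest.approx(2 / 512, abs=1e-15)

    def test_frozen_tail_sum(self):
        # sum of C(20,k) for k >= 16 is 6196; doubled over 2^20
        assert binomial_two_sided(16, 20) == pytest.approx(2 * 6196 / 2 ** 20,
                                                           abs=1e-12)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            binomial_two_sided(5, 4)
        with pytest.raises(ValueError):
            binomial_two_sided(-1, 4)

    def test_enumeration_oracle_and_symmetry(self):
        """Doubled-tail P equals full outcome enumeration for n <= 12."""
        for n in range(1, 13):
            pmf = [math.comb(n, j) / 2 ** n for j in range(n + 1)]
            for k in range(n + 1):
                lower = sum(pmf[: k + 1])
                upper = sum(pmf[k:])
                expected = min(1.0, 2 * min(lower, upper))
                assert binomial_two_sided(k, n) == pytest.approx(expected,
                                                                 abs=1e-12)
                assert binomial_two_sided(k, n) == pytest.approx(
                    binomial_two_sided(n - k, n), abs=1e-15)


class TestFisherCombine:
    def test_single_p_identity(self):
        for p in (0.01, 0.2, 0.77, 1.0):
            chi, dof, combined = fisher_combine([p])
            assert dof == 2
            assert combined == pytest.approx(p, rel=1e-12)

    def test_all_ones(self):
        chi, dof, combined = fisher_combine([1.0, 1.0])
        assert chi == pytest.approx(0.0) and combined == pytest.approx(1.0)

    def test_df4_closed_form(self):
        chi, dof, combined = fisher_combine([0.05, 0.05])
        x = -4 * math.log(0.05)
        assert chi == pytest.approx(x, rel=1e-12)
        assert dof == 4
        assert combined == pytest.approx((1 + x / 2) * math.exp(-x / 2),
                                         rel=1e-12)
        assert combined == pytest.approx(0.01748, abs=5e-6)

    def test_replication_strengthens(self):
        assert fisher_combine([0.04, 0.04])[2] < 0.04

    def test_zero_p_clamped(self):
        chi, dof, combined = fisher_combine([0.0, 0.5])
        assert math.isfinite(chi) and combined >= 0


def het_panel(samples, snp=SNP):
    """All-heterozygous single-SNP panel (0|1 for everyone)."""
    haps = np.tile(np.array([[0, 1]], dtype=np.uint8), (len(samples), 1, 1))
    return HaplotypePanel(samples, [snp], haps)


class TestTestSite:
    def test_single_sample_equals_binomial(self):
        panel = het_panel(["S1"])
        res = site_meta_test(SNP, "H3K27ac", panel, [ad(16, 4)])
        assert res.combined_p == pytest.approx(binomial_two_sided(16, 20))
        assert res.is_imbalanced

    def test_balanced_samples_not_imbalanced(self):
        panel = het_panel(["S1", "S2"])
        res = site_meta_test(SNP, "H3K27ac", panel,
                        [ad(5, 5, "S1"), ad(5, 5, "S2")])
        assert res.combined_p == pytest.approx(1.0)
        assert not res.is_imbalanced

    def test_homozygous_samples_excluded(self):
        snp = SNP
        haps = np.array([[[0, 1]], [[1, 1]]], dtype=np.uint8)
        panel = HaplotypePanel(["S1", "S2"], [snp], haps)
        res = site_meta_test(snp, "H3K27ac", panel,
                        [ad(16, 4, "S1"), ad(20, 0, "S2")])
        assert [t.sample for t in res.per_sample_tests] == ["S1"]

    def test_untestable_returns_none(self):
        panel = het_panel(["S1"])
        assert site_meta_test(SNP, "H3K27ac", panel, [ad(4, 4)]) is None

    def test_planted_imbalance_power(self, rng):
        """Ratio 0.8 at depth 30 in 5 samples is detected >95% of the time."""
        panel = het_panel([f"S{i}" for i in range(5)])
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            counts = [ad(int(rng.binomial(30, 0.8)), 0, f"S{i}")
                      for i in range(5)]
            counts = [ad(c.ref_depth, 30 - c.ref_depth, c.sample)
                      for c in counts]
            res = site_meta_test(SNP, "H3K27ac", panel, counts)
            if res is not None and res.is_imbalanced:
                hits += 1
        assert hits / n_rep > 0.95


class TestNullCalibration:
    def test_per_sample_rejection_rate_conservative(self, rng):
        """Balanced binomial counts at depth 30: rejection rate <= nominal."""
        n_sites = 10_000
        k = rng.binomial(30, 0.5, size=n_sites)
        keep = (k / 30 >= 0.15) & (k / 30 <= 0.85)
        p_by_k = np.array([binomial_two_sided(j, 30) for j in range(31)])
        p = p_by_k[k[keep]]
        rate = float((p < 0.05).mean())
        mc_se = math.sqrt(0.05 * 0.95 / keep.sum())
        assert rate <= 0.05 + 3 * mc_se


class TestBenjaminiHochberg:
    def test_matches_step_up_definition(self):
        from allelink.imbalance import benjamini_hochberg

        ps = [0.01, 0.04, 0.03, 0.20]
        adj = benjamini_hochberg(ps)
        # step-up: sort, p*(m/rank), cumulative min from the right
        assert adj == pytest.approx([0.04, 0.053333333, 0.053333333, 0.2])
        assert np.all(adj >= np.asarray(ps))
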