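"""R^2 of transcript-on-regulatory regression, distance curve, permutations."""

import numpy as np
import pytest

from allelink.explanatory import (distance_curve, eqtl_pairing_alternative,
                                  fit_ratio_regression, pair_ratio_points,
                                  permute_interactions)
from allelink.pairing import TRUE_PAIR, build_pairs
from allelink.synthetic import simulate_ratio_pairs


class TestFitRatioRegression:
    def test_perfect_fit(self):
        pts = [(x, x) for x in np.linspace(0.1, 0.9, 10)]
        assert fit_ratio_regression(pts).r_squared == pytest.approx(1.0)

    def test_independent_ratios_near_zero(self, rng):
        pts = list(zip(rng.uniform(0.1, 0.9, 10_000),
                       rng.uniform(0.1, 0.9, 10_000)))
        assert fit_ratio_regression(pts).r_squared < 0.01

    def test_r2_equals_squared_pearson(self, rng):
        x = rng.uniform(0, 1, 200)
        y = 0.4 * x + rng.normal(0, 0.1, 200)
        fit = fit_ratio_regression(list(zip(x, y)))
        assert fit.r_squared == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2,
                                              abs=1e-10)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_ratio_regression([(0.1, 0.2)])
        with pytest.raises(ValueError, match="constant"):
            fit_ratio_regression([(0.5, 0.1), (0.5, 0.2), (0.5, 0.3)])

    @pytest.mark.parametrize("planted", [0.2, 0.5, 0.8])
    def test_planted_r2_recovery(self, planted, rng):
        reg, tx, _ = simulate_ratio_pairs(5000, planted, 1.0, True, rng)
        fit = fit_ratio_regression(list(zip(reg, tx)))
        assert fit.r_squared == pytest.approx(planted, abs=0.05)


class TestDistanceCurve:
    def test_phased_flat_unphased_decays(self, rng):
        """With phasing the curve stays near the planted R^2 at every
        distance; without phasing it decays as |r| falls."""
        planted = 0.6
        ld = rng.uniform(0, 1, 4000)
        grids = {}
        for phased in (True, False):
            reg, tx, dist = simulate_ratio_pairs(4000, planted, ld,
                                                 phased,
                                                 np.random.default_rng(7))
            order = np.argsort(dist)
            # cumulative R^2 within growing distance thresholds
            r2s = []
            for thr in (0.2, 0.5, 1.0):
                sel = dist <= thr
                fit = fit_ratio_regression(list(zip(reg[sel], tx[sel])))
                r2s.append(fit.r_squared)
            grids[phased] = r2s
        assert all(abs(r2 - planted) < 0.1 for r2 in grids[True])
        assert grids[False][0] > grids[False][2] + 0.1
        assert grids[True][2] > grids[False][2] + 0.2

    def test_curve_values_valid_on_scenario(self, small_scenario):
        inputs = small_scenario.mapping_inputs()
        pairs = build_pairs(inputs.tags, inputs.ld_expansion, inputs.peaks,
                            inputs.interactions, inputs.genes, inputs.panel,
                            inputs.counts, inputs.imbalance_cfg, with_ld=True)
        curve = distance_curve(pairs, small_scenario.cfg.mark)
        assert curve.grid[0] == 0.0
        finite = [r for r in curve.mean_r2_at if not np.isnan(r)]
        assert finite and all(0 <= r <= 1 for r in finite)

    def test_grid_must_increase(self, small_pairs):
        with pytest.raises(ValueError):
            distance_curve(small_pairs, "H3K27ac", grid=[0.5, 0.5])


class TestPermuteInteractions:
    def test_deterministic_and_conserving(self, small_scenario):
        ias = small_scenario.interactions
        p1 = permute_interactions(ias, seed=5)
        p2 = permute_interactions(ias, seed=5)
        assert [(x.anchor1, x.anchor2) for x in p1] == \
               [(x.anchor1, x.anchor2) for x in p2]
        assert len(p1) == len(ias)
        # anchor multisets preserved per chromosome
        def multiset(items, which):
            return sorted((getattr(x, which).chrom, getattr(x, which).start,
                           getattr(x, which).end) for x in items)
        assert multiset(p1, "anchor1") == multiset(ias, "anchor1")
        assert multiset(p1, "anchor2") == multiset(ias, "anchor2")
        assert all(x.anchor1.chrom == x.anchor2.chrom for x in p1)

    def test_two_interactions_identity_or_swap(self, small_scenario):
        ias = small_scenario.interactions[:2]
        out = permute_interactions(ias, seed=0)
        a2 = {(x.anchor2.start, x.anchor2.end) for x in out}
        assert a2 == {(x.anchor2.start, x.anchor2.end) for x in ias}

    def test_permutation_reduces_r2(self, small_scenario):
        """Random rewiring of the interactome lowers the explanatory power
        of the mapped allele-specific pairs (direction matching keeps some
        power even after randomisation, but less than the real links)."""
        inputs = small_scenario.mapping_inputs()

        def mapped_r2(interactions):
            pairs = build_pairs(inputs.tags, inputs.ld_expansion, inputs.peaks,
                                interactions, inputs.genes, inputs.panel,
                                inputs.counts, inputs.imbalance_cfg)
            pts = pair_ratio_points([p for p in pairs
                                     if p.label == TRUE_PAIR])
            return fit_ratio_regression(pts).r_squared if len(pts) >= 3 else None

        r2_real = mapped_r2(inputs.interactions)
        perm_r2 = [mapped_r2(permute_interactions(inputs.interactions, seed))
                   for seed in range(4)]
        perm_r2 = [r for r in perm_r2 if r is not None]
        assert perm_r2 and float(np.mean(perm_r2)) < r2_real


class TestEqtlAlternative:
    def test_matching_links_reproduce_interaction_pairs(self, small_scenario,
                                                        small_pairs):
        sc = small_scenario
        links = {b.reg_snp_id: {b.gene_id} for b in sc.truth.blocks}
        alt = eqtl_pairing_alternative(sc.tags, sc.ld_expansion, sc.peaks,
                                       links, sc.genes, sc.panel, sc.counts)
        key = lambda p: (p.reg_snp, p.gene_id, p.tx_snp, p.label)
        real_keys = {key(p) for p in small_pairs
                     if p.interaction_sources == ("sim",)}
        alt_keys = {key(p) for p in alt}
        assert real_keys <= alt_keys

    def test_empty_table_zero_pairs(self, small_scenario):
        sc = small_scenario
        alt = eqtl_pairing_alternative(sc.tags, sc.ld_expansion, sc.peaks,
                                       {}, sc.genes, sc.panel, sc.counts)
        assert alt == []

    def test_half_the_links_half_the_pairs(self, small_scenario):
        sc = small_scenario
        blocks = sc.truth.blocks
        full = {b.reg_snp_id: {b.gene_id} for b in blocks}
        half = {b.reg_snp_id: {b.gene_id} for b in blocks[: len(blocks) // 2]}
        n_full = len(eqtl_pairing_alternative(
            sc.tags, sc.ld_expansion, sc.peaks, full, sc.genes, sc.panel,
            sc.counts))
        n_half = len(eqtl_pairing_alternative(
            sc.tags, sc.ld_expansion, sc.peaks, half, sc.genes, sc.panel,
            sc.counts))
        assert n_half == n_full // 2
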