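# allelink

Long-range allele-specific mapping of regulatory variants to their target
genes, with Random Forest rescue of pairs that small sample panels cannot
test directly.

## The problem

Most disease-associated GWAS variants are non-coding and act in *cis*: one
chromosome carries a regulatory allele that shifts enhancer activity and,
through a chromatin loop, the expression of a distal gene. In a sample
heterozygous at both a regulatory SNP (read out by histone ChIP-seq) and a
transcript SNP (read out by RNA-seq), both effects are visible as **allelic
imbalance** — unequal read counts between the two alleles — with the trans
environment perfectly controlled, so even a handful of individuals can
reveal a cis effect that dosage-based QTL mapping would need large cohorts
to detect.

`allelink` implements this mapping end to end:

1. **LD expansion** — GWAS tag SNPs are expanded to candidate causal
   variants sharing a haplotype block (four-gamete-rule blocks built from
   phased genotypes, merged with confidence-interval blocks read from a
   file, intersected across populations).
2. **Imbalance testing** — at each heterozygous SNP with total allelic
   depth > 8 and reference ratio in [0.15, 0.85], an exact binomial test
   against p = 0.5; evidence across samples is combined with Fisher's
   method, χ² = −2 Σ ln pᵢ on 2k df, thresholded at combined P < 0.05.
3. **Pairing** — regulatory SNPs inside ChIP-seq peaks are linked to genes
   through chromatin interactions (BEDPE anchors overlapping peak and gene
   body/promoter). Because ref/alt labels come from the reference genome,
   the transcript ratio is **flipped** (r → 1 − r) in every sample whose
   phased genotypes place the two alternative alleles on different
   chromosomes. Activating marks (H3K27ac, H3K4me1/3, H3K36me3) must show
   the major regulatory and transcript alleles on the same chromosome;
   the repressive mark H3K27me3 on opposite chromosomes.
4. **Explanatory power** — transcript ratios are regressed on paired
   regulatory ratios; mean R² as a function of genetic distance 1 − |r|
   shows that phasing keeps the association flat far outside LD, while
   unphased pairing decays. Controls: eQTL-link substitution and random
   interactome permutation.
5. **QTL comparator** — hQTL and eQTL linear regressions on genotype
   dosage with same-direction filtering, run on the identical candidates.
6. **Predictive rescue** — pairs testable in a panel are labelled true
   (both sides imbalanced, direction matched) or control; a Random Forest
   ensemble (1000 trees, mtry = ⌊√p⌋, 5-fold CV × 2 repetitions = 10
   classifiers) learns their epigenomic features (peak overlap bits,
   promoter half-coverage bits, GO membership, TSS distance, TF binding
   affinity) and votes on the **untestable** pairs — those with no usable
   heterozygote; more than 5 of 10 votes is a positive call. Calls made
   from a small subpanel are validated by re-testing on the full panel.

A first-class synthetic-data module generates complete reference panels
(phased haplotypes with LD structure, binomial allelic counts with planted
haplotype effects, interactomes, gene models, trait matrices, feature
tables) with known ground truth, so every stage is testable without any
external data.

## Worked example

```
$ allelink simulate --samples 30 --tags 10 --seed 42 --out demo/panel
wrote 12 files to demo/panel (90 SNPs, 30 samples)

$ allelink run-all --panel-dir demo/panel --out demo/results --seed 42 --trees 200
INFO allelink.pairing: build_pairs: 10 tags in, 4 tags paired, 4 genes paired, 33 candidate pairs
pipeline complete; stages: ['explanatory', 'pairing', 'prediction', 'qtl']

$ cat demo/results/funnel.tsv
stage        n_snps   n_genes
applicable   8        9
imbalanced   5        5
paired       4        4
```

The funnel counts tag SNPs (and genes) that are applicable (heterozygous
with counts and an interaction), show regulatory imbalance, and survive
long-range pairing. `pairs.tsv` holds one row per candidate pair; for a
recovered planted effect it looks like

```
reg_snp  gene_id  tx_snp  mean_reg_ratio  mean_tx_ratio  reg_p      tx_p       label
b2s1     gene2    b2tx0   0.314           0.313          6.0e-16    8.4e-18    true_pair
```

— the oriented reference-allele fractions agree on both sides of the loop
(≈ 0.31, i.e. the alternative-allele chromosome produces ~69% of both the
H3K27ac and the RNA reads), and both exact binomial/Fisher tests reject a
balanced null. The manifest reports the QTL comparator on the same
candidates (here: 4 tags detected by allelic mapping vs 2 by the
hQTL→eQTL arm at 30 samples) and `prediction.tsv` the ensemble's held-out
AUC and rescue-validation counts.

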