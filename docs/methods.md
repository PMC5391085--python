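# Methods

## Statistical model

**Imbalance test.** At a heterozygous SNP observed with reference depth k
out of n = ref + alt reads, the null of no cis effect is X ~ Binomial(n,
0.5). The two-sided P is the doubled smaller tail, min(1, 2·min(P(X ≤ k),
P(X ≥ k))); for the symmetric p = 0.5 null this equals the
minimum-likelihood two-sided test and is checkable against full outcome
enumeration. Sites enter only with n > 8 (strict) and reference ratio in
the closed interval [0.15, 0.85]; extreme ratios at heterozygotes are
treated as mapping artefacts rather than biology. When the same sample was
assayed by several studies, depths are averaged component-wise across
studies and rounded half-up before testing (the exact test needs integer
counts; rounding direction is a convention and is applied after averaging,
with the filter applied to the averaged record). Evidence across samples
is combined with Fisher's method, χ² = −2 Σ ln pᵢ on 2k degrees of
freedom; a locus is called imbalanced when the combined P < 0.05. No
multiple-testing correction is applied at the site level (raw thresholds
are the operating point of the screening design); Benjamini–Hochberg can
be layered on the output table if desired.

**Phase orientation.** Reference/alternative labels are reference-genome
conventions, so for two SNPs outside LD they say nothing about which
alleles share a chromosome. Phased genotypes do: within each doubly
heterozygous sample, the transcript ratio is flipped (r → 1 − r) when the
two alternative alleles lie on different haplotypes. After the flip, both
members of a pair measure the read fraction of the chromosome carrying
the regulatory SNP's *reference* allele. We anchor the frame to the
regulatory reference allele — a fixed allele identity — rather than to
"haplotype 1", because haplotype numbering is arbitrary per sample;
anchoring to an allele is the only convention under which ratios can be
averaged and compared across samples. Within any one sample the two
conventions differ by a simultaneous complement of both ratios, which
changes neither direction matching nor regression R².

**Direction matching.** Activating marks (H3K27ac, H3K4me1, H3K4me3,
H3K36me3) must show the major regulatory allele and major transcript
allele on the same chromosome (mean oriented ratios on the same side of
0.5); the repressive mark H3K27me3 the opposite. A mean ratio of exactly
0.5 has no major allele; the pair is excluded from matching and logged.
A candidate pair is **true** when both sites are imbalanced and the
direction matches; **control** when testable but failing either; and
**untestable** when no sample is doubly heterozygous with both sites
passing the depth/ratio filters — without such a sample the pair cannot
be phase-oriented at all, so filter-failed heterozygotes also fall here.

**LD blocks.** Four-gamete blocks are built greedily left to right: a SNP
joins the current block iff every member shows at most 3 of the 4 gametes
with it across all 2N phased haplotypes (the strictest deterministic
reading; monomorphic SNPs always join). Confidence-interval blocks are
consumed from a definition file, not reimplemented. Blocks of one
population are merged by transitive closure of co-membership, and a tag
SNP expands to the intersection of its merged block across all
populations; a blockless tag degenerates to itself. LD is the Pearson r
of allele indicators over haplotypes (not dosages), and the genetic
distance between two loci is 1 − |r|.

**Explanatory power.** Transcript oriented ratios are regressed on paired
regulatory oriented ratios by OLS, pooling per-sample observations of the
*mapped allele-specific pairs* as points; the distance curve reports the
cumulative R² for pairs within each genetic-distance threshold (default
grid 0 to 1 in steps of 0.1, thresholds with fewer than 3 points are
missing). The interactome permutation control shuffles the anchor2 column
within chromosomes (count and anchor multisets preserved exactly,
deterministic under seed); four permutations by default. Because only
direction-matched pairs map, permutation retains some power — the
comparison is real > permuted mean, not real > 0.

**QTL comparator.** Per-sample peak intensities and expression levels are
regressed on additive genotype dosage (0/1/2 alternative alleles), plain
OLS with a two-sided t-test on the slope, no covariates or normalisation.
An hQTL–eQTL pair is kept when both sides have unadjusted P < 0.05 for
the same SNP, the gene is linked to the peak by a chromatin interaction,
and the effect signs agree (activating marks; the sign rule inverts for
the repressive mark — a symmetric generalisation the comparator flags,
since activating marks are its primary use). Sensitivity is compared on
the identical tag-SNP candidate set.

**Random Forest rescue.** True vs control pairs are learned per histone
mark with 1000-tree forests, mtry = ⌊√(feature count)⌋, terminal nodes
grown to minimum size 1. Stratified 5-fold cross-validation repeated
twice yields 10 classifiers; each pair is held out exactly twice, and AUC
is computed per held-out fold from probability scores (midrank ties). All
10 classifiers vote on every untestable pair; a positive call needs
strictly more than 5 votes. Class imbalance is left as is (no resampling;
class weighting is available in the configuration). Subpanel experiments
draw k ∈ {2, 5, 10, 20} samples 10 times, re-run the whole
pair/partition/train cycle per subpanel, and validate the positive calls
by re-testing them on the full panel: a call is *tested* if the full
panel makes it testable and *confirmed* if the full panel labels it
allele-specific.

## The synthetic reference panel

The generator emulates a panel of genetically distinct lymphoblastoid-like
cell lines with phased genotypes and allele-resolved ChIP/RNA readouts.
One chromosome is carved into 100-kb blocks; each holds a tag SNP, a
regulatory SNP inside a ChIP-seq peak, and a gene 50 kb away with
transcript SNPs, linked by one real interaction (plus 8 random decoy
links by default — roughly the spurious-contact rate of real
interactomes; note that in a small synthetic world a decoy is far more
likely to join two causal loci than in a genome with thousands of genes,
which makes decoys *more* adversarial here, not less). Haplotypes are
mosaics of two founders with a 0.02 per-SNP switch probability, so LD
decays with SNP separation; founder frequency 0.5 (an optional rare
stratum at 0.08 supplies pairs that small subpanels cannot test — the
rescue scenario).

Cis effects are planted at the haplotype level: in samples heterozygous at
the regulatory SNP, the chromosome carrying its alternative allele emits a
fraction f of both the ChIP and the RNA reads. Planted strengths cycle
through f ∈ {0.65, 0.70, 0.75, 0.80, 0.85, 0.90} across effect loci (half
of all blocks) — real cis effects vary in strength, and this between-pair
variance is what the explanatory R² measures. On top, f wobbles per
sample with sd 0.05, shared between the ChIP and RNA readout of a block:
trans variation in enhancer output moves mark and transcript together,
giving true pairs the within-pair correlation real data shows. Read
counts are Binomial(depth, f-mapped-through-phase) at Poisson(50) depths
— deliberately matched to the balanced-binomial null of the test (no
overdispersion; a beta-binomial option exists for robustness work).
Homozygous samples emit no counts. Repressive-mark ChIP fractions are
complemented. Binary feature tables carry planted class signal: bits at
rate 0.9 for effect loci vs 0.1 otherwise, split between variant-level
(TF-affinity) and gene-level (GO) features, assigned from latent effect
status so untestable pairs are informative.

What the generator does **not** emulate: reference-mapping bias toward the
reference allele, overdispersed counts, genotyping error, peak-boundary
uncertainty, trans-QTL structure, and realistic gene/interactome density.
Passing tests therefore demonstrate the correctness and calibration of
the machinery under the model's own assumptions, not performance on real
sequencing data.

## Problem sizes and numerical choices

The test suite and the acceptance script run desk-scale versions of each
experiment: panels of 100 samples × 30 loci for the subpanel and rescue
experiments (150-tree forests there; the 1000-tree default stands for
real analyses), 5,000–6,000 simulated ratio pairs for R² recovery, and
10,000+ sites for null calibration. The rescue experiment uses the
strong-effect stratum (f ∈ {0.8, 0.85, 0.9}) with 12 rare blocks; the
subpanel-stability experiment uses the default moderate-effect panel,
where labels are genuinely noisier at k = 2 — with uniformly strong
effects every subpanel reaches AUC 1.0 and "spread" becomes degenerate.

Other conventions: VCF positions are 1-based, BED/BEDPE 0-based
half-open, converted in exactly one predicate (position p in [s, e) iff
s ≤ p − 1 < e); multiallelic and unphased VCF records are skipped, not
decomposed; promoter windows are 1.5 kb upstream / 0.5 kb downstream of
the TSS, strand-aware, clamped at 0, always 2000 bp before clamping;
promoter coverage is computed on the union of peaks and "at least half"
is inclusive; TSS distance is unsigned; zero p-values entering Fisher's
method are clamped to the smallest positive float with a warning; ties at
ratio 0.5 are excluded from direction matching; and every stochastic
component takes an explicit seed, so reruns are byte-identical.

## Known limitations

Binomial (not beta-binomial) testing is anti-conservative under
overdispersion; no mapping-bias correction (WASP-style filtering should
precede this tool on real data); the four-gamete scan is one of several
defensible block definitions; eQTL-link pairing reuses the peak
requirement on the regulatory side, so a variant outside any peak cannot
pair even with an eQTL link; and the QTL comparator deliberately omits
covariates, normalisation and FDR control because it mirrors the
minimal regression the allelic arm is compared against, not a production
QTL pipeline.
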