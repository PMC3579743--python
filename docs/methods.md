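# Methods

## The liability-threshold model

All machinery in this package rests on the classical liability-threshold
model: each individual carries a latent liability `y = G + e`, where `G` is
an additive genetic value with variance `h²` (the narrow-sense heritability
of liability) and `e ~ Normal(0, 1 − h²)` is an independent environmental
deviate, so `y` is standard normal in a random-mating population. An
individual is affected when `y ≥ τ = Φ⁻¹(1 − K)`; at the default population
prevalence `K = 0.01`, `τ = 2.326`.

## The family simulator (`liabherit.liability`)

**Genetic architecture.** Liability is spread over `n = 1000` biallelic
SNPs (the default; configurable). Allele frequencies `p_i` are uniform on
(0.01, 0.99). Relative SNP importances are `w_i = t_i / Σt` with
`t_i ~ Uniform(0, 1)`, and the allele-substitution effect is

    a_i = sqrt(w_i h² / (2 p_i (1 − p_i))),

the unique scaling under which the per-SNP additive variances
`2 p_i (1 − p_i) a_i²` sum exactly to `h²` (enforced to 1e-10 at
construction). The genetic value of a genotype `x` (allele counts) is
`G = Σ x_i a_i − μ_G` with the centering constant `μ_G = Σ 2 p_i a_i`, so
`E[G] = 0` under Hardy-Weinberg. (An alternative centering constant
`Σ p_i(1−p_i) a_i` floating around in descriptions of this design does not
center `G` — at `n = 1000` it shifts the population mean by roughly +20
liability units and makes the 2.326 threshold meaningless — so the
expectation-zero form is used.)

**Families.** Parental haplotypes are Bernoulli(`p_i`) draws; each child
receives one allele per SNP from each parent with probability ½, with the
transmitted alleles recorded. The pseudo-control genotype is the two
untransmitted alleles per SNP, taken against child 1; consequently
`child + pseudo-control = father + mother` in allele counts at every SNP,
an identity asserted in tests. Every family member, including the
pseudo-control, receives its own environmental deviate.

**Ascertainment.** Rejection sampling implements four recruitment designs:
screened quads (proband affected; father, mother and designated sibling
unaffected), unscreened simplex trios (proband affected, nothing else
constrained), unscreened multiplex quads (both children affected), and a
fixed 60/40 mixture of the latter two. Candidates are generated in
vectorized chunks; the proband is simulated and screened first and the
rest of the family is materialized only for candidates whose proband is
affected — the deferred members are conditionally independent of the
proband's affection status given the parents, so the accepted distribution
is exact. A hard cap on candidate families (default 1e9) bounds runtime
when a scenario is effectively unreachable.

**Assortative mating.** Maternal genotypes can be assigned by a fair-coin
rule instead of an independent draw: heads, the mother's genotype is drawn
from the allele frequencies; tails, it is set equal to the father's. Both
granularities of the coin are implemented. The default
(`mating="assortative"`) tosses the coin **per SNP**; `assortative_per_family`
tosses it once per family. The per-SNP reading is the default because it
is the one that reproduces both published simulation expectations at once:
in the limit of many SNPs it gives a pseudo-control expectation of 1/9
(11.1%) for unscreened simplex families at h² = 0.5 and 3/7 (42.9%) for
unscreened multiplex families at h² = 0.75, against printed values of
11.3% and 42.8%; the per-family coin gives 13.2% and 49.6% for the same
cells. Both rules produce a parental liability correlation of ½.

**The R/S estimator.** For a set of accepted families, `S` is the mean
proband liability (the selection differential; ≈ φ(τ)/K = 2.665 for
unscreened simplex ascertainment at K = 0.01) and `R` the mean liability
of a relative class (father, mother, designated sibling, pseudo-control);
`R/S` estimates the heritability attributable to that class. For probands
themselves the ratio `mean(G)/mean(y)` checks that the simulator recovers
the configured h² (a variance-based alternative, inverting the reduction
of genetic variance under truncation selection, is provided; it is only
meaningful when selection acts on the proband alone and its discriminant
is clamped at zero against sampling noise). Under random mating the
truncated-normal regression gives `R/S = h²/2` for parents and siblings
and 0 for simplex pseudo-controls, which the acceptance suite verifies.

**A note on the multiplex random-mating expectation.** The same
truncated-normal algebra gives the pseudo-control expectation
`(h²/2)/(1 + h²/2)` under multiplex (both-children) ascertainment with
random mating: 27.3% at h² = 0.75 and 20.0% at h² = 0.50. The simulator
reproduces the closed form (~28% at h² = 0.75 once finite-SNP skewness is
included). A printed reference value of 20.2% for this cell at h² = 0.75
is consistent with the h² = 0.50 computation but not with any reading of
the h² = 0.75 procedure we could construct — including parental screening
variants and both coin granularities — while its assortative companion
(42.8%) is reproduced at h² = 0.75 exactly. The package follows the stated
conditions (h² = 0.75) and reports what they produce.

## Case-control heritability (`liabherit.greml`)

**GRM.** The genetic relationship matrix follows the standard GCTA
estimator: off-diagonals `(1/m) Σ (x_ij − 2p̂_i)(x_ik − 2p̂_i) / (2p̂_i q̂_i)`
and bias-adjusted diagonals `1 + (1/m) Σ (x² − (1+2p̂)x + 2p̂²)/(2p̂q̂)`.
Frequencies are estimated from the joint case + control analysis sample
(both groups must share one scale) and missing genotypes are mean-imputed,
which makes the SNP-count-weighted combination of per-chromosome GRMs
*exactly* equal to the pooled-SNP GRM — asserted as an algebraic identity
in tests. Monomorphic SNPs are a hard error (QC runs first). GRMs read and
write GCTA's binary triplet (`.grm.bin` float32 lower triangle,
`.grm.N.bin`, `.grm.id`).

**REML.** `GREML` fits `y ~ Normal(Xβ, Σ_c σ²_c A_c + σ²_e I)` by
average-information REML: three expectation-maximization warm-start
iterations (monotone, safe), then AI (quasi-Newton) steps with step-halving
and EM fallback whenever a step would decrease the restricted likelihood.
Convergence is a restricted log-likelihood change below 1e-8 (100
iterations maximum, warning on non-convergence); components are floored at
1e-8 × var(y) unless `constrain=False`. Standard errors come from the
inverse average-information matrix, with the delta method for variance
ratios. With a single GRM the model is rotated once into the GRM's
eigenbasis, making every iteration O(n·p) — the dense and eigen backends
agree to 1e-7 in tests. A GRM numerically indistinguishable from the
identity triggers an explicit non-identifiability warning.

**Liability transform.** Observed-scale estimates are rescaled by
`K²(1−K)² / (z² P(1−P))` with `z = φ(Φ⁻¹(1−K))` and `P` the sample case
proportion — the ascertainment-corrected transform; its standard error is
scaled by the same factor (delta method; the sampling variability of `P`
is neglected, matching common practice).

**Known shrinkage under strong ascertainment.** At the conditions of the
parameter-recovery experiment (true liability h² = 0.5, K = 0.01, case
fraction P = 0.5) this estimation chain is *not* unbiased: the first-order
transform undercorrects severe case enrichment, and the recovered mean is
≈ 0.37–0.41 rather than 0.5 — a behaviour of REML-on-ascertained-binary
data that is well documented in the quantitative-genetics literature and
the motivation for later ascertainment-aware estimators. The recovery test
asserts the idealized expectation and therefore documents this shrinkage
rather than hiding it; every other component of the chain (REML itself on
quantitative traits, the transform's closed form, the GRM identities) is
verified unbiased/exact in isolation.

**Per-chromosome partition.** Each chromosome is fitted jointly with a
rest-of-genome GRM (two genetic components + residual; a marginal
single-component mode is available) and the per-chromosome estimates are
correlated with physical chromosome length (GRCh37 lengths bundled).

## Quality control (`liabherit.qc`)

Order: strand-ambiguous SNPs (A/T, C/G) out; individual call rate ≥ 0.98;
sex concordance (X heterozygosity < 0.02 → male, > 0.20 → female, else
ambiguous and not flagged); SNP call rate ≥ 0.98; MAF > 0.01; Hardy-
Weinberg p > 0.005. The HWE test is the conditional exact test (summing
probabilities of heterozygote counts no more probable than the observed
one, computed with log-factorials; verified against full enumeration in
exact rational arithmetic), with the 1-df chi-square variant behind a
flag. The report records removals per rule and is asserted to partition
the input. Cross-family relatedness pruning (greedy, GRM cutoff 0.05,
ties broken toward the lower call rate) matches GRMs built from dense
SNP panels; at the small SNP counts used in tests the GRM noise floor
(sd ≈ 1/√m) approaches the cutoff, which the tests account for by passing
explicit cutoffs.

## Genomic coverage (`liabherit.coverage`)

Synthetic LD haplotypes stand in for reference-panel data: each block
draws an anchor allele per haplotype and each site copies the anchor with
probability `c = r²_target^(1/4)` (giving pairwise within-block r² ≈
target, cross-block r² ≈ 0). Coverage of a forced tag set at threshold X
is `M/(M+N)` where `N` is the minimum number of additional candidate SNPs
(MAF > 0.1) needed so every candidate has r² ≥ X with some tag. The
minimum is computed exactly by branch-and-bound set cover when ≤ 25
candidates are uncovered and greedily above that; the two agree on all toy
regions tested. The subsampling experiment (fractions 1, ½, ¼, ⅛ of the
forced set, five draws each, X ∈ {0.5, 0.7, 0.9}) averages coverage per
cell and is monotone in both X and the subsampling fraction.

## What the synthetic data do and do not emulate

The generators provide biallelic autosomal + X panels with configurable
MAF ranges, Hardy-Weinberg genotypes, liability architectures with known
h², nuclear families with exact Mendelian transmission, and block-wise LD.
They do **not** emulate realistic demography (no coalescent, no
recombination maps, no allele-frequency spectra), genotyping error, batch
effects, population stratification beyond planted two-population scenarios,
or X-specific transmission (liability SNPs are treated as autosomal in the
simulator; chromosome X receives autosomal GRM scaling). Passing tests
therefore demonstrate correctness of the algorithms under the stated
model, not robustness to real-data artifacts.

## Problem sizes used by the test suite

Chosen as desk-scale renditions of the published experiment sizes: the
simulator's acceptance runs use 1000 accepted families × 20 replicates
(unscreened simplex) and 500 × 10 (multiplex, where acceptance probability
is ~1e-3); the recovery experiment uses six cohorts of 1000 cases + 1000
controls over 5000 SNPs; oracle equivalences run at n = 200 (REML grid),
≤ 20-SNP regions (tagging) and n = 100 (HWE enumeration). The
`scripts/acceptance.py` entry point re-runs the four simulator cells at
the same scale from a single seed.
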