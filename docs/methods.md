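# Methods

`gsbench` benchmarks genomic-selection methods on a simulated dataset that
reproduces the statistical structure of a well-known community workshop
dataset: a two-generation livestock pedigree, dense SNP genotypes with
realistic linkage disequilibrium, and a quantitative trait controlled by a
small number of QTL of heterogeneous kinds. This note records the models,
the defaults and their rationale, the numerical choices, and what the
simulator does and does not emulate.

## The simulated population

**Pedigree.** 20 sires, each mated to 10 dams, each dam producing 15
offspring: 3220 individuals forming 20 half-sib and 200 full-sib families.
Founders are unrelated within the pedigree but share ancestry through the
historical population below.

**Genome and founder LD.** Five chromosomes of 1 Morgan, each carrying
2000 equally spaced biallelic loci. Founder haplotypes are produced by
gene-dropping through a random-mating historical population of effective
size `ne = 100` for 100 generations, initialised with allele frequencies
uniform on [0.05, 0.95]. Drift plus linkage generates LD that decays with
map distance, which is what makes marker-based prediction work at all.
Loci whose final minor-allele frequency drops below 0.01 are redrawn
independently at a fresh frequency (U(0.2, 0.8)); this keeps the panel
fully polymorphic at the cost of destroying LD locally at the handful of
affected loci. Meiosis uses the Haldane (no-interference) model:
crossovers are a Poisson process along the chromosome, so the
recombination fraction at distance d Morgans is (1 − e^(−2d))/2.

**Trait architecture.** Eight QTL, at marker positions but excluded from
the analysis panel (QTL are unobserved):

| chromosome | QTL | kind |
|---|---|---|
| 1 | 1 | additive, forced largest variance |
| 2 | 2 | additive, linked (< 0.2 M apart) |
| 3 | 2 | additive, linked |
| 4 | 1 | imprinted (paternal expression) |
| 5 | 2 | epistatic pair |

Raw additive effects are drawn from a signed gamma (shape 1.2) and
redrawn until the chromosome-1 locus carries the largest single-locus
variance; all effects are then rescaled by one common factor so the
variance of the true breeding value (TBV) among founders equals
`sigma2_g` (default 1). The imprinted QTL acts only through the
paternally inherited allele. The epistatic pair's 3×3 genotype-value
table is `k (g1 − 2p1)(g2 − 2p2)` — additive-by-additive interaction with
exactly zero marginal substitution effects at founder frequencies, so it
contributes nothing to TBV and maximally stresses additive predictors.
Its full (non-additive) variance is set to 10% of `sigma2_g`, a modest
contribution consistent with "hard to capture" epistatic QTL.

**Breeding values and phenotypes.** TBV is the sum of average
(allele-substitution) effect contributions — additive `a(z − 2p)`, the
paternal-allele term for imprinting, and the (zero) marginals of the
epistatic table. Phenotypes are `y = mu + G + e` where G is the *full*
genotypic value (non-marginalised imprinting and epistasis) and
`e ~ N(0, sigma2_e)` with `sigma2_e = sigma2_g (1 − h2)/h2` for the h²
target 0.3. Because the epistatic variance (0.1 sigma2_g) sits in Var(y)
but not in Var(TBV), the expected realised narrow-sense ratio is
0.3/1.03 ≈ 0.291, i.e. a target of 0.3 with a small, deliberate
non-additive bite taken out of it. Within each full-sib family the first
⌈2/3 · 15⌉ = 10 offspring (in id order) are phenotyped: exactly 2000
records, founders never phenotyped.

**What the simulator does not emulate.** No sequence-level detail
(nucleotides, mutation), no selection, no overlapping generations, no sex
chromosomes, no genotyping error or missingness. Tests passing on this
generator demonstrate correct method implementations and the qualitative
method ranking under a sparse-QTL architecture; they do not certify
performance on real livestock data, where LD structure, family sizes and
genetic architecture differ.

## Prediction methods

**Pedigree BLUP / GBLUP.** The mixed model `y = 1 mu + g + e`,
`g ~ N(0, K sigma2_g)`, with K either the pedigree numerator relationship
matrix A (tabular method) or the realised genomic relationship
`G = WW' / (2 Σ p_j(1 − p_j))` (VanRaden method 1, observed-frequency
centring). Variance components are estimated first by REML and then
plugged into the BLUP equations (two-step). Because there is a single
random effect, the restricted likelihood is one-dimensional in h²: we
eigendecompose the phenotyped submatrix of K once, profile out the mean
and the total variance, locate the optimum on a 21-point grid and refine
by bounded scalar minimisation to 1e−6. BLUP solves the
equivalent variance form (`V = sigma2_g K_OO + sigma2_e I`) via Cholesky,
predicting unphenotyped individuals through K; PEV comes from the
projection form `sigma2_g K_ii − sigma2_g² k_i' P k_i`, identical to the
mixed-model-equation inverse but avoiding an inverse of (possibly
singular) G. Non-PSD matrices get an escalating diagonal jitter
(1e−8 × 10^t, at most 5 levels).

**Whole-genome regression.** `y = mu + Σ_j z_j beta_j + e` with four
priors on SNP effects, all run by single-site Gibbs sampling:

* LASSO: Laplace(rate λ), as a normal-exponential mixture
  (`beta | tau² ~ N(0, tau²)`, `tau² ~ Exp(λ²/2)`); `1/tau²` has an
  inverse-Gaussian full conditional; λ² gets a Gamma draw under a flat
  prior on λ.
* Bayes A: scaled-t(df, scale λ), as normal with per-SNP
  scaled-inverse-χ² variance; the scale gets a Gamma draw under a flat
  prior.
* BBn (Bayes C): spike-and-slab, normal slab with one shared variance
  `sigma2_snp`; its conditional is scaled-inverse-χ² under a flat prior
  on the variance (kept at its current value while fewer than 3 SNP are
  in the slab, where the flat-prior conditional is improper).
* BBt: spike-and-slab with a scaled-t slab.

Inclusion indicators are updated from the marginal (effect-integrated)
likelihood ratio; exact ties go to the spike. π has the conjugate
Beta(1 + m₁, 1 + m − m₁) conditional under a flat prior. The t shape df
is sampled by random-walk Metropolis on log(df) with reflection at the
flat-prior bounds [0.5, 9] and a Jacobian correction; the step size
adapts toward 20–40% acceptance during burn-in and is then frozen, so
detailed balance holds for every retained sample. The residual variance
has a flat prior on the variance scale. Initialisation: beta = 0,
mu = mean(y), sigma2_e = Var(y), π = 0.5, df = 4, scales from a
method-of-moments pass that spreads half the phenotypic variance over the
markers. The residual vector is updated incrementally after every effect
change and refreshed from scratch every 100 cycles to bound float drift.
The inner loop is numba-compiled; a given (data, prior, schedule, seed)
is bit-reproducible.

**Chain schedule.** Defaults follow the standard protocol: 10,000 burn-in
cycles, then 10,000 retained realisations separated by 20 cycles —
210,000 cycles in total. When df is estimated the burn-in and the
thinning interval are multiplied by 5 (chain 5× longer, same number of
realisations); multiplying every component including the realisation
count would make the sampling phase 25× longer, which is not what "five
times longer" means.

**Evaluation.** Accuracy r = cor(TBV, GEBV), by default over all 3000
offspring (flags for phenotyped-only or candidates-only). Improvement is
100(r − r_BLUP)/r_BLUP against pedigree BLUP. Explained genetic variance
uses the infinitesimal-model identities Var(EBV) = r² sigma2_g and
PEV = (1 − r²) sigma2_g, hence sigma2_g = Var(EBV) + mean(PEV); each
method's implied h² uses its own residual-variance estimate. For the
regression methods PEV is defined as the across-retained-samples
posterior variance of each individual's Σ z_j beta_j (the methods
themselves do not define one).

**GRAMMAR scan.** Step 1 fits the polygenic model on the pedigree A
matrix (flag for genomic G) and takes residuals `y − mu_hat − g_hat`;
step 2 regresses residuals on each SNP dosage, two-sided p from the t
statistic. The polygenic adjustment absorbs part of the marker signal, so
the test runs at or below the nominal level — the calibration test checks
conservativeness, not exact uniformity. No multiple-testing correction by
default. A perfect single-SNP fit (zero residual variance) is reported as
the smallest representable p rather than t = 0.

## Problem sizes used in the test suite

The test and acceptance runs choose sizes that keep each check
informative at interactive runtimes: structural checks and unit oracles
run on reduced marker panels (30–200 loci/chromosome) and/or smaller
pedigrees, since pedigree structure, phenotyping counts and QTL layout do
not depend on panel density; heritability recovery uses the full pedigree
with a 200-locus/chromosome panel; the method-comparison benchmark uses
the full 3220-individual pedigree with a ~1000-marker panel and chains
one tenth the default length over 3 seeds, the scale at which the
qualitative method ranking (Bayes A/B ≥ GBLUP > pedigree BLUP) is already
stable. The acceptance script runs the simulator at the full default
scale (10,000 loci). Bayes A/BBt appear there with df fixed at 4 (the
published "_4df" scenarios); estimating df quintuples those chains
without changing the qualitative pattern.

## Known limitations

* The historical-population LD generator is a plain Wright-Fisher
  gene-drop; it produces realistic LD decay but is not calibrated to any
  specific livestock LD map.
* The flat priors on λ / sigma2_snp are improper; propriety of the
  conditionals is data-dependent and guarded by wide numeric bounds
  [1e−8, 1e8].
* The BBn slab variance is shared across SNP (the per-SNP alternative is
  BBt's t slab).
* REML assumes a single random effect and an overall mean; no additional
  fixed effects.
* GEBV for the regression methods are reported on the genetic scale
  (without the intercept); add `mu_hat` for trait-scale predictions.
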