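# Methods

`scmr` implements a complete desk-scale analysis chain for asking whether
genetically regulated gene expression in individual brain cell types
mediates risk of central-nervous-system phenotypes, and whether those
allelic effects depend on disease context. The chain is: pseudobulk
cis-eQTL mapping → genotype×context interaction modelling with nested
mixed models → approximate-Bayes-factor colocalization against GWAS
summary statistics → colocalization-anchored two-sample Mendelian
randomization (MR). Because individual-level brain cohorts are access
restricted, the package ships a first-class synthetic-data generator whose
generative law is exactly the model family the inference stages fit, so
every stage can be validated against known ground truth.

## Synthetic cohorts

**Genotypes.** Each LD block is simulated per haplotype as a latent AR(1)
Gaussian with adjacent correlation `ld_rho` (default 0.8), thresholded at
the Φ⁻¹(MAF) quantile; a donor's dosage is the sum of two independent
haplotypes. This gives hard calls in {0,1,2}, marginal Hardy–Weinberg
equilibrium by construction, and tunable within-block r² without a
haplotype panel. MAF = 0 degenerates cleanly to a monomorphic column.

**Cohort.** Default 391 donors: 183 controls and 208 disease cases split
near-evenly across AD/PD/MS (the case split is a configurable choice, not
an inference). Age ~ N(75, 15) years, sex ~ Bernoulli(½), postmortem
interval ~ Gamma(4, 6) hours, and donors are assigned uniformly to 4
sample sources. Diagnosis counts follow the configured proportions by
largest-remainder apportionment, so 183/391 controls is reproduced
exactly.

**Cell counts.** For each cell type, a donor's per-gene log-mean is

    baseline + covariate effects + β_main·G + Σ_d β_d·G·1[diagnosis=d]
    + β_age·G·(age − 75) + u_source + u_source×diagnosis + ε_donor

with u-terms drawn per gene from N(0, sd²) (defaults 0.1/0.1) and donor
noise sd 0.15. Cell-level counts are negative binomial around
exp(log-mean) (dispersion 0.5; Poisson as dispersion → 0), with
cells-per-donor Poisson around the configured plan. The donor-level law is
therefore *exactly* the M2 interaction model below, which makes parameter
recovery well posed. What the generator does not emulate: ambient RNA,
doublets, batch-dependent library chemistry, trans effects, and realistic
gene–gene correlation; passing tests demonstrate the statistics are
implemented correctly, not that real snRNA-seq data meet the model's
assumptions.

**GWAS.** Summary statistics come from individual-level simulation: a
fresh cohort of N individuals is drawn over the same LD law; the phenotype
is γ·(SD-scaled dosage of the causal SNP) + N(0,1) for quantitative
traits, or a liability-threshold binary outcome for case-control traits
(linear-probability marginal effects rescaled by 1/(μ(1−μ)) to an
approximate log-odds scale). Marginal per-SNP beta/se/p are exact OLS.

**Seeding.** All randomness flows from one root seed; each consumer draws
from a named stream (`rng_for(seed, "cells", cell_type)`, …) hashed into a
NumPy `SeedSequence` spawn key, so outputs are bit-reproducible and
insensitive to stage ordering.

## Pseudobulk

Counts are summed per donor within a cell type; donors with fewer than 10
cells in a cell type are excluded from that cell type only. An
`all_cells` mode pools every cell first, emulating an equivalently sized
bulk-tissue design. Normalization is `log2(count/libsize·1e6 + 2)`; the
prior count of 2 acts on the CPM scale, which keeps the transform exactly
invariant to per-donor library scaling (the alternative of scaling the
prior by mean library size breaks that invariance, which is why it was not
adopted). Genes with a nonzero pseudobulk count in fewer than 5% of
donors are dropped, then each gene is centred and scaled to unit SD — one
unit of expression is one SD, which is what makes sdY = 1 in
colocalization and gives eQTL betas SD-per-allele units.

## cis-eQTL scan

Expression is first residualized per gene on age, sex, PMI, diagnosis and
sample source (one-hot, reference level dropped; constant terms are
absorbed by the intercept so control-only runs need no special casing).
Expression PCs are computed from the donor×gene residual matrix and
genotype PCs (default 5) from centred dosages, both as orthonormal donor
scores with a fixed sign convention (largest-magnitude loading positive).
The number of expression PCs is chosen per cell type as the argmax of the
eGene count over a configured grid, ties to the smallest.

The scan model per pair is `E ~ G + ePCs(1..n) + gPCs(1..5)`. Both sides
are projected off the PC design once (Frisch–Waugh), so the per-pair
statistics equal full OLS exactly: t with df = n − #covariates − 1,
two-sided p from the t distribution. A SNP is tested against a gene when
its distance to the nearest gene-body boundary is ≤ 1 Mb (0 inside the
gene). Dosage MAF floor 0.05 (configurable); missing dosages are
mean-imputed per SNP for the scan only, with the imputed count reported.
BH FDR is applied across all tested pairs within a cell type (per-gene
correction is a coarser alternative the scan tool convention does not
use); an eGene has min FDR < 5%.

## Interaction mixed models

For each eGene's top eSNP the package refits, by maximum likelihood,

* M0: `E ~ diagnosis + age + PMI + sex + PCs`
* M1: M0 + G
* M2: M1 + G×diagnosis

each with a random intercept per sample source plus a per-(source ×
diagnosis) deviation. This nested variance-components structure (two
independent variances) is the diagonal counterpart of a correlated
random-slope model; it matches the generator exactly and avoids estimating
a 4×4 covariance from 4 sources. ML (not REML) is used throughout because
the LRTs compare fixed-effect structures.

The likelihood is maximized by L-BFGS-B over log variance ratios with the
fixed effects and residual variance profiled out; Woodbury and
determinant-lemma identities reduce each evaluation to a q×q Cholesky
(q = number of random-effect columns), so a fit costs ~10 ms and
scan-scale Monte Carlo is feasible. Multi-start (two jittered starts plus
the θ = 0 boundary) guards against local optima; if all variance
components hit zero the fit, including its log-likelihood, is exactly OLS.
Grouping factors with fewer than two levels are dropped, so a
single-source cohort degrades gracefully.

Gating follows the two-step scheme: M0-vs-M1 (df 1) validates the eQTL at
p < 0.05; only then is M2 fitted and M1-vs-M2 tested (df = number of
non-reference diagnosis levels, 3 here; the random structure is identical
across M1/M2 so no boundary correction arises). Per-level interaction
coefficients carry Wald p-values on ML standard errors (a normal
reference; Satterthwaite df would be the convention of one particular
mixed-model package and differs negligibly at these n). Storey q-values
are computed per cell type over the M1-vs-M2 LRT p-values of converged,
passing fits: π₀ from the λ = 0.05…0.90 grid with a cubic-polynomial
smoother evaluated at λ = 0.90, capped at 1 (falling back to π₀ = 1 — plain
BH — below 100 tests). Degenerate interactions (e.g. constant age making
G×age collinear with G) reduce the comparison to stat 0, p 1 rather than
erroring.

The age variant, for control-only cohorts, compares `G + age` against
`G×age` (df 1) with a source random intercept only; its hits join the
disease-interaction hits in the MR exclusion list, since a
context-dependent instrument violates the MR assumption that the
instrument–exposure association is stable.

## Colocalization

GWAS summary statistics are munged to a fixed schema (aliases resolved
case-insensitively; missing se imputed as |β|/|Φ⁻¹(p/2)|, missing β as
z·se; unresolvable rows dropped and counted). Regions are built by greedy
1 Mb distance clumping of genome-wide-significant variants (p < 5×10⁻⁸),
each region being lead ± 500 kb repopulated with all GWAS SNPs; regions
under 100 SNPs are dropped.

Each (gene, cell type) with eQTL statistics in a region is tested against
each trait under the single-causal-variant assumption. Per-SNP evidence is
the Wakefield approximate Bayes factor, log ABF = ½(log(1−r) + r·z²) with
r = W/(W+se²); prior effect SD √W = 0.15·sdY for quantitative traits
(sdY = 1 for standardized expression; otherwise sdY² is the through-origin
regression slope of 2·N·MAF·(1−MAF) on 1/var(β)) and 0.2 on the log-odds
scale for case-control traits. Hypothesis weights use the standard priors
p1 = p2 = 10⁻⁴, p12 = 10⁻⁵ (p12 = 0.01 for the pQTL replication setting),
accumulated in log space with log-sum-exp; the H3 cross term is
log(exp(S1+S2) − exp(S12)). Alleles are label-harmonized (swapped A1/A2
flips the GWAS beta; other combinations are dropped and counted;
palindromic SNPs are retained but flagged — the harmonization is
label-only, with no strand inference). Genes in configured exclusion loci
(MAPT, HLA) are flagged rather than silently merged. A colocalization is
called at PP.H4 > 0.8.

## Mendelian randomization

For each flagged colocalization (exposure not on the interaction exclusion
list, gene outside excluded loci), instruments are the region's eQTL
associations at FDR < 5%, greedily r²-pruned at 0.01 with the
colocalization lead SNP as the anchor (the anchor survives pruning by
construction when eligible), then filtered on per-SNP instrument strength
F = (β_x/se_x)² > 15. LD is computed in-cohort (Pearson correlation of
dosages, pairwise deletion).

Estimators: Wald ratio β_y/β_x with first-order SE se_y/|β_x| for a single
instrument; fixed-effects IVW Σ(β_x β_y/se_y²)/Σ(β_x²/se_y²) otherwise
(identical to Wald for one instrument); normal p-values, significance at
p < 0.05 with no further multiplicity correction (the small number of
exposures makes FDR control over MR results ineffective, a known caveat).
As cross-validation, PCA-IVW summarizes the full FDR-passing region set:
the weighted matrix Ψ_kl = (β_x,k/se_y,k)(β_x,l/se_y,l)ρ_kl is
eigendecomposed, components covering 99.9% of its trace replace the
correlated instruments, and a generalized (correlation-aware) IVW is run
on the projections. Decomposing weighted Ψ rather than raw ρ follows the
method's own derivation; the direction-agreement flag between IVW and
PCA-IVW is reported per exposure.

## Calibration and validation choices

The `validation` module quantifies, at the sizes below (chosen to give
tight Monte-Carlo error while keeping a laptop-scale run):

* **LRT type-I error** — 1,000 genes simulated under M1 (no interaction),
  n = 200 donors, 4 sources: rejection at p < 0.05 should be 3–7%.
* **Null-scan uniformity** — 10,000 null pairs (20 genes × 500 independent
  SNPs, 200 donors): KS test against uniform, and eGene fraction ≤ 5%.
* **IVW recovery** — γ = 0.2, 3 independent instruments, exposure
  n = 20,000, outcome N = 50,000, 500 seeds: |bias| < 0.02 and 95% CI
  coverage 0.95 ± 0.03. Instruments are strong (F ≈ 2,000) because the
  fixed-effects IVW standard error is first-order in the outcome only;
  weak instruments attenuate the estimate by ~1/F — which is precisely why
  the pipeline filters on F upstream.
* **Coloc discrimination** — 50-SNP two-block region (block r = 0.8),
  eQTL n = 400 with a 0.5-SD effect, GWAS N = 10,000 with a lead z ≈ 8:
  shared-variant draws should reach PP.H4 > 0.8 and distinct-variant draws
  (causal SNPs in different blocks, r² < 0.01) should make PP.H3 maximal,
  each in ≥ 90% of 100 seeds.
* **M2 recovery** — 200 replicates at n = 400: the fraction of
  (coefficient, replicate) pairs with the ML estimate within 2 SEs of
  truth should be ≥ 93% (2 SEs of a normal cover 95.4%; ML SEs are
  slightly anticonservative at these n). The pooled-across-coefficients
  reading is used; requiring all four coefficients jointly would bound the
  rate near 0.95⁴ ≈ 0.81 and tests a different quantity.

## Numerical and degenerate-input choices

* Variance-ratio optimization bounds: log θ ∈ [−16, 8]; relative ll
  tolerance 1e−12; non-convergent fits are flagged and excluded from the
  q-value denominator, never dropped silently.
* Rank deficiency anywhere raises an error naming the collinear columns;
  zero-variance genes are dropped with a warning before scaling;
  zero-variance SNPs get zeroed LD rows with a flag.
* BH/q-value tie-breaks use stable mergesort; per-SNP H4 posteriors break
  argmax ties to the first SNP in region order.
* Posterior probabilities are normalized in log space; the five PPs sum to
  1 within 1e−10 by construction.
* The PCA-IVW projected covariance receives a 1e−8 ridge only if singular,
  with a warning.

## Known limitations

Single-causal-variant colocalization only (no SuSiE-style multiple
signals); no trans-eQTLs or conditional signals; no genotype imputation,
liftover, or reference-panel LD (inputs must share one genome build; LD is
in-cohort); kinship is consumed from a precomputed table, not estimated;
the case-control GWAS effect scale is a liability/logistic approximation
adequate for testing machinery, not for epidemiological realism.
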