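# Methods

`pleioscan` implements an integration pipeline that asks, for a set of
complex brain traits, which genes' molecular abundance (protein or mRNA)
carries evidence *consistent with a causal role* for each trait, how those
genes are shared within and across trait groups, and whether two groups'
causal genes interact physically more often than chance. This note records
the models, the defaults and why they hold, the simulator's scope, and the
numerical choices.

## The statistical pipeline

**Genetic correlation (LDSC).** For each trait the per-SNP chi-square is
regressed on `N*l_j/M` with a free intercept, where `l_j` is the SNP's LD
score (sum of adjusted squared correlations with neighbors within a 1 Mb
window; `r2_adj = r2 - (1-r2)/(n-2)` removes finite-panel bias); the slope
estimates SNP heritability and the intercept absorbs confounding. Pairwise
genetic correlation divides the slope of the `z1*z2` regression (whose free
intercept absorbs sample overlap) by `sqrt(h2_1*h2_2)`. SNPs with
chi-square > 80 are removed first, as very large effects dominate the
regression. Standard errors are delete-one block jackknives over 200
contiguous SNP blocks. Both regressions use heteroskedasticity weights
`1/(1 + N*h2_0*l/M)^2` derived from a single first-pass OLS fit; using the
*same* first-pass weights for the univariate and bivariate regressions makes
a trait regressed on itself return rg = 1 exactly.

**Heritability screen and weights.** Per-gene cis heritability (SNPs within
500 kb of the gene body, boundaries inclusive) is estimated by
Haseman-Elston regression of phenotype cross-products on cis-GRM entries:
closed-form, deterministic, no REML iterations. Its one-sided p comes from
a 100-block jackknife over samples. Genes with p < 0.01 outside the HLA
region (chr6:25-34 Mb, configurable) are declared heritable. Cis weights
come from the best of four models — marginal top-SNP, ridge (the BLUP
analog; penalty `m*(1-h2)/h2` from the HE estimate), lasso, and elastic net
(both with internally cross-validated penalties) — selected by 5-fold
cross-validated R²; a gene whose best model has CV R² <= 0 is dropped.
BSLMM is not implemented: its MCMC is out of scope at desk scale and ridge
is its point-mass-free limit, so the winner is typically among the retained
four on dense cis signals.

**PWAS/TWAS.** The gene-level statistic is `z = w'Z / sqrt(w'Rw)` with `w`
the trained weights, `Z` the harmonized GWAS z-vector and `R` the panel LD
submatrix (ridge-regularized by 1e-6). Weights and z-scores are both aligned
to the panel's allele coding, which makes the statistic invariant to any
SNP's allele flip. Weight SNPs missing from the summary statistics are
dropped, not imputed — deterministic and conservative. Benjamini-Hochberg
FDR is applied within trait; the significance gate is FDR p < 0.05.

**SMR and HEIDI.** Mediation of the SNP-trait association through abundance
is tested at the lead cis pQTL with
`T_SMR = z_g^2 z_p^2/(z_g^2 + z_p^2)` against chi-square(1). Because a
mediation signal can also arise from linkage (two distinct causal variants
in LD), HEIDI tests whether the ratio estimate `b_xy = b_GWAS/b_pQTL` is
homogeneous across LD-linked instruments: deviations `d_i` from the top
SNP's ratio are standardized with a delta-method covariance built from the
LD matrix, and the statistic `sum z_d_i^2` is referred to a positively
weighted sum of chi-square(1) with weights the eigenvalues of the deviation
correlation matrix. Instrument eligibility follows the SMR tool's published
defaults (pQTL p < 1.57e-3, r² to the top SNP in [0.05, 0.9], at most 20
SNPs, at least 3 to run); the source names no thresholds of its own.

**Weighted chi-square tail.** Evaluated by Ruben's mixture series (the sum
is rewritten as a nonnegative mixture of central chi-squares, so every term
is positive and the tail is accurate on the log scale) whenever the
eigenvalue ratio is below 1e4; otherwise Imhof's oscillatory integral, then
a Lugannani-Rice saddlepoint, then seeded Monte Carlo with 1e5 draws. The
method used is recorded per test. In the independence limit the result
matches the plain chi-square(k) tail to machine precision.

**COLOC.** Per-SNP Wakefield log approximate Bayes factors
(`0.5*log(1-r) + z^2 r/2`, `r = W/(W+se^2)`) for the GWAS and the pQTL scan
are combined by enumerating the five single-causal-variant hypotheses in
log space. Priors default to p1 = p2 = 1e-4, p12 = 1e-5 (the COLOC tool's
defaults; the source states none) and W = 0.15² on the standardized scale.
When only z and N are available, beta/se are reconstructed as
`se = 1/sqrt(N)`, `beta = z*se`.

**Causal calls.** Cis: XWAS FDR p < 0.05 AND either (SMR p < 0.05 and HEIDI
p > 0.05) or COLOC PP4 > 0.5; the published criterion D duplicates A and is
implemented once as the shared FDR gate. A gene whose HEIDI test was
skipped (fewer than 3 instruments) can qualify only through COLOC. Trans:
pQTL p < 5e-8 outside the 500 kb window, trans-SMR below Bonferroni
0.05/(number of significant trans-pQTLs) — an FDR switch exists because the
source's Results and Methods disagree on this rule — and HEIDI p > 0.05,
with SMR/HEIDI restricted to SNP-gene pairs at least 5 Mb apart and HEIDI
instruments drawn from the ±500 kb window around the trans instrument.

**Sharing and enrichment.** shared%(t, G) = 100 × |genes causal for t and
for at least one *other* trait in G| / |genes causal for t|; traits with no
calls print dashes. The Spearman correlation of rg against pairwise sharing
uses one observation per cross-group trait pair, sharing defined as
|intersection|/|second-group trait's causal set| (switchable; the pairing
construction is not fully specified in the source), with an exact
permutation p below 10 pairs. The PPI bootstrap redraws both causal sets
from the network universe preserving sizes and shared count, and
`p = (1 + #{s_i >= s0})/(N+1)` exactly, ties in the tail; fold = s0/mean.
Set members absent from the network are dropped before sizing (the
404-of-407 adjustment). Edges between two shared members count once —
a documented convention; the source is silent. Annotation enrichment
reports fold `(k/n)/(K/N_bg)` with both hypergeometric and Fisher one-sided
p against an *explicit* background size, never inferred, because published
analyses use different backgrounds in different places (18,215 for ontology
enrichment, a 20,338-protein proteome for the synaptic fold).

## The synthetic study

The generator emulates every input at desk scale with known planted truth.

*Genotypes.* Haplotypes are latent AR(1) Gaussians (within-block correlation
`rho^|i-j|`, rho = 0.9) thresholded at the MAF quantile (MAF ~ U[0.05,
0.5]); dosages are the sum of two haplotypes. 200 blocks of 100 SNPs at
10 kb spacing on 2 chromosomes give 20k SNPs; one 10 kb gene is centered in
each block. All summary-level LD uses the *exact dosage-scale* population
correlation implied by this copula (bivariate-normal rectangle
probabilities by Gauss-Legendre quadrature of Plackett's identity), so
panel-estimated LD scores and LD submatrices converge to the generating
matrices; using the latent matrix instead biased h2 by ~1.5x in early
testing.

*GWAS.* Simulated at summary level: per block `z ~ MVN(sqrt(N) R a, R)`.
Polygenic effects (h2 = 0.4 spread over all 20k SNPs, N = 50,000 per trait)
are drawn jointly across the 5 traits with the target genetic-correlation
matrix (0.5 within group, 0.2 between; groups: 2 psychiatric, 2
neurodegenerative, 1 brain-structure). Case/control traits are not modeled;
every downstream statistic consumes z-scores only. Optional noise
correlation emulates sample overlap (inflates the cross-trait intercept,
not rg).

*Molecular cohort.* 722 individuals (the real proteomic cohort's size) with
per-gene abundance = cis genetic value + optional trans genetic value +
covariate effect + Gaussian noise, each component rescaled so the realized
cis h² equals the target (0.3 by default — the parameter-recovery setting;
real brain proteomes average ~12% cis variance) and columns z-scaled.

*Planted truth.* 10 pleiotropic genes (mediation b_xy = 0.1, giving GWAS
|z| ~ 12 at the causal cis SNP, clearly above the polygenic background of
sd ~ 2-3); 5 linkage decoys (a trait-causal SNP at latent r² ~ 0.7 from the
protein-causal SNP, matched effect size); 3 trans links (standardized
effect 0.4 on abundance, mediated onto a trait by b_xy = 0.1, SNP on the
other chromosome); a PPI network over genes plus background symbols
(default 3000 nodes, edge probability 0.01, physical-evidence fraction 0.8)
with a planted 2.5-fold edge excess between a 404- and a 43-member set
sharing 13 symbols — the real study's set sizes; annotation sets with a
planted in-target fraction. One global seed; each stage hashes its name
into the stream, so any stage reruns identically in isolation.

*What a green test does not establish.* The generator has no population
structure, no MAF-dependent architecture, no imputation error, no
case/control ascertainment, and block-diagonal LD; calibration and recovery
results transfer to real data only insofar as those features do not
dominate. Because the polygenic background touches every SNP, most genes
carry *true* weak mediated signal — sensitivity is therefore measured on the
planted strong links and specificity on a fully null study, not on
"non-planted" genes of the default study. At this desk scale the 18 planted
large-effect loci occupy 9% of all LD blocks, which inflates the LDSC
intercept (~1.9) in the full default study; the rg *ratio* is unaffected in
expectation, and the parameter-recovery criterion for rg uses the pure
polygenic scenario it states.

## Numerical choices

- LD-score window 1 Mb; MAF filter >= 0.05 at merge; strand-ambiguous (A/T,
  C/G) SNPs always dropped during harmonization.
- Jackknife blocks: 200 (SNPs, LDSC), 100 (samples, HE).
- Lead pQTL = minimum p, ties broken by smaller position.
- Genotype PCs: randomized SVD, 10 components by default.
- HEIDI covariance regularization: eigenvalues clipped at 0; a matrix with
  eigenvalues below -1e-6 raises rather than silently proceeding.
- COLOC H3 term computed as `log1p(-exp(ls12 - ls1 - ls2))`; the inequality
  `S12 <= S1*S2` holds for nonnegative terms, so a single-SNP region gives
  PP3 = 0 exactly.
- Degenerate inputs: monomorphic SNPs standardize to zero columns; a perfect
  pQTL fit reports an infinite t (p = 0) rather than p = 1; empty clump
  lists are allowed; a trait with zero causal calls prints dashes.
- The PPI null canonicalizes set order before sampling so swapping set
  labels cannot change the null stream.

## Known limitations

- The heritability p-value estimator (HE + sample jackknife) is a
  documented divergence: the source reports cis-variance statistics but not
  its estimator.
- HEIDI's delta-method standardization is mildly anticonservative with
  moderate-strength instruments (type-I ~ 0.069 at the default cohort size
  versus 0.048 with near-asymptotic instruments); this is a property of the
  published test, not of this implementation, and sits within the
  calibration band the acceptance criteria allow.
- Weight training's CV fold assignment depends on sample order; the fitted
  predictor is stable under permutation but the sparse support may differ.
- Multi-SNP SMR, SuSiE-style multi-causal colocalization, conditional gene
  tests, partitioned heritability and liability-scale conversion are out of
  scope.
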