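# Methods

## Models

**Bivariate twin ACE model.** Each standardized trait is Y = A + C + E with
variance V_Y = V_A + V_C + V_E; dominance and interaction components are
fixed at zero. For a twin pair the 4-vector (twin1·trait1, twin1·trait2,
twin2·trait1, twin2·trait2) is zero-mean Gaussian. Within-twin cross-trait
covariance is ρ_A√(V_A1V_A2) + ρ_C√(V_C1V_C2) + ρ_E√(V_E1V_E2); cross-twin
same-trait covariance is r·V_A + V_C with r = 1 (MZ) or ½ (DZ); cross-twin
cross-trait covariance is r·ρ_A√(V_A1V_A2) + ρ_C√(V_C1V_C2). This matrix is
positive semi-definite for every admissible parameter value (W ± B are sums
of PSD component matrices), so no extra constraint is needed beyond
non-negative variances and correlations in [−1, 1].

The likelihood is full-information ML: each family contributes the Gaussian
density of its observed subvector (missing cells marginalized by dropping
rows/columns of the expected covariance). Families are grouped by
(zygosity, missingness pattern) so a likelihood evaluation costs one
Cholesky factorization per distinct pattern, independent of cohort size.

**Population-level SNP model.** For N unrelated individuals with GRM
A_jk = (1/M)Σ_i (x_ij − 2p_i)(x_ik − 2p_i)/(2p_i(1−p_i)), the stacked traits
(y1, y2) are zero-mean Gaussian with covariance blocks σ²_gk·A + σ²_ek·I and
cross-block ρ_G√(σ²_g1σ²_g2)·A + ρ_ε√(σ²_e1σ²_e2)·I. Writing A = VΛVᵀ and
rotating each trait by Vᵀ factorizes the density into N independent 2×2
blocks with per-eigenvalue covariance
[[σ²_g1λ+σ²_e1, ρ_G√(σ²_g1σ²_g2)λ+ρ_ε√(σ²_e1σ²_e2)], [·, σ²_g2λ+σ²_e2]],
so after one O(N³) eigendecomposition every likelihood evaluation is O(N) —
the property the MCMC depends on. Covariates (age, sex, genetic PCs) are
regressed out of the traits beforehand rather than modelled inside the
variance-component likelihood; no REML-style degrees-of-freedom correction
is applied for those fixed effects, a small-sample difference documented
here rather than corrected.

## Inference choices

- **Optimization.** Both fitters maximize over transformed coordinates
  (log variances, atanh correlations) with L-BFGS-B and multi-start (5 starts
  for the twin model, 3 for the SNP model; first start from moment
  estimates, the rest jittered from the run seed). Variances landing below
  1e-7 are reported as exactly 0. If a fitted genetic (or residual) variance
  is at the zero boundary, the attached correlation is unidentified — the
  covariance term is zero for any value — and is reported as 0 by
  convention.
- **Twin confidence intervals** are likelihood-profile intervals: the bound
  is where twice the profile log-likelihood drop equals the χ²₁ quantile,
  found by outward expansion plus bisection to 1e-4 in parameter units.
  Bounds that run into a domain edge (variance at 0, correlation at ±1) are
  reported at the edge and flagged one-sided.
- **MCMC.** Random-walk Metropolis on the transformed coordinates, with the
  uniform priors on the natural scale — variances U[0, 3·sample variance],
  correlations U[−1, 1] — carried into the transformed space by the exact
  Jacobian (Σ log V + Σ log(1−ρ²)). Defaults: 50,000 iterations, 10,000
  burn-in, thinning 10; a single global proposal scale adapts toward 25%
  acceptance during burn-in and is frozen afterwards, preserving detailed
  balance for the retained draws. Chains are initialized at the ML fit.
  Point estimates are posterior means; intervals are central quantiles.
- **Bayes factor** for ρ_G ≠ 0 is the Savage–Dickey ratio: prior density at
  0 (= ½) over a Gaussian-KDE (Silverman bandwidth) estimate of the marginal
  posterior at 0. When no draw falls within one bandwidth of 0 the KDE value
  is tail extrapolation, so the reported value is instead a rule-of-three
  lower bound (posterior density at 0 ≤ 3/(2·bw·n_draws)) and is flagged.
- **Permutation test.** The pairing of y2 against (genotypes, y1) is broken
  in the whitened domain: y2 is rotated into the GRM eigenbasis, divided by
  its fitted per-eigenvalue marginal standard deviation (making the
  coordinates exchangeable under the null), permuted, and re-colored. A
  naive permutation of sample labels would also destroy y2's own alignment
  with the GRM; the null refits would then have ŝ²_g2 ≈ 0 and an
  unidentified ρ̂_G whose absolute value piles up near 1, wrecking both
  calibration and power. The whitened scheme preserves y2's marginal genetic
  structure while destroying both cross-trait correlations. The statistic is
  |ρ̂_G| from the ML fit; P-values use the add-one estimator.
- **Parametric-bootstrap (simulation) test.** Fits the null model (ρ_G = 0,
  ρ_ε free), simulates trait pairs from it on the observed GRM, and
  re-estimates ρ̂_G. Under a strong alternative the constrained null fit
  shifts genetic variance into the residual (it must explain the cross-trait
  covariance through ρ_ε alone), so the bootstrap null re-creates the
  boundary-unidentifiability of ρ̂_G and the test is markedly less powerful
  than the permutation test (e.g. P = 0.20 vs 0.01 on the same cohort-scale
  replicate). Its type-I calibration is unaffected — under a true null the
  constrained and unconstrained fits coincide — which the self-consistency
  test confirms. Both tests are provided because the two null constructions
  answer slightly different questions; the permutation test is the
  recommended default.

## Synthetic cohorts

`synthgen` draws exactly from the assumed models, so estimator recovery is a
well-posed check. Twin pairs are 4-vector Gaussians from the ACE covariance;
age (uniform on [11, 13]) and sex (balanced, shared within MZ pairs) carry no
trait effect by default, so the residualization path can be exercised
without confounding the truth.

Unrelated cohorts have M unlinked Hardy–Weinberg SNPs, dosages
Binomial(2, p) with p uniform on the MAF range (default 0.05–0.5). Causal
variants split into a pleiotropic set (one effect shared by both traits) and
two trait-specific sets, with effects i.i.d. normal applied to
*standardized* dosages — equal per-variant variance contribution — so the
implied genetic correlation is c/√((c+s1)(c+s2)) up to effect-sampling
noise. Genetic values are rescaled so realized in-sample variance fractions
hit the requested heritabilities exactly, and residuals are orthogonalized
against the genetic values before scaling, removing one layer of Monte Carlo
noise from recovery targets. Deliberately absent: linkage disequilibrium,
population stratification, ascertainment, non-normal residuals, and sex
chromosomes. Because the SNPs are unlinked and all causal variants are in
the typed panel, SNP-heritability equals total genetic variance here —
passing recovery tests therefore validates the estimators under their own
assumptions, not robustness to LD, tagging loss, or confounding (the
directional tests for partial panels and PC-corrected stratification probe
those separately).

## Study conditions and problem sizes

The canonical experiments (`gencorr.experiments`) use the cohort's fitted
point estimates as generating truth: twin A/C/E = 0.66/0.14/0.20 (reading)
and 0.51/0.21/0.27 (mathematics) with ρ_A/ρ_C/ρ_E = 0.64/0.90/0.30; SNP
model h² = 0.27/0.52 with ρ_G = 0.74. The residual correlation ρ_ε = 0.545
is chosen so the model-implied phenotypic correlation equals the observed
r = 0.60 (0.60 = 0.74√(0.27·0.52) + ρ_ε√(0.73·0.48)). The twin study uses
2,794 pairs — the analyzed cohort size — split 1:1 MZ:DZ since the true
ratio is not published; 10 seeded replicates. The population study uses
N = 2,000 individuals and M = 4,000 SNPs with 1,000 causal variants per
trait (740 shared + 260 specific, giving ρ_G = 0.74 under equal effect
variance); 5 seeded replicates. Type-I calibration of the permutation test
runs at N = 300, M = 600 with 60 replicates of 39 permutations.

## Preprocessing conventions

- Inverse-normal transform: Φ⁻¹((rank − ½)/n) with ties averaged; the Blom
  constant was considered and rejected in favour of the symmetric ½ offset
  (the two differ negligibly at cohort sizes).
- Composites are unweighted means of the available (already normalized)
  scales, re-standardized; missing scales are dropped, not imputed.
- Twin-path residualization uses age + sex; the population path adds the
  leading genetic PCs (default 10). Trait standardization happens per trait
  across all individuals before pair assembly.
- Relatedness pruning reads GRM off-diagonals (threshold 0.05) with a greedy
  loop: repeatedly take the most related remaining pair and drop the member
  with more missing genotypes, ties broken toward keeping the
  lexicographically earlier id — deterministic and row-order invariant.
- GRM construction mean-imputes missing calls per variant (2p̂) only inside
  the computation, estimates allele frequencies in-sample, and drops
  variants with 2p̂(1−p̂) < 1e-6 rather than dividing by them.

## Numerical details

- Eigenvalues of the GRM in (−tol, 0) with tol = 1e-8·max(1, λ_max) are
  clamped to 0; anything more negative raises.
- The twin likelihood returns −∞ (not an exception) on singular pattern
  covariances, logged once.
- The pleiotropy bound's closed form (minimum shared fraction = ρ²) is
  verified at run time against a brute-force scan over the constraint
  surface: both the constraint ρ = c/√((c+s1)(c+s2)) and the objective
  c/(c+s1+s2) are scale-invariant, so the scan fixes c = 1 and sweeps s1
  with s2 solved exactly.

## Known limitations

- The decomposition shares assume standardized traits; with the published
  rounded inputs the A + C + E shares need not sum exactly to 1.
- Profile CIs are provided for the nine natural parameters; an interval for
  h² itself would need a reparameterized profile and is approximated by the
  V_A interval on standardized data.
- The ML fitter reports point estimates without standard errors; use the
  posterior or profile intervals for uncertainty.
- No BGEN/PLINK binary genotype input; VCF and a plain text dosage matrix
  only.
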