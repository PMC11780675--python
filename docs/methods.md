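# Methods

`potatovc` re-creates the variance- and covariance-component analysis
used for A-clone-stage evaluations of tetraploid potato: a network of
augmented field trials run by several breeding companies, tied together
by a small set of replicated check varieties, analyzed with a ladder of
linear mixed models fitted by REML. Because the plot data of such
programs are proprietary, the package pairs the analysis chain with a
synthetic-trial generator whose ground truth is known, so every
estimator can be scored by parameter recovery.

## The observation model

A plot value of clone *i* in column *m*, row *l*, block *k* of
environment *j* (a year-location combination of one company) is

    y_ijklm = mu + g_i + e_j + C_i (ge)_ij + b_kj + r_lkj + h_mkj + eps_ijklm

with `C_i` the 0/1 check indicator: only the replicated checks support a
genotype-by-environment interaction term. The model ladder varies which
effects are fixed and how the genotypic variance is structured:

* **base model** (`model2`) — all clone effects fixed; used for
  adjusted entry means (AEMs), outlier screening and the check-based
  corrections;
* **genotypic-variance model** (`model3`) — checks fixed, entries
  random with variance `sigma_g^2`; `model3het` additionally gives each
  environment its own residual variance `sigma_eps_j^2`;
* **market-segment model** (`model6`) — a fixed segment mean for
  entries (starch ST, table TA, crisps CR, french fries FF) and a
  heterogeneous genotypic variance per segment;
* **population models** (`model7`, `model7het`, `model8`) — entries
  from full-sib families with at least 6 clones ("population entries")
  decompose into a family effect (inter-population variance
  `sigma_p^2`) plus a within-family deviation (intra-population
  variance `sigma_a^2`, optionally one per family); smaller families
  contribute "single entries" with their own `sigma_g^2`; `model8` adds
  a family-by-environment interaction `sigma_pe^2`.

Heritability is reported on the entry-mean basis,
`h^2 = sigma_g^2 / (sigma_g^2 + nu)`, with `nu` the mean variance of a
difference of two adjusted entry means, and on the plot basis,
`h_plot^2 = sigma_g^2 / (sigma_g^2 + sigma_eps^2)`; with heterogeneous
residuals, `sigma_eps^2` is the mean residual variance across
environments. The entry-mean formula is implemented literally (the
classical form divides `nu` by two; `halve_nu=True` switches to it —
we do not guess which was intended and default to the literal ratio).

## REML engine

The restricted log-likelihood is evaluated through the mixed-model
equations: with `V = R + Z G Z'` and `W = [X Z]`,

    -2 l_R = (n-p) log 2 pi + log|R| + log|G| + log|C| + y'Py ,

where `C` is the MME coefficient matrix. All random factors are
categorical, so the cross-product blocks of `C` are assembled once per
residual group and reweighted during optimization; one likelihood
evaluation is a dense Cholesky factorization (problems here have a few
hundred to ~2000 mixed-model equations). Gradients are analytic,
`d l_R/d theta = -1/2 [tr(P dV) - y'P dV P y]`, and optimization runs
on the log-variance scale with L-BFGS-B (starting values: the
phenotypic variance split equally across components). Components whose
estimate falls below 1e-6 of the total variance are fixed at exactly
zero, flagged as boundary estimates, and the rest refitted — the same
convention as "variances fixed at their boundary" in dedicated mixed-
model software. Rank-deficient fixed-effect matrices are resolved by an
order-preserving greedy QR: a column is dropped only if it depends on
the columns before it, which keeps the restricted likelihood invariant
when redundant columns are added.

Equality constraints between components (used by the test of
`sigma_p^2 = sigma_a^2`) tie two design matrices to one shared variance
parameter. The comparison of inter- and intra-population variance is
reported both as the raw ratio with a naive F reference and as a
likelihood-ratio test of the equality constraint; the latter is primary
because the degrees of freedom of a variance-ratio F are not well
defined in unbalanced mixed models.

The bivariate engine stacks two traits (restricted to plots observing
both — pairwise-complete, which keeps the residual 2x2 structure exact)
and gives each random level and the residual an unstructured 2x2
covariance parameterized by its Cholesky factor, so estimates stay
positive semidefinite. Genotypic correlation is the entry-genotype
covariance over the geometric mean of the genotypic variances. The
phenotypic correlation is defined at plot level from the summed
genotype + check-GxE + residual covariances; row/column terms are
dropped from bivariate fits (singular information on augmented
designs), and the block term is retained. Perfectly collinear trait
pairs make the bivariate likelihood degenerate (a singular residual
covariance has unbounded density); they are detected and solved
analytically as the rank-one limit with correlation ±1.

Significance of random terms uses the naive chi-square LRT at
alpha = 0.05 (conservative at the boundary; a 50:50 chi0:chi1 mixture
is available via `mixture=True`).

## Preprocessing

Corrections run in a fixed order. (1) Raw plot yields are normalized
to a 16-plant plot; missing plants enter the denominator only when
they exceed 20% of the planted count (strict inequality), below that
full compensation by neighbours is assumed. (2) In an environment
split into two adjacent trials, the absolute difference of the trial
check means is subtracted from every plot of the higher trial.
(3) Outliers are plots whose conditional base-model residual exceeds
3.5 environment-specific (or pooled) residual standard deviations;
removal is single-pass by default (`iterate_outliers=True` repeats it —
the original procedure does not state whether it iterated). (4) The
check-based block correction generalizes the two-group trial rule to k
blocks — each block is centred on its environment's check mean — and is
applied only when the LRT on the block variance is significant at 0.05.
All corrections are location shifts and are logged shift by shift.

## Environment geometry

AMMI operates on the check-mean table (genotype x environment cell
means — replicates exist only for checks): additive main effects by
double centring, SVD of the interaction, singular value split evenly
between genotype and environment scores (symmetric scaling; the
reference analysis does not state its scaling, so this is configurable).
The generalized Procrustes analysis aligns the per-trait environment
configurations (first two interaction-score columns): each
configuration is centred and scaled once to unit norm, then iteratively
rotated against the leave-one-out mean until the consensus is stable
(tolerance 1e-8). Aligning against a consensus that contains the
configuration itself, or rescaling against a renormalized consensus
each round, both admit spurious fixed points — the two-configuration
closed form (residual `1 - sum of singular values`) is used as the
oracle for this. The reported consensus is rotated to principal axes
and scaled to unit size; residuals are on the standardized scale. The
optional company correction estimates a fixed breeding-company effect
from the checks (clone and company fixed; environment, clone-by-
environment, block, row, column random) and subtracts it, mirroring how
systematic scoring differences between companies are removed before
comparing environments across traits.

## Preselection study

Clones carry a discard status (0 kept; 1 discarded while siblings were
kept; 2 whole family discarded) marking what a single-hills visual
preselection would have removed. The genotypic variance of the reduced
set (status 0 plus checks) is compared with the mean over stratified
samples of the complete set at the reduced-set size, each sample
preserving the discard-status composition exactly (largest-remainder
rounding) and always containing the checks. The change statistic is
`Delta = (mean_strat - reduced) / mean_strat x 100` — the denominator
is the stratified mean, the reading consistent with the published
per-trait table (e.g. a trait whose reduced-set variance collapses to
zero gives exactly +100). AEM differences between discard groups are
tested per market segment with two-sided Welch t-tests,
Bonferroni-corrected within each trait x segment family (the published
analysis does not state the family; a pooled-variance variant and the
correction scope are flags). Correlation-matrix stability across the
complete / reduced / D12 subsets is assessed by pairwise Mantel tests
(Pearson correlation of off-diagonal elements; label permutations;
p = share of permuted |r| at or above the observed).

## Synthetic trials

The generator reproduces the design topology of the study it emulates:
3 companies x 5 year-location combinations (one location in the first
year, two in the later years), 8 common checks replicated 8 times per
environment and at least once per block, unreplicated entries grown
once per environment of their own company, blocks (8 for the first
company, 4 for the others by default) subdivided into rows and columns,
one designated 2021 environment split into two adjacent trials with the
checks replicated four times each and an additive trial offset (default
0.5 trait units) so the trial correction is exercised, plot plant
counts (default 16) with binomial missing plants (rate 0.02) feeding
the yield normalization. Families are assigned to companies round-robin
and to market segments explicitly (the real assignment is
pedigree-based and unavailable). All effects are Gaussian; ratings are
simulated on a continuous scale (an optional discretize step clips to
1-9, off by default because the analysis treats scores as continuous);
rows and columns are labels only — no spatial correlation model, since
plot adjacency is not part of the emulated design description.

What passing recovery tests show is that the estimators recover the
generating parameters under the model's own assumptions at the stated
design sizes; they do not certify behaviour under real-data features
the generator omits (non-Gaussian scores, spatial trend, outliers other
than the injected ones, non-random missingness).

`standardize_effects=True` rescales each drawn effect vector so its
sample variance equals the generating variance exactly. This is a
variance-reduction device for parameter-recovery experiments: with only
6 environments, the chi-square draw noise of the environment variance
(relative SD ~63% per replicate) would otherwise dominate the recovery
tolerance rather than measure the estimator. The default is plain
Gaussian draws.

## Problem sizes and test design

Recovery experiments run at 200 entries (20 families of 8 above the
population threshold, 10 families of 4 below) x 6 environments, with
80 replicates for the full heterogeneous-residual structure and 30 for
the segment/population structures; bivariate recovery runs 30
replicates at 150 entries x 5 environments; the permutation test is
calibrated on an exchangeable null (no family-mean structure, equal
within-family variances — label permutation destroys family means as
well as variance heterogeneity, so the p-value is uniform only under
full exchangeability) at 30 entries x 2 environments with n = 100
permutations. Permutation fits reuse the observed fit's estimates as
starting values. The permutation p uses strict ">" with no +1
correction, as specified for the emulated procedure.

## Known limitations

* Dense linear algebra only; the engine is sized for desk-scale
  problems (up to roughly 20k plots / 2000 equations), not for
  national-trial databases.
* No pedigree or genomic relationship matrices, no spatial models, no
  standard errors for heritabilities.
* Bivariate fits are pairwise; the assembled correlation matrices are
  not jointly positive semidefinite by construction.
* The naive LRT reference makes boundary tests conservative; the
  mixture reference is available but not the default.
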