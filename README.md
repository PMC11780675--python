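# potatovc

Variance and covariance components of augmented multi-environment
trials for clonal crops — a reusable implementation of the analysis
chain used for A-clone-stage evaluations of tetraploid potato, paired
with a synthetic-trial generator with known ground truth.

## Who this is for

Breeders and quantitative geneticists who analyze augmented designs:
a handful of replicated **check** varieties calibrate blocks and
environments, while the candidate **entries** (clones from full-sib
families, assigned to market segments such as starch, table, crisps or
french-fries use) are grown once per environment of their own breeding
program. From such data the package estimates the quantitative-genetic
parameters that drive resource-allocation decisions: variance
components, heritabilities, inter- vs intra-population variance,
genotypic and phenotypic correlations between traits, and the effect of
early visual preselection on later-stage genetic variability.

## The model at its core

The base observation model for a plot of clone *i* in environment *j*,
block *k*, row *l*, column *m* is

    y_ijklm = mu + g_i + e_j + C_i (ge)_ij + b_kj + r_lkj + h_mkj + eps_ijklm

where `C_i` filters the genotype-by-environment interaction to the
replicated checks. A ladder of REML-fitted variants estimates the
genotypic variance of the entries (optionally with heterogeneous
residual variance per environment), heterogeneous genotypic variances
per market segment, and the decomposition of the genotypic variance
into inter-population (`sigma_p^2`) and intra-population (`sigma_a^2`)
parts with a family-by-environment interaction. Heritability is
computed on the entry-mean basis, `h2 = sigma_g^2/(sigma_g^2 + nu)`
with `nu` the mean variance of a difference of two adjusted entry
means, and on the plot basis,
`h2_plot = sigma_g^2/(sigma_g^2 + sigma_eps^2)`.

Around the core sit the standard pipeline stages: plot-yield
normalization to a 16-plant plot, trial- and check-based block
corrections, outlier screening at 3.5 standardized residuals, AMMI plus
generalized Procrustes analysis of environment similarity on the check
data, pairwise bivariate REML for genotypic/phenotypic correlation
matrices with threshold networks and Mantel comparisons, and a
stratified-resampling study of the preselection effect. The REML
engine (mixed-model equations, analytic gradients, boundary handling
for collapsing components) is implemented in `potatovc.reml`; see
`docs/methods.md` for the full model and algorithm description.

## Worked example

```python
import numpy as np
from potatovc import (SyntheticScenario, FamilySpec, TraitSpec,
                      generate_design, simulate_trait, fit_reml,
                      model_spec, prepare_frame, compute_heritabilities)

families = tuple(FamilySpec(f"F{i:02d}", 8, ["ST", "TA", "CR", "FF"][i % 4])
                 for i in range(12))
scenario = SyntheticScenario(
    n_companies=1, environments_per_company=4, families=families,
    blocks_per_env=2, rows_per_block=10, cols_per_block=10,
    split_trial=False, seed=0,
)
design = generate_design(scenario)
trait = TraitSpec("STA", sigma_g2=0.6, sigma_e2=0.3, sigma_ge2=0.2,
                  sigma_b2=0.05, sigma_r2=0.05, sigma_h2=0.05,
                  sigma_eps2=0.4)
plots = simulate_trait(design, trait, seed=103)
fit = fit_reml(prepare_frame(plots), model_spec("model3", "STA"))
print(f"sigma_g2   = {fit.varcomp['entries']:.3f}  (simulated 0.6)")
print(f"sigma_e2   = {fit.varcomp['environment']:.3f}  (simulated 0.3)")
print(f"sigma_ge2  = {fit.varcomp['check_gxe']:.3f}  (simulated 0.2)")
print(f"sigma_eps2 = {fit.resid:.3f}  (simulated 0.4)")
h = compute_heritabilities(plots, "STA")
print(f"h2 = {h.h2:.2f}   h2_plot = {h.h2_plot:.2f}")
```

prints

```
sigma_g2   = 0.603  (simulated 0.6)
sigma_e2   = 0.241  (simulated 0.3)
sigma_ge2  = 0.170  (simulated 0.2)
sigma_eps2 = 0.376  (simulated 0.4)
h2 = 0.74   h2_plot = 0.62
```

The 96 simulated entries, grown once in each of four environments,
recover the generating genotypic variance (0.603 vs 0.6); the
environment variance rests on only four environment draws, so its
single-dataset estimate scatters more. `h2 = 0.74` says that 74% of
the variance among adjusted entry means is genetic at this design's
replication; `h2_plot = 0.62` is the single-plot signal-to-noise ratio.

The same stages are scriptable from the shell (`potatovc simulate |
preprocess | fit | heritability | populations | gxe | correlate |
preselection`), each consuming the previous stage's CSV.

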