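"""The model ladder: from the across-environment base model to
population decomposition.

This module wires the REML engine to the specific model sequence used
for augmented potato trials:

* base model (``model2``): all clone effects fixed; environment,
  check-by-environment interaction, block, row and column random —
  the model behind adjusted entry means and outlier screening;
* genotypic-variance model (``model3``): check genotypes fixed, entries
  random; optionally with heterogeneous residual variance per
  environment (``model3het``);
* market-segment model (``model6``): fixed segment means plus a
  heterogeneous genotypic variance per segment;
* population models (``model7``/``model8``): entries split into
  population entries (families with >= ``min_family`` clones) and
  single entries, decomposing the genotypic variance into
  inter-population (sigma_p^2) and intra-population (sigma_a^2) parts,
  optionally heterogeneous per family, plus a population-environment
  interaction (sigma_pe^2) in ``model8``.

It also provides the two heritability measures, the permutation test
for heterogeneous intra-population variances, the inter- vs intra-
population comparisons, and the variance-mean association.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, f as f_dist, fisher_exact, pearsonr

from .reml import (
    FitResult,
    RandomTerm,
    ReMLError,
    VarianceModelSpec,
    adjusted_entry_means,
    fit_reml,
    lrt,
    pairwise_difference_variance,
)

__all__ = [
    "prepare_frame",
    "model_spec",
    "heritability_entry_mean",
    "heritability_plot",
    "HeritabilityResult",
    "compute_heritabilities",
    "fit_market_segments",
    "decompose_populations",
    "permutation_test_heterogeneous_intra",
    "population_environment_interaction",
    "variance_mean_association",
    "PopulationDecomposition",
]


def prepare_frame(df: pd.DataFrame, min_family: int = 6) -> pd.DataFrame:
    """Derive the combined factor columns the ladder models need.

    Adds check-by-environment and family-by-environment interaction
    keys, and (re)computes the population-entry / single-entry split:
    entries from families with at least ``min_family`` clones are
    population entries, the rest are single entries.
    """
    out = df.copy()
    out["clone_env"] = (
        out["clone_id"].astype(str) + "@" + out["environment_id"].astype(str)
    )
    out["fam_env"] = (
        out["family_id"].astype(str) + "@" + out["environment_id"].astype(str)
    )
    ent = out.loc[out["is_entry"] == 1]
    fam_sizes = ent.groupby("family_id")["clone_id"].nunique()
    pop_fams = set(fam_sizes.index[fam_sizes >= min_family])
    is_pop = (
        (out["is_entry"] == 1) & out["family_id"].isin(pop_fams)
    ).astype(int)
    out["is_population_entry"] = is_pop
    out["is_single_entry"] = ((out["is_entry"] == 1) & (is_pop == 0)).astype(int)
    return out


_BASE_RANDOM = (
    RandomTerm("environment", "environment_id"),
    RandomTerm("check_gxe", "clone_env", filter="is_check"),
    RandomTerm("block", "block_id"),
    RandomTerm("row", "row_id"),
    RandomTerm("col", "col_id"),
)


def model_spec(name: str, trait: str) -> VarianceModelSpec:
    """Named presets of the model ladder for one trait column."""
    if name == "model2":
        return VarianceModelSpec(
            trait, ("1", "C(clone_id)"), _BASE_RANDOM
        )
    if name == "model2_noblock":
        return VarianceModelSpec(
            trait, ("1", "C(clone_id)"),
            tuple(t for t in _BASE_RANDOM if t.name != "block"),
        )
    if name in ("model3", "model3het"):
        return VarianceModelSpec(
            trait,
            ("1", "C(clone_id)|is_check"),
            (RandomTerm("entries", "clone_id", filter="is_entry"),)
            + _BASE_RANDOM,
            residual_by="environment_id" if name == "model3het" else None,
        )
    if name == "model6":
        return VarianceModelSpec(
            trait,
            ("1", "C(clone_id)|is_check", "C(segment)|is_entry"),
            (RandomTerm("entries_by_segment", "clone_id",
                        filter="is_entry", by="segment"),)
            + _BASE_RANDOM,
        )
    if name in ("model7", "model7het", "model8"):
        a_term = RandomTerm(
            "within_family", "clone_id", filter="is_population_entry",
            by="family_id" if name == "model7het" else None,
        )
        extra = ()
        if name == "model8":
            extra = (RandomTerm("pop_env", "fam_env",
                                filter="is_population_entry"),)
        return VarianceModelSpec(
            trait,
            ("1", "C(clone_id)|is_check"),
            (RandomTerm("population", "family_id",
                        filter="is_population_entry"),
             a_term,
             RandomTerm("single_entries", "clone_id",
                        filter="is_single_entry"))
            + extra + _BASE_RANDOM,
        )
    raise ValueError(f"unknown model preset {name!r}")


# ---------------------------------------------------------------------------
# heritability


def heritability_entry_mean(
    sigma_g2: float, nu_hat: float, halve_nu: bool = False
) -> float:
    """Entry-mean heritability ``sigma_g^2 / (sigma_g^2 + nu_hat)``.

    ``nu_hat`` is the mean variance of a difference of two adjusted
    entry means.  ``halve_nu=True`` uses ``nu_hat / 2`` instead, the
    form in which the mean difference variance enters the classical
    entry-mean heritability; the literal ratio is the default.
    """
    if sigma_g2 < 0 or nu_hat < 0:
        raise ValueError("variances must be non-negative")
    if sigma_g2 == 0 and nu_hat == 0:
        raise ValueError("heritability undefined when both inputs are zero")
    nu = nu_hat / 2.0 if halve_nu else nu_hat
    return sigma_g2 / (sigma_g2 + nu)


def heritability_plot(sigma_g2: float, sigma_eps2: float) -> float:
    """Plot-basis heritability ``sigma_g^2 / (sigma_g^2 + sigma_eps^2)``.

    With heterogeneous residuals, pass the mean residual variance
    across environments as ``sigma_eps2``.
    """
    if sigma_g2 < 0 or sigma_eps2 < 0:
        raise ValueError("variances must be non-negative")
    if sigma_g2 == 0 and sigma_eps2 == 0:
        raise ValueError("heritability undefined when both inputs are zero")
    return sigma_g2 / (sigma_g2 + sigma_eps2)


@dataclass
class HeritabilityResult:
    trait: str
    h2: float
    h2_plot: float
    sigma_g2: float
    nu_hat: float
    sigma_eps2: float


def compute_heritabilities(
    df: pd.DataFrame,
    trait: str,
    heterogeneous_residuals: bool = False,
    halve_nu: bool = False,
) -> HeritabilityResult:
    """Both heritability measures for one trait.

    Fits the base model (clones fixed) for the pairwise-difference
    variance of the entry means, and the genotypic-variance model
    (entries random, optionally heterogeneous residuals) for
    ``sigma_g^2`` and the residual variance.
    """
    df = prepare_frame(df)
    fit2 = fit_reml(df, model_spec("model2", trait))
    entries = sorted(df.loc[df["is_entry"] == 1, "clone_id"].unique())
    nu = pairwise_difference_variance(fit2, "clone_id", entries=entries)
    fit3 = fit_reml(
        df, model_spec("model3het" if heterogeneous_residuals else "model3",
                       trait)
    )
    sg2 = fit3.varcomp["entries"]
    se2 = fit3.mean_resid()
    return HeritabilityResult(
        trait=trait,
        h2=heritability_entry_mean(sg2, nu, halve_nu=halve_nu),
        h2_plot=heritability_plot(sg2, se2),
        sigma_g2=sg2,
        nu_hat=nu,
        sigma_eps2=se2,
    )


# ---------------------------------------------------------------------------
# market segments


def fit_market_segments(df: pd.DataFrame, trait: str) -> dict:
    """Heterogeneous per-segment genotypic variances plus their tests.

    Returns the per-segment variances, the LRT of variance
    heterogeneity against the homogeneous model, and both tests of the
    segment mean effect (LRT of the fixed segment term via profile
    comparison is not available under REML, so a Wald chi-square on the
    fixed segment means is reported together with the heterogeneity
    LRT).  Entries must span at least two segments.
    """
    df = prepare_frame(df)
    ent = df.loc[df["is_entry"] == 1]
    seg_counts = ent.groupby("segment")["clone_id"].nunique()
    if (df[trait].notna() & (df["is_entry"] == 1)).sum() == 0:
        raise ReMLError(f"trait {trait!r} has no entry observations")
    segs = seg_counts.index.tolist()
    if len(segs) < 2:
        raise ReMLError("market-segment analysis needs at least two segments")
    small = seg_counts.index[seg_counts < 2].tolist()
    if small:
        import warnings

        warnings.warn(
            f"segments with fewer than two entries pooled into baseline: {small}"
        )
    fit_het = fit_reml(df, model_spec("model6", trait))
    # homogeneous counterpart: same fixed effects, single entry variance
    hom_spec = VarianceModelSpec(
        trait,
        ("1", "C(clone_id)|is_check", "C(segment)|is_entry"),
        (RandomTerm("entries", "clone_id", filter="is_entry"),)
        + _BASE_RANDOM,
    )
    fit_hom = fit_reml(df, hom_spec)
    n_seg = len(fit_het.varcomp["entries_by_segment"])
    het_stat, het_p = lrt(fit_het, fit_hom, df=max(1, n_seg - 1))

    # Wald test of the fixed segment means (joint equality)
    seg_labels = [f"segment[{s}]" for s in segs
                  if f"segment[{s}]" in fit_het.beta.index]
    wald_stat = np.nan
    wald_p = np.nan
    if len(seg_labels) >= 2:
        b = fit_het.beta[seg_labels].to_numpy()
        V = fit_het.fixed_cov.loc[seg_labels, seg_labels].to_numpy()
        k = len(b)
        D = np.eye(k - 1, k) - np.eye(k - 1, k, 1)  # successive differences
        d = D @ b
        Vd = D @ V @ D.T
        wald_stat = float(d @ np.linalg.solve(Vd, d))
        wald_p = float(chi2.sf(wald_stat, k - 1))

    return {
        "segment_variances": fit_het.varcomp["entries_by_segment"],
        "heterogeneity_lrt": (het_stat, het_p),
        "segment_effect_wald": (wald_stat, wald_p),
        "fit_het": fit_het,
        "fit_hom": fit_hom,
    }


# ---------------------------------------------------------------------------
# populations


@dataclass
class PopulationDecomposition:
    trait: str
    sigma_p2: float
    sigma_a2: float
    sigma_g2_single: float | None
    f_ratio: float | None
    f_ratio_p: float | None
    equality_lrt: tuple | None
    family_variances: dict | None = None
    permutation_p: float | None = None
    family_means: pd.Series | None = None
    variance_mean_correlation: float | None = None
    zero_variance_share: float | None = None
    fit: FitResult | None = None
    fit_het: FitResult | None = None


def decompose_populations(
    df: pd.DataFrame,
    trait: str,
    min_family: int = 6,
    heterogeneous: bool = False,
) -> PopulationDecomposition:
    """Inter- vs intra-population decomposition of the genotypic variance.

    Families with fewer than ``min_family`` clones collapse their
    members into single entries.  The comparison of ``sigma_p^2`` and
    ``sigma_a^2`` is reported both as the raw variance ratio with a
    naive F reference and as an LRT of the equality constraint
    ``sigma_p^2 = sigma_a^2`` (the primary p-value: the degrees of
    freedom of a variance-ratio F in an unbalanced mixed model are not
    well defined).
    """
    df = prepare_frame(df, min_family=min_family)
    if df["is_population_entry"].sum() == 0:
        raise ReMLError(
            f"no family reaches the population threshold ({min_family})"
        )
    fit = fit_reml(df, model_spec("model7", trait))
    sp2 = fit.varcomp["population"]
    sa2 = fit.varcomp["within_family"]
    sg2 = fit.varcomp.get("single_entries")

    n_fam = df.loc[df["is_population_entry"] == 1, "family_id"].nunique()
    n_within = int(df.loc[df["is_population_entry"] == 1, "clone_id"].nunique())
    f_ratio = sp2 / sa2 if sa2 > 0 else np.inf
    # naive F reference with level counts as degrees of freedom
    f_p = (
        float(2 * min(f_dist.sf(f_ratio, n_fam - 1, n_within - n_fam),
                      f_dist.cdf(f_ratio, n_fam - 1, n_within - n_fam)))
        if np.isfinite(f_ratio) else 0.0
    )

    eq_fit = _fit_equal_pa(df, trait)
    eq_stat = max(0.0, 2.0 * (fit.loglik - eq_fit.loglik))
    eq_p = float(chi2.sf(eq_stat, 1)) if eq_stat > 0 else 1.0

    out = PopulationDecomposition(
        trait=trait,
        sigma_p2=sp2,
        sigma_a2=sa2,
        sigma_g2_single=sg2,
        f_ratio=f_ratio,
        f_ratio_p=f_p,
        equality_lrt=(eq_stat, eq_p),
        fit=fit,
    )

    if heterogeneous:
        fit_het = fit_reml(df, model_spec("model7het", trait))
        fam_vars = dict(fit_het.varcomp["within_family"])
        out.fit_het = fit_het
        out.family_variances = fam_vars
        if fam_vars:
            out.zero_variance_share = float(
                np.mean([v == 0.0 for v in fam_vars.values()])
            )
    return out


def _fit_equal_pa(df: pd.DataFrame, trait: str) -> FitResult:
    """Population model with sigma_p^2 constrained equal to sigma_a^2.

    The family-mean and within-family terms are tied to one shared
    variance parameter, so the combined design ``[Z_p  Z_a]`` carries a
    single sigma^2 — the null of the equality test.
    """
    spec = VarianceModelSpec(
        trait,
        ("1", "C(clone_id)|is_check"),
        (RandomTerm("population", "family_id",
                    filter="is_population_entry", tie="pa_equal"),
         RandomTerm("within_family", "clone_id",
                    filter="is_population_entry", tie="pa_equal"),
         RandomTerm("single_entries", "clone_id",
                    filter="is_single_entry"))
        + _BASE_RANDOM,
    )
    return fit_reml(df, spec)


def permutation_test_heterogeneous_intra(
    df: pd.DataFrame,
    trait: str,
    n_perm: int = 100,
    seed: int = 0,
    min_family: int = 6,
) -> dict:
    """Permutation test of heterogeneous intra-population variances.

    Entry clones are randomly reassigned to the populations (family
    sizes preserved) ``n_perm`` times; the p-value is the share of
    permuted fits with a restricted log-likelihood above the observed
    one (strict inequality, no small-sample correction).  Permutation
    fits that fail to converge are dropped and the p-value computed
    over the convergent ones.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    df = prepare_frame(df, min_family=min_family)
    spec = model_spec("model7het", trait)
    observed = fit_reml(df, spec)
    rng = np.random.default_rng(seed)

    pop = df["is_population_entry"] == 1
    clones = df.loc[pop, ["clone_id", "family_id"]].drop_duplicates("clone_id")
    clone_ids = clones["clone_id"].to_numpy()
    fams = clones["family_id"].to_numpy()

    start = _start_values(observed, spec)
    higher = 0
    used = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(clone_ids))
        mapping = dict(zip(clone_ids, fams[perm]))
        work = df.copy()
        mask = work["is_population_entry"] == 1
        work.loc[mask, "family_id"] = work.loc[mask, "clone_id"].map(mapping)
        try:
            fperm = fit_reml(work, spec, start=start)
        except Exception:
            continue
        used += 1
        if fperm.loglik > observed.loglik:
            higher += 1
    if used == 0:
        raise ReMLError("no permutation fit converged")
    return {
        "p": higher / used,
        "n_used": used,
        "observed_loglik": observed.loglik,
        "fit": observed,
    }


def _start_values(fit: FitResult, spec: VarianceModelSpec) -> np.ndarray:
    """Starting variances for ``spec`` taken from a previous fit.

    Boundary zeros are floored at a small share of the total variance
    so the optimizer can leave them again.
    """
    total = fit.total_variance() or 1.0
    floor = 1e-3 * total
    vals: list[float] = []
    for term in spec.random:
        est = fit.varcomp.get(term.name)
        if term.by is None:
            vals.append(max(floor, est if isinstance(est, float) else floor))
        else:
            groups = est if isinstance(est, dict) else {}
            for g in sorted(groups):
                vals.append(max(floor, groups[g]))
    if isinstance(fit.resid, dict):
        vals.extend(max(floor, v) for v in fit.resid.values())
    else:
        vals.append(max(floor, fit.resid))
    return np.asarray(vals)


def population_environment_interaction(
    df: pd.DataFrame, trait: str, min_family: int = 6
) -> dict:
    """Population-environment interaction variance and its LRT.

    Fits the population model with a family-by-environment term
    (intra-population variance homogeneous) and compares against the
    model without it.  Also reports the ratio of sigma_pe^2 to the
    checks' GxE variance.
    """
    df = prepare_frame(df, min_family=min_family)
    pop = df.loc[df["is_population_entry"] == 1]
    if pop.empty:
        raise ReMLError("no population entries")
    if pop.groupby("family_id")["environment_id"].nunique().max() < 2:
        raise ReMLError(
            "population-environment interaction requires populations in "
            "at least two environments"
        )
    fit8 = fit_reml(df, model_spec("model8", trait))
    fit7 = fit_reml(df, model_spec("model7", trait))
    stat, p = lrt(fit8, fit7, df=1)
    spe2 = fit8.varcomp["pop_env"]
    sge2 = fit8.varcomp["check_gxe"]
    return {
        "sigma_pe2": spe2,
        "lrt": (stat, p),
        "ratio_to_check_gxe": spe2 / sge2 if sge2 > 0 else np.inf,
        "fit": fit8,
        "fit_reduced": fit7,
    }


def variance_mean_association(
    family_variances: dict, family_means: pd.Series | dict
) -> float:
    """Pearson correlation between family variance and family mean AEM.

    Returns NaN when either vector is constant (undefined correlation).
    """
    fams = sorted(set(family_variances) & set(pd.Series(family_means).index))
    if len(fams) < 3:
        raise ValueError("need at least three families")
    v = np.array([family_variances[f] for f in fams], dtype=float)
    m = pd.Series(family_means).loc[fams].to_numpy(dtype=float)
    if np.allclose(v, v[0]) or np.allclose(m, m[0]):
        return float("nan")
    return float(pearsonr(v, m)[0])


def trait_class_enrichment(
    inter_higher: dict, trait_classes: dict
) -> tuple[float, float]:
    """Fisher's exact test: trait class (A/Q) vs inter > intra membership.

    ``inter_higher`` maps trait -> bool (sigma_p^2 > sigma_a^2);
    ``trait_classes`` maps trait -> "agronomic" | "quality".
    Returns (odds ratio, p).
    """
    table = np.zeros((2, 2), dtype=int)
    for t, hi in inter_higher.items():
        cls = trait_classes[t]
        table[0 if cls == "quality" else 1, 0 if hi else 1] += 1
    odds, p = fisher_exact(table)
    return float(odds), float(p)
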