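"""Genotypic and phenotypic trait correlations from bivariate fits.

All trait pairs are analyzed with the bivariate REML engine (check
genotypes fixed, entry genotypes random, row/column terms dropped); the
genotypic correlation is the entry-genotype covariance scaled by the
geometric mean of the genotypic variances, and the phenotypic
correlation is defined at plot level from the summed component
covariances (genotype + check GxE + residual).  The module assembles
full correlation matrices, derives threshold networks, compares
matrices by Mantel's permutation test and computes market-segment
specific correlations with their across-segment spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bivariate import BivariateFitResult, fit_bivariate_reml
from .ladder import prepare_frame

__all__ = [
    "TraitCorrelationSet",
    "fit_bivariate",
    "correlation_matrices",
    "correlation_network",
    "mantel_test",
    "segment_specific_correlations",
]

PHENOTYPIC_LEVELS = ("entries", "check_gxe", "residual")


@dataclass
class PairCorrelation:
    trait_a: str
    trait_b: str
    r_g: float
    r_p: float
    cov_g: float
    cov_ge: float
    cov_eps: float
    converged: bool
    fit: BivariateFitResult | None = None


@dataclass
class TraitCorrelationSet:
    """Pairwise genotypic/phenotypic correlations over a trait list."""

    traits: list
    pairs: list = field(default_factory=list)

    def matrix(self, which: str = "r_g") -> pd.DataFrame:
        mat = pd.DataFrame(
            np.eye(len(self.traits)), index=self.traits, columns=self.traits
        )
        for p in self.pairs:
            val = getattr(p, which)
            mat.loc[p.trait_a, p.trait_b] = val
            mat.loc[p.trait_b, p.trait_a] = val
        return mat


def _phenotypic_correlation(
    fit: BivariateFitResult, entry_mean_level: bool = False
) -> float:
    """Plot-level phenotypic correlation from the component covariances.

    Sums the covariances of the levels estimable for entries (genotype,
    check GxE, residual) over the matching variance sums.  With
    ``entry_mean_level=True`` only the genotype and a residual shrunken
    by the fit is used (entry-mean level definition).
    """
    levels = ("entries",) if entry_mean_level else PHENOTYPIC_LEVELS
    num = 0.0
    va = 0.0
    vb = 0.0
    for lev in levels:
        S = fit.resid if lev == "residual" else fit.covariances.get(lev)
        if S is None:
            continue
        num += S[0, 1]
        va += S[0, 0]
        vb += S[1, 1]
    denom = np.sqrt(va * vb)
    return float(num / denom) if denom > 0 else float("nan")


def fit_bivariate(
    df: pd.DataFrame,
    trait_a: str,
    trait_b: str,
    entry_mean_level: bool = False,
) -> PairCorrelation:
    """Component covariances and both correlations for one trait pair."""
    work = prepare_frame(df) if "clone_env" not in df.columns else df
    fit = fit_bivariate_reml(work, trait_a, trait_b)
    Sg = fit.covariances.get("entries", np.zeros((2, 2)))
    Sge = fit.covariances.get("check_gxe", np.zeros((2, 2)))
    return PairCorrelation(
        trait_a=trait_a,
        trait_b=trait_b,
        r_g=fit.correlation("entries"),
        r_p=_phenotypic_correlation(fit, entry_mean_level=entry_mean_level),
        cov_g=float(Sg[0, 1]),
        cov_ge=float(Sge[0, 1]),
        cov_eps=float(fit.resid[0, 1]),
        converged=fit.converged,
        fit=fit,
    )


def correlation_matrices(
    df: pd.DataFrame, traits: list[str]
) -> TraitCorrelationSet:
    """All pairwise bivariate fits over ``traits``.

    Non-convergent pairs are retained with their flag so callers can
    exclude them from networks.
    """
    work = prepare_frame(df)
    out = TraitCorrelationSet(traits=list(traits))
    for i, a in enumerate(traits):
        for b in traits[i + 1:]:
            try:
                out.pairs.append(fit_bivariate(work, a, b))
            except Exception:
                out.pairs.append(PairCorrelation(
                    a, b, np.nan, np.nan, np.nan, np.nan, np.nan, False
                ))
    return out


def correlation_network(
    matrix: pd.DataFrame, threshold: float = 0.25, strong: float = 0.5
):
    """Undirected graph with edges where ``|r| > threshold``.

    Edges with ``|r| > strong`` carry ``strong=True``.  Requires a
    symmetric matrix; NaN entries yield no edge.
    """
    import networkx as nx

    vals = matrix.to_numpy(dtype=float)
    if matrix.shape[0] != matrix.shape[1] or not np.allclose(
        vals, vals.T, equal_nan=True
    ):
        raise ValueError("correlation matrix must be symmetric")
    G = nx.Graph()
    G.add_nodes_from(matrix.index)
    traits = list(matrix.index)
    for i, a in enumerate(traits):
        for j in range(i + 1, len(traits)):
            r = vals[i, j]
            if np.isfinite(r) and abs(r) > threshold:
                G.add_edge(a, traits[j], r=float(r),
                           strong=bool(abs(r) > strong))
    return G


def mantel_test(
    matrix_a: pd.DataFrame,
    matrix_b: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel's permutation test between two trait-correlation matrices.

    The statistic is the Pearson correlation of the off-diagonal
    elements; the null distribution permutes the trait labels of one
    matrix (rows and columns jointly).  ``p`` is the share of permuted
    ``|r|`` at or above the observed ``|r|``.  Pairs where either
    matrix is NaN are excluded consistently.
    """
    if list(matrix_a.index) != list(matrix_b.index):
        raise ValueError("matrices must share the same trait order")
    A = matrix_a.to_numpy(dtype=float)
    B = matrix_b.to_numpy(dtype=float)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise ValueError("matrices must be square and of equal size")
    k = A.shape[0]
    iu = np.triu_indices(k, 1)

    def corr(Bp):
        a, b = A[iu], Bp[iu]
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 3:
            return np.nan
        return np.corrcoef(a[ok], b[ok])[0, 1]

    r_obs = corr(B)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(k)
        if abs(corr(B[np.ix_(perm, perm)])) >= abs(r_obs):
            hits += 1
    return float(r_obs), hits / n_perm


def segment_specific_correlations(
    df: pd.DataFrame,
    traits: list[str],
    sd_threshold: float = 0.2,
) -> dict:
    """Genotypic correlations per market segment and their spread.

    Fits the bivariate model separately within each segment (checks are
    retained in every subset so the GxE term stays estimable).  Traits
    missing entirely in any segment are skipped for that segment, and
    the across-segment standard deviation per pair is computed over the
    segments that produced a convergent estimate.
    """
    work = prepare_frame(df)
    ent = work.loc[work["is_entry"] == 1]
    segments = sorted(ent["segment"].astype(str).unique())
    if len(segments) < 2:
        raise ValueError("need at least two segments")
    per_segment = {}
    for seg in segments:
        sub = work.loc[
            (work["is_check"] == 1)
            | ((work["is_entry"] == 1) & (work["segment"].astype(str) == seg))
        ]
        usable = [
            t for t in traits
            if sub.loc[sub["is_entry"] == 1, t].notna().sum() > 0
        ]
        if len(usable) < 2:
            continue
        per_segment[seg] = correlation_matrices(sub, usable)
    sd = pd.DataFrame(np.nan, index=traits, columns=traits)
    flagged = []
    for i, a in enumerate(traits):
        for b in traits[i + 1:]:
            vals = []
            for seg, cset in per_segment.items():
                for p in cset.pairs:
                    if {p.trait_a, p.trait_b} == {a, b} and p.converged \
                            and np.isfinite(p.r_g):
                        vals.append(p.r_g)
            if len(vals) >= 2:
                s = float(np.std(vals, ddof=1))
                sd.loc[a, b] = sd.loc[b, a] = s
                if s > sd_threshold:
                    flagged.append((a, b, s))
    return {"per_segment": per_segment, "sd": sd, "flagged": flagged}
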