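"""Bivariate REML: 2x2 unstructured covariances at every random level.

Used to estimate genotypic and phenotypic covariances between trait
pairs.  The observation vector stacks the two traits, restricted to
plots on which both are observed; each random term (entry genotypes,
check-by-environment interaction, block) and the residual carry an
unstructured 2x2 covariance matrix across traits, parameterized by its
Cholesky factor so estimates stay positive semidefinite.  The restricted
log-likelihood is evaluated through the mixed-model equations exactly as
in the univariate engine; the cross-product matrices for the three row
patterns (trait A x A, B x B, A x B) are precomputed once, so each
evaluation reweights them with the entries of the inverse residual
covariance and factorizes the coefficient matrix.  Gradients are
analytic (differentials of the covariance entries chained through the
Cholesky parameterization).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .reml import (
    RandomTerm,
    ReMLError,
    _build_fixed,
    _build_random,
    _drop_rank_deficient,
)

__all__ = ["BivariateFitResult", "fit_bivariate_reml"]


@dataclass
class BivariateFitResult:
    """Per-level 2x2 covariance matrices of a bivariate fit.

    ``covariances`` maps term name -> 2x2 numpy array (trait A first);
    ``resid`` is the residual 2x2.  ``correlation(term)`` returns the
    correlation at one level, NaN if a variance is zero.
    """

    traits: tuple[str, str]
    covariances: dict
    resid: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    beta: pd.Series | None = None
    dropped: list = field(default_factory=list)

    def correlation(self, term: str) -> float:
        S = self.resid if term == "residual" else self.covariances[term]
        denom = np.sqrt(S[0, 0] * S[1, 1])
        if denom <= 0:
            return float("nan")
        return float(np.clip(S[0, 1] / denom, -1.0, 1.0))


def _chol_from_params(p):
    """(log l11, l21, log l22) -> 2x2 covariance and factor."""
    l11, l21, l22 = np.exp(p[0]), p[1], np.exp(p[2])
    L = np.array([[l11, 0.0], [l21, l22]])
    return L @ L.T, L


def _chain_jacobian(p):
    l11, l21, l22 = np.exp(p[0]), p[1], np.exp(p[2])
    # rows: parameters, cols: (sAA, sAB, sBB)
    return np.array([
        [2 * l11 ** 2, l11 * l21, 0.0],
        [0.0, l11, 2 * l21],
        [0.0, 0.0, 2 * l22 ** 2],
    ])


def _degenerate_fit(pr, trait_a, trait_b, fixed, random):
    """Analytic limit for ``y_b = c + s * y_a``: every level covariance
    is rank one with correlation sign(s)."""
    from .reml import VarianceModelSpec, fit_reml

    slope = np.polyfit(pr.ya, pr.yb, 1)[0]
    uni = fit_reml(pr.df, VarianceModelSpec(trait_a, fixed, random))
    covs = {}
    for tm in pr.terms:
        v = uni.varcomp.get(tm.term.name, 0.0)
        if isinstance(v, dict):
            v = float(np.mean(list(v.values())))
        covs[tm.term.name] = np.array([
            [v, slope * v], [slope * v, slope ** 2 * v]
        ])
    ve = uni.mean_resid()
    resid = np.array([[ve, slope * ve], [slope * ve, slope ** 2 * ve]])
    beta = pd.Series(
        np.concatenate([uni.beta.to_numpy(),
                        slope * uni.beta.to_numpy()]),
        index=pr.fixed_names[: 2 * len(uni.beta)],
    )
    return BivariateFitResult(
        traits=(trait_a, trait_b),
        covariances=covs,
        resid=resid,
        loglik=np.inf,
        converged=True,
        n_iter=0,
        beta=beta,
    )


class _BivariateProblem:
    def __init__(self, df, trait_a, trait_b, fixed, random):
        both = df[trait_a].notna() & df[trait_b].notna()
        df = df.loc[both].reset_index(drop=True)
        if len(df) == 0:
            raise ReMLError("no plots observe both traits")
        self.df = df
        self.n = len(df)
        self.ya = df[trait_a].to_numpy(dtype=float)
        self.yb = df[trait_b].to_numpy(dtype=float)

        Xb, names = _build_fixed(df, fixed)
        Xb, names, _ = _drop_rank_deficient(Xb, names)
        self.p_base = Xb.shape[1]
        self.fixed_names = (
            [f"{trait_a}:{n}" for n in names] + [f"{trait_b}:{n}" for n in names]
        )
        Zb, self.terms = _build_random(df, random)
        if any(tm.term.by is not None for tm in self.terms):
            raise ReMLError("bivariate terms cannot be group-heterogeneous")
        self.term_names = [tm.term.name for tm in self.terms]
        q = Zb.shape[1]
        self.p = 2 * self.p_base
        self.m = self.p + 2 * q

        # global column order: [X_A | X_B | termwise (A block | B block)]
        Xs = sp.csr_matrix(Xb)
        zero_x = sp.csr_matrix(Xb.shape)
        blocks_a = [Xs, zero_x]
        blocks_b = [zero_x, Xs]
        self.term_cols = {}
        offset = self.p
        for tm in self.terms:
            Zt = Zb[:, tm.start: tm.start + tm.levels.size]
            zero_z = sp.csr_matrix(Zt.shape)
            blocks_a += [Zt, zero_z]
            blocks_b += [zero_z, Zt]
            k = tm.levels.size
            self.term_cols[tm.term.name] = (
                np.arange(offset, offset + k),
                np.arange(offset + k, offset + 2 * k),
            )
            offset += 2 * k
        WA = sp.hstack(blocks_a, format="csr")  # rows of trait A
        WB = sp.hstack(blocks_b, format="csr")  # rows of trait B
        self.WA, self.WB = WA, WB

        self.A_AA = np.asarray((WA.T @ WA).todense())
        self.A_BB = np.asarray((WB.T @ WB).todense())
        self.A_AB = np.asarray((WA.T @ WB).todense())
        self.b_AA = WA.T @ self.ya
        self.b_AB = WA.T @ self.yb
        self.b_BA = WB.T @ self.ya
        self.b_BB = WB.T @ self.yb
        self.yy = np.array([
            self.ya @ self.ya, self.ya @ self.yb, self.yb @ self.yb
        ])
        self.n_par = 3 * (len(self.terms) + 1)

    # -- likelihood ---------------------------------------------------------

    def _split(self, theta):
        K = len(self.terms)
        covs = [
            _chol_from_params(theta[3 * i: 3 * i + 3])[0] for i in range(K)
        ]
        Se = _chol_from_params(theta[3 * K: 3 * K + 3])[0]
        return covs, Se

    def _assemble(self, theta):
        covs, Se = self._split(theta)
        det = Se[0, 0] * Se[1, 1] - Se[0, 1] ** 2
        if det <= 0 or Se[0, 0] <= 0:
            return None
        Sinv = np.array([[Se[1, 1], -Se[0, 1]], [-Se[0, 1], Se[0, 0]]]) / det
        a, g, b = Sinv[0, 0], Sinv[0, 1], Sinv[1, 1]
        M = a * self.A_AA + b * self.A_BB + g * (self.A_AB + self.A_AB.T)
        bvec = (a * self.b_AA + g * (self.b_AB + self.b_BA) + b * self.b_BB)
        yRy = a * self.yy[0] + 2 * g * self.yy[1] + b * self.yy[2]
        logR = self.n * np.log(det)

        C = M.copy()
        logG = 0.0
        for i, tm in enumerate(self.terms):
            S = covs[i]
            dS = S[0, 0] * S[1, 1] - S[0, 1] ** 2
            if dS <= 0 or S[0, 0] <= 0:
                return None
            Si = np.array([[S[1, 1], -S[0, 1]], [-S[0, 1], S[0, 0]]]) / dS
            ca, cb = self.term_cols[tm.term.name]
            C[ca, ca] += Si[0, 0]
            C[cb, cb] += Si[1, 1]
            C[ca, cb] += Si[0, 1]
            C[cb, ca] += Si[0, 1]
            logG += ca.size * np.log(dS)
        return covs, Se, Sinv, M, bvec, yRy, logR, logG, C

    def objective(self, theta):
        parts = self._assemble(theta)
        if parts is None:
            return np.inf, np.zeros(self.n_par)
        covs, Se, Sinv, M, bvec, yRy, logR, logG, C = parts
        try:
            cf = cho_factor(C, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return np.inf, np.zeros(self.n_par)
        chat = cho_solve(cf, bvec, check_finite=False)
        logC = 2.0 * np.sum(np.log(np.diag(cf[0])))
        yPy = yRy - bvec @ chat
        neg2 = (2 * self.n - self.p) * np.log(2 * np.pi) \
            + logR + logG + logC + yPy

        # gradient pieces
        Cinv = cho_solve(cf, np.eye(self.m), check_finite=False)
        a, g, b = Sinv[0, 0], Sinv[0, 1], Sinv[1, 1]
        ea = self.ya - self.WA @ chat
        eb = self.yb - self.WB @ chat
        ra = a * ea + g * eb           # rows of R^{-1} e, trait A slots
        rb = g * ea + b * eb
        u = self.WA.T @ ra + self.WB.T @ rb
        diagM = np.diag(M)
        T = Cinv @ M
        quadM = np.einsum("ij,ij->j", M, T)

        grad = np.zeros(self.n_par)
        for i, tm in enumerate(self.terms):
            ca, cb = self.term_cols[tm.term.name]
            # trace terms: t(x, y) = sum_j [Z_y' P Z_x]_{jj}
            t_aa = diagM[ca].sum() - quadM[ca].sum()
            t_bb = diagM[cb].sum() - quadM[cb].sum()
            t_ab = M[ca, cb].sum() - np.sum(M[:, cb] * T[:, ca])
            q_aa = float(u[ca] @ u[ca])
            q_bb = float(u[cb] @ u[cb])
            q_ab = float(u[ca] @ u[cb])
            d = np.array([
                t_aa - q_aa,            # d/d sAA
                2 * (t_ab - q_ab),      # d/d sAB
                t_bb - q_bb,            # d/d sBB
            ])
            grad[3 * i: 3 * i + 3] = _chain_jacobian(theta[3 * i: 3 * i + 3]) @ d

        # residual: tr(P dR) - r' dR r for the three covariance entries
        vA = np.vdot(Cinv, self.A_AA)
        vB = np.vdot(Cinv, self.A_BB)
        vX = np.vdot(Cinv, self.A_AB + self.A_AB.T)
        d_aa = (self.n * a
                - (a * a * vA + a * g * vX + g * g * vB)
                - float(ra @ ra))
        d_bb = (self.n * b
                - (g * g * vA + b * g * vX + b * b * vB)
                - float(rb @ rb))
        d_ab = (2 * self.n * g
                - (2 * a * g * vA + (a * b + g * g) * vX + 2 * b * g * vB)
                - 2 * float(ra @ rb))
        K = len(self.terms)
        grad[3 * K: 3 * K + 3] = _chain_jacobian(theta[3 * K:]) @ np.array(
            [d_aa, d_ab, d_bb]
        )
        return neg2, grad

    def solution(self, theta):
        parts = self._assemble(theta)
        covs, Se, Sinv, M, bvec, yRy, logR, logG, C = parts
        cf = cho_factor(C, lower=True, check_finite=False)
        chat = cho_solve(cf, bvec, check_finite=False)
        logC = 2.0 * np.sum(np.log(np.diag(cf[0])))
        neg2 = (2 * self.n - self.p) * np.log(2 * np.pi) \
            + logR + logG + logC + (yRy - bvec @ chat)
        return neg2, chat


def fit_bivariate_reml(
    df: pd.DataFrame,
    trait_a: str,
    trait_b: str,
    fixed: tuple = ("1", "C(clone_id)|is_check"),
    random: tuple = (
        RandomTerm("entries", "clone_id", filter="is_entry"),
        RandomTerm("environment", "environment_id"),
        RandomTerm("check_gxe", "clone_env", filter="is_check"),
        RandomTerm("block", "block_id"),
    ),
    maxiter: int = 400,
) -> BivariateFitResult:
    """Bivariate REML fit of two trait columns.

    The default model mirrors the across-environment base model with
    row and column terms dropped (they are not estimable in bivariate
    form on augmented designs) and the check genotypes fixed / entry
    genotypes random, which makes the genotypic covariance estimable.
    The intercept and every fixed term are trait-specific.

    Perfectly (anti)collinear trait pairs make the bivariate likelihood
    degenerate (a singular residual covariance has unbounded density);
    they are detected up front and solved analytically: one univariate
    fit supplies the variances, and every level's 2x2 is the exact
    rank-one limit with correlation +-1.
    """
    pr = _BivariateProblem(df, trait_a, trait_b, fixed, random)
    r_raw = np.corrcoef(pr.ya, pr.yb)[0, 1]
    if np.isfinite(r_raw) and 1.0 - abs(r_raw) < 1e-10:
        return _degenerate_fit(pr, trait_a, trait_b, fixed, random)
    va = np.var(pr.ya) or 1.0
    vb = np.var(pr.yb) or 1.0
    # start from an equal split of each trait's variance, with every
    # level correlation seeded at the empirical phenotypic correlation
    rho0 = float(np.clip(np.corrcoef(pr.ya, pr.yb)[0, 1], -0.9, 0.9))
    if not np.isfinite(rho0):
        rho0 = 0.0
    K = len(pr.terms)
    theta0 = np.zeros(pr.n_par)
    for i in range(K + 1):
        sa = va / (K + 1)
        sb = vb / (K + 1)
        theta0[3 * i] = 0.5 * np.log(sa)
        theta0[3 * i + 1] = rho0 * np.sqrt(sb)
        theta0[3 * i + 2] = 0.5 * np.log(sb * (1 - rho0 ** 2))
    lo = [0.5 * np.log(va * 1e-8), None, 0.5 * np.log(vb * 1e-8)] * (K + 1)
    hi = [0.5 * np.log(va * 1e6), None, 0.5 * np.log(vb * 1e6)] * (K + 1)
    res = minimize(
        pr.objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=list(zip(lo, hi)),
        options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-6},
    )
    converged = bool(res.success or np.abs(res.jac).max() < 5e-2)
    neg2, chat = pr.solution(res.x)
    covs, Se = pr._split(res.x)
    covariances = {
        tm.term.name: covs[i] for i, tm in enumerate(pr.terms)
    }
    beta = pd.Series(chat[: pr.p], index=pr.fixed_names)
    return BivariateFitResult(
        traits=(trait_a, trait_b),
        covariances=covariances,
        resid=Se,
        loglik=-0.5 * neg2,
        converged=converged,
        n_iter=int(res.nit),
        beta=beta,
    )
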