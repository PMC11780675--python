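"""Restricted maximum likelihood (REML) estimation for linear mixed models.

The models handled here are the ones that arise in augmented
multi-environment trials of clonal crops: arbitrary fixed terms
(intercept, check genotypes, market-segment means), independent random
terms whose variance may be homogeneous or heterogeneous across groups
of levels (e.g. a separate genotypic variance per market segment or per
full-sib family), and a residual variance that is either pooled or
heterogeneous across environments.

The restricted log-likelihood is evaluated through the mixed-model
equations.  With ``V = R + Z G Z'`` and ``W = [X Z]``,

    -2 l_R = (n - p) log 2*pi + log|R| + log|G| + log|C| + y'Py,

where ``C`` is the coefficient matrix of the mixed-model equations and
``y'Py = y'R^{-1}y - b'C^{-1}b`` with ``b = W'R^{-1}y``.  Because every
random factor is categorical and the residual covariance is diagonal,
the cross-product blocks of ``C`` can be assembled once per residual
group and reweighted during optimization, so a likelihood evaluation
reduces to one dense Cholesky factorization of a moderate matrix.
Gradients with respect to the variance parameters are analytic,

    d l_R / d theta = -1/2 [ tr(P dV/dtheta) - y'P (dV/dtheta) P y ],

and the optimization runs on the log-variance scale with L-BFGS-B.
Components that collapse towards zero are fixed at the boundary and the
model refitted without them, mirroring how variances "fixed at their
boundary" are handled in dedicated mixed-model software.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve, qr
from scipy.optimize import minimize
from scipy.stats import chi2

__all__ = [
    "RandomTerm",
    "VarianceModelSpec",
    "FitResult",
    "fit_reml",
    "lrt",
    "adjusted_entry_means",
    "pairwise_difference_variance",
    "ReMLError",
    "ConvergenceError",
]

# share of the total variance below which a component is treated as a
# boundary (exact zero) estimate
BOUNDARY_SHARE = 1e-6


class ReMLError(ValueError):
    """Invalid model specification or data for REML fitting."""


class ConvergenceError(RuntimeError):
    """The optimizer failed; carries the optimizer result as trajectory."""

    def __init__(self, message, trajectory=None):
        super().__init__(message)
        self.trajectory = trajectory


@dataclass(frozen=True)
class RandomTerm:
    """One independent random term ``u ~ N(0, sigma^2 I)``.

    Parameters
    ----------
    name:
        Label used for the variance component in the fit result.
    factor:
        Column holding the levels of the random factor.
    filter:
        Optional 0/1 column; rows where it is 0 do not receive the
        effect (the dummy-variable device used for checks vs entries).
    by:
        Optional column assigning each *level* of ``factor`` to a
        variance group, yielding one variance per group (heterogeneous
        structure, e.g. per-segment or per-family genotypic variance).
    tie:
        Optional label; homogeneous terms carrying the same label share
        a single variance parameter (used to impose equality
        constraints between components).
    """

    name: str
    factor: str
    filter: str | None = None
    by: str | None = None
    tie: str | None = None


@dataclass(frozen=True)
class VarianceModelSpec:
    """Declarative model description.

    ``fixed`` accepts a tiny term language: ``"1"`` for the intercept,
    ``"C(col)"`` for a treatment-coded categorical over all rows (first
    level dropped when an intercept is present), ``"C(col)|flag"`` for a
    categorical applied only where the 0/1 column ``flag`` is 1 (all
    levels kept; the unfiltered rows act as baseline), and a bare column
    name for a numeric covariate.
    """

    response: str
    fixed: tuple[str, ...]
    random: tuple[RandomTerm, ...]
    residual_by: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "fixed", tuple(self.fixed))
        object.__setattr__(self, "random", tuple(self.random))


# ---------------------------------------------------------------------------
# design-matrix construction


def _build_fixed(df: pd.DataFrame, terms) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = []
    names: list[str] = []
    has_intercept = "1" in terms
    for term in terms:
        if term == "1":
            cols.append(np.ones(len(df)))
            names.append("(Intercept)")
            continue
        flt = None
        t = term
        if "|" in term:
            t, flt_col = term.split("|", 1)
            if flt_col not in df.columns:
                raise ReMLError(f"filter column {flt_col!r} not in data")
            flt = df[flt_col].to_numpy().astype(bool)
        if t.startswith("C(") and t.endswith(")"):
            col = t[2:-1]
            if col not in df.columns:
                raise ReMLError(f"fixed-effect column {col!r} not in data")
            vals = df[col].astype(str).to_numpy()
            if flt is None:
                levels = sorted(pd.unique(vals))
                start = 1 if has_intercept else 0
                for lev in levels[start:]:
                    cols.append((vals == lev).astype(float))
                    names.append(f"{col}[{lev}]")
            else:
                levels = sorted(pd.unique(vals[flt]))
                for lev in levels:
                    cols.append(((vals == lev) & flt).astype(float))
                    names.append(f"{col}[{lev}]")
        else:
            if t not in df.columns:
                raise ReMLError(f"fixed-effect column {t!r} not in data")
            v = df[t].to_numpy(dtype=float)
            if flt is not None:
                v = np.where(flt, v, 0.0)
            cols.append(v)
            names.append(term)
    if not cols:
        raise ReMLError("model must contain at least one fixed term")
    X = np.column_stack(cols)
    return X, names


def _drop_rank_deficient(X: np.ndarray, names: list[str]):
    """QR rank check dropping linearly dependent columns.

    Order-preserving and greedy: a column is dropped only if it is
    dependent on the columns before it, so adding a redundant column
    never changes which basis is fitted (and therefore never shifts
    the restricted log-likelihood).
    """
    keep = list(range(X.shape[1]))
    dropped: list[str] = []
    while keep:
        r = qr(X[:, keep], mode="economic")[1]
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps \
            if diag.size else 0.0
        bad = np.flatnonzero(diag <= tol)
        if bad.size == 0:
            break
        dropped.append(names[keep[bad[0]]])
        keep.pop(bad[0])
    return X[:, keep], [names[i] for i in keep], dropped


@dataclass
class _TermCols:
    term: RandomTerm
    levels: np.ndarray          # level labels, one per column
    groups: np.ndarray          # variance-group label per column
    group_names: list[str]      # distinct groups, fit order
    start: int                  # first column index within Z


def _build_random(df: pd.DataFrame, terms):
    """Sparse Z with column metadata per term.

    Terms whose active-row mask is empty after applying the filter and
    any boundary exclusions are silently skipped (they have collapsed
    entirely to the zero boundary).
    """
    n = len(df)
    blocks = []
    meta: list[_TermCols] = []
    start = 0
    for term in terms:
        if term.factor not in df.columns:
            raise ReMLError(f"random factor {term.factor!r} not in data")
        mask = np.ones(n, dtype=bool)
        if term.filter is not None:
            if term.filter not in df.columns:
                raise ReMLError(f"filter column {term.filter!r} not in data")
            mask &= df[term.filter].to_numpy().astype(bool)
        excl = getattr(term, "_excluded", None)
        if excl:
            mask &= ~df[term.by].astype(str).isin(excl).to_numpy()
        if not mask.any():
            continue
        vals = df[term.factor].astype(str).to_numpy()
        sub = np.flatnonzero(mask)
        levels, codes = np.unique(vals[sub], return_inverse=True)
        Z = sp.csr_matrix(
            (np.ones(sub.size), (sub, codes)), shape=(n, levels.size)
        )
        if term.by is not None:
            by = df[term.by].astype(str).to_numpy()
            grp = np.empty(levels.size, dtype=object)
            for j, lev in enumerate(levels):
                g = np.unique(by[sub][vals[sub] == lev])
                if g.size != 1:
                    raise ReMLError(
                        f"level {lev!r} of {term.factor!r} maps to several "
                        f"{term.by!r} groups"
                    )
                grp[j] = g[0]
            group_names = sorted(set(grp))
        else:
            grp = np.array([""] * levels.size, dtype=object)
            group_names = [""]
        blocks.append(Z)
        meta.append(_TermCols(term, levels, grp, group_names, start))
        start += levels.size
    Z = sp.hstack(blocks, format="csr") if blocks else sp.csr_matrix((n, 0))
    return Z, meta


# ---------------------------------------------------------------------------
# the fitted-model workhorse


class _MMEProblem:
    """Precomputed cross-products for one model/data combination."""

    def __init__(self, df: pd.DataFrame, spec: VarianceModelSpec):
        if spec.response not in df.columns:
            raise ReMLError(f"response {spec.response!r} not in data")
        df = df.loc[df[spec.response].notna()].reset_index(drop=True)
        if len(df) == 0:
            raise ReMLError("no non-missing observations")
        self.df = df
        self.spec = spec
        self.y = df[spec.response].to_numpy(dtype=float)
        self.n = len(df)

        X, names = _build_fixed(df, spec.fixed)
        X, names, dropped = _drop_rank_deficient(X, names)
        self.X, self.fixed_names, self.dropped_fixed = X, names, dropped
        self.p = X.shape[1]
        if self.n - self.p <= 0:
            raise ReMLError("no residual degrees of freedom")

        self.Z, self.terms = _build_random(df, spec.random)
        self.q = self.Z.shape[1]
        self.m = self.p + self.q
        self.W = sp.hstack([sp.csr_matrix(X), self.Z], format="csr")

        # residual groups
        if spec.residual_by is None:
            self.res_groups = [""]
            self.res_index = {"": np.arange(self.n)}
        else:
            vals = df[spec.residual_by].astype(str).to_numpy()
            self.res_groups = sorted(pd.unique(vals))
            self.res_index = {
                g: np.flatnonzero(vals == g) for g in self.res_groups
            }

        # per-residual-group cross products
        self.A, self.b, self.yy, self.ng = {}, {}, {}, {}
        for g, rows in self.res_index.items():
            Wg = self.W[rows]
            self.A[g] = np.asarray((Wg.T @ Wg).todense())
            self.b[g] = Wg.T @ self.y[rows]
            self.yy[g] = float(self.y[rows] @ self.y[rows])
            self.ng[g] = rows.size

        # variance-parameter layout: one parameter per (term, group),
        # except that homogeneous terms sharing a `tie` label share one
        # parameter; then one residual parameter per residual group
        self.vc_index: list[list[tuple[int, str]]] = []
        self.vc_cols: list[np.ndarray] = []
        tie_slot: dict[str, int] = {}
        for k, tm in enumerate(self.terms):
            for gname in tm.group_names:
                cols = self.p + tm.start + np.flatnonzero(tm.groups == gname)
                tie = tm.term.tie if tm.term.by is None else None
                if tie is not None and tie in tie_slot:
                    i = tie_slot[tie]
                    self.vc_index[i].append((k, gname))
                    self.vc_cols[i] = np.concatenate([self.vc_cols[i], cols])
                    continue
                if tie is not None:
                    tie_slot[tie] = len(self.vc_index)
                self.vc_index.append([(k, gname)])
                self.vc_cols.append(cols)
        self.n_vc = len(self.vc_index)
        self.n_par = self.n_vc + len(self.res_groups)

    # -- likelihood ---------------------------------------------------------

    def _assemble(self, theta):
        sig = np.exp(theta[: self.n_vc])
        phi = np.exp(theta[self.n_vc:])
        M = np.zeros((self.m, self.m))
        bvec = np.zeros(self.m)
        yRy = 0.0
        logR = 0.0
        for j, g in enumerate(self.res_groups):
            w = 1.0 / phi[j]
            M += w * self.A[g]
            bvec += w * self.b[g]
            yRy += w * self.yy[g]
            logR += self.ng[g] * np.log(phi[j])
        ginv = np.zeros(self.m)
        logG = 0.0
        for i, cols in enumerate(self.vc_cols):
            ginv[cols] = 1.0 / sig[i]
            logG += cols.size * np.log(sig[i])
        C = M + np.diag(ginv)
        return sig, phi, M, bvec, yRy, logR, logG, C

    def evaluate(self, theta):
        """-2 restricted log-likelihood, solution and Cholesky factor."""
        _, _, _, bvec, yRy, logR, logG, C = self._assemble(theta)
        cf = cho_factor(C, lower=True, check_finite=False)
        chat = cho_solve(cf, bvec, check_finite=False)
        logC = 2.0 * np.sum(np.log(np.diag(cf[0])))
        yPy = yRy - bvec @ chat
        neg2 = (
            (self.n - self.p) * np.log(2.0 * np.pi)
            + logR + logG + logC + yPy
        )
        return neg2, chat, cf

    def objective(self, theta):
        """(-2 l_R, analytic gradient on the log-variance scale)."""
        sig, phi, M, bvec, yRy, logR, logG, C = self._assemble(theta)
        try:
            cf = cho_factor(C, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return np.inf, np.zeros(self.n_par)
        chat = cho_solve(cf, bvec, check_finite=False)
        logC = 2.0 * np.sum(np.log(np.diag(cf[0])))
        yPy = yRy - bvec @ chat
        neg2 = (
            (self.n - self.p) * np.log(2.0 * np.pi)
            + logR + logG + logC + yPy
        )
        Cinv = cho_solve(cf, np.eye(self.m), check_finite=False)
        e = self.y - self.W @ chat
        r = np.empty(self.n)
        for j, g in enumerate(self.res_groups):
            r[self.res_index[g]] = e[self.res_index[g]] / phi[j]
        u = self.W.T @ r
        grad = np.zeros(self.n_par)
        # tr(Z_S' P Z_S) = sum_{j in S} [ M_jj - M[:,j]' C^{-1} M[:,j] ]
        diagM = np.diag(M)
        quadM = np.einsum("ij,ij->j", M, Cinv @ M)
        for i, cols in enumerate(self.vc_cols):
            tr = diagM[cols].sum() - quadM[cols].sum()
            quad = float(u[cols] @ u[cols])
            # d(-2 l_R)/d sigma^2 = tr(P ZZ') - r'ZZ'r, chained to log scale
            grad[i] = (tr - quad) * sig[i]
        for j, g in enumerate(self.res_groups):
            w = 1.0 / phi[j]
            tr = self.ng[g] * w - (w * w) * np.vdot(Cinv, self.A[g])
            quad = float(r[self.res_index[g]] @ r[self.res_index[g]])
            grad[self.n_vc + j] = (tr - quad) * phi[j]
        return neg2, grad


@dataclass
class FitResult:
    """Outcome of one REML fit.

    ``varcomp`` maps term names to either a float (homogeneous) or a
    dict group -> float (heterogeneous); ``resid`` analogously for the
    residual.  Boundary components are exact zeros and listed in
    ``boundary`` as ``(term, group)`` pairs.  The object retains the
    solved mixed-model equations, so adjusted entry means, prediction
    covariances, BLUPs and conditional residuals can be extracted.
    """

    spec: VarianceModelSpec
    varcomp: dict
    resid: float | dict
    loglik: float
    converged: bool
    n_iter: int
    boundary: list = field(default_factory=list)
    beta: pd.Series | None = None
    blups: dict | None = None
    dropped_fixed: list = field(default_factory=list)
    _problem: object | None = field(default=None, repr=False)
    _theta: np.ndarray | None = field(default=None, repr=False)
    _Cinv: np.ndarray | None = field(default=None, repr=False)
    _chat: np.ndarray | None = field(default=None, repr=False)

    # -- downstream accessors ----------------------------------------------

    @property
    def fixed_cov(self) -> pd.DataFrame:
        """Prediction covariance of the fixed-effect estimates."""
        pr = self._problem
        V = self._Cinv[: pr.p, : pr.p]
        return pd.DataFrame(V, index=pr.fixed_names, columns=pr.fixed_names)

    def residuals(self) -> pd.Series:
        """Conditional (plot-level) residuals y - X beta - Z u."""
        pr = self._problem
        e = pr.y - pr.W @ self._chat
        return pd.Series(e, index=pr.df.index)

    def residual_sd_per_row(self) -> pd.Series:
        """Residual standard deviation applying to each observation."""
        pr = self._problem
        sd = np.empty(pr.n)
        for g in pr.res_groups:
            s = self.resid[g] if isinstance(self.resid, dict) else self.resid
            sd[pr.res_index[g]] = np.sqrt(s)
        return pd.Series(sd, index=pr.df.index)

    def mean_resid(self) -> float:
        """Residual variance, averaged over environments when heterogeneous."""
        if isinstance(self.resid, dict):
            return float(np.mean(list(self.resid.values())))
        return float(self.resid)

    def total_variance(self) -> float:
        """Sum of all variance components plus the (mean) residual."""
        tot = self.mean_resid()
        for v in self.varcomp.values():
            tot += sum(v.values()) if isinstance(v, dict) else v
        return float(tot)

    def data(self) -> pd.DataFrame:
        return self._problem.df


def _fit_once(df, spec, start=None, maxiter=500):
    pr = _MMEProblem(df, spec)
    vary = float(np.var(pr.y)) or 1.0
    if start is not None:
        start = np.asarray(start, dtype=float)
        if start.size != pr.n_par:
            # layout changed (e.g. a term without active rows); restart
            start = None
    if start is None:
        theta0 = np.log(np.full(pr.n_par, vary / (pr.n_vc + 1)))
    else:
        theta0 = np.log(np.maximum(start, vary * 1e-9))
    lo, hi = np.log(vary * 1e-10), np.log(vary * 1e6)
    res = minimize(
        pr.objective,
        np.clip(theta0, lo, hi),
        jac=True,
        method="L-BFGS-B",
        bounds=[(lo, hi)] * pr.n_par,
        options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-9},
    )
    return pr, res


def fit_reml(
    df: pd.DataFrame,
    spec: VarianceModelSpec,
    start: np.ndarray | None = None,
    maxiter: int = 500,
    boundary_share: float = BOUNDARY_SHARE,
) -> FitResult:
    """Fit ``spec`` to the plot table ``df`` by REML.

    Components whose estimate collapses below ``boundary_share`` of the
    total variance are fixed at exactly zero, flagged in ``boundary``,
    and the remaining components refitted without them.
    """
    spec_cur = spec
    boundary: list[tuple[str, str]] = []
    n_rounds = sum(
        len(pd.unique(df[t.by].astype(str))) if t.by else 1
        for t in spec.random
    ) + 1
    for _ in range(n_rounds):
        pr, res = _fit_once(df, spec_cur, start=start, maxiter=maxiter)
        # L-BFGS-B reports an abnormal line-search exit when rounding
        # noise dominates near the optimum; accept if the gradient is flat
        if not (res.success or res.status == 1
                or np.abs(res.jac).max() < 1e-2):
            pr, res = _fit_once(
                df, spec_cur, start=np.exp(res.x) * 1.3, maxiter=maxiter
            )
            if not (res.success or res.status == 1
                    or np.abs(res.jac).max() < 1e-2):
                raise ConvergenceError(
                    f"REML optimizer failed: {res.message}", trajectory=res
                )
        sig = np.exp(res.x[: pr.n_vc])
        phi = np.exp(res.x[pr.n_vc:])
        total = sig.sum() + phi.mean()
        small = np.flatnonzero(sig < boundary_share * total)
        if small.size == 0:
            break
        for i in small:
            for k, gname in pr.vc_index[i]:
                term = pr.terms[k].term
                boundary.append((term.name, gname))
                spec_cur = _drop_component(spec_cur, term, gname)
        keep = np.setdiff1d(np.arange(pr.n_vc), small)
        start = np.concatenate([sig[keep], phi])
    else:  # pragma: no cover - defensive
        raise ConvergenceError("boundary elimination did not stabilize")

    neg2, chat, cf = pr.evaluate(res.x)
    Cinv = cho_solve(cf, np.eye(pr.m), check_finite=False)

    varcomp: dict = {}
    for orig in spec.random:
        varcomp[orig.name] = {} if orig.by is not None else None
    for i, members in enumerate(pr.vc_index):
        for k, gname in members:
            tm = pr.terms[k]
            if tm.term.by is None:
                varcomp[tm.term.name] = float(sig[i])
            else:
                varcomp[tm.term.name][gname] = float(sig[i])
    for name, gname in boundary:  # boundary components as exact zeros
        orig = next(t for t in spec.random if t.name == name)
        if orig.by is None:
            varcomp[name] = 0.0
        else:
            varcomp[name][gname] = 0.0
    for name, v in varcomp.items():
        if v is None:
            varcomp[name] = 0.0  # term vanished without explicit flag

    if spec.residual_by is None:
        resid: float | dict = float(phi[0])
    else:
        resid = {g: float(phi[j]) for j, g in enumerate(pr.res_groups)}

    beta = pd.Series(chat[: pr.p], index=pr.fixed_names)
    blups = {
        tm.term.name: pd.Series(
            chat[pr.p + tm.start: pr.p + tm.start + tm.levels.size],
            index=tm.levels,
        )
        for tm in pr.terms
    }

    return FitResult(
        spec=spec,
        varcomp=varcomp,
        resid=resid,
        loglik=-0.5 * neg2,
        converged=bool(res.success or np.abs(res.jac).max() < 1e-2),
        n_iter=int(res.nit),
        boundary=boundary,
        beta=beta,
        blups=blups,
        dropped_fixed=pr.dropped_fixed,
        _problem=pr,
        _theta=res.x,
        _Cinv=Cinv,
        _chat=chat,
    )


def _drop_component(spec: VarianceModelSpec, term: RandomTerm, gname: str):
    """Remove one variance component (whole term, or one het group)."""
    new_random = []
    for t in spec.random:
        if t.name != term.name:
            new_random.append(t)
            continue
        if t.by is None:
            continue  # homogeneous component dropped entirely
        excl = getattr(t, "_excluded", frozenset()) | {gname}
        nt = RandomTerm(t.name, t.factor, t.filter, t.by)
        object.__setattr__(nt, "_excluded", frozenset(excl))
        new_random.append(nt)
    return VarianceModelSpec(
        spec.response, spec.fixed, tuple(new_random), spec.residual_by
    )


# ---------------------------------------------------------------------------
# inference helpers


def lrt(full: FitResult, reduced: FitResult, df: int, mixture: bool = False):
    """Likelihood-ratio test of nested variance structures.

    Returns ``(statistic, p)`` with the statistic clamped at zero.  The
    default reference is the naive chi-square with ``df`` degrees of
    freedom, as commonly applied to random effects; ``mixture=True``
    uses the 50:50 chi0:chi1 boundary mixture (meaningful for df=1).
    """
    if full.spec.response != reduced.spec.response:
        raise ReMLError("LRT requires the same response")
    if tuple(full.spec.fixed) != tuple(reduced.spec.fixed):
        raise ReMLError("LRT requires identical fixed effects")
    if df < 1:
        raise ReMLError("df must be >= 1")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    if stat == 0.0:
        return 0.0, 1.0
    p = chi2.sf(stat, df)
    if mixture:
        p = 0.5 * p
    return stat, float(p)


def adjusted_entry_means(
    fit: FitResult, factor: str = "clone_id", use_blups: bool = False
) -> pd.Series:
    """Adjusted entry means ``mu + g_i`` for the levels of ``factor``.

    With the genotype fixed (the across-environment analysis), the AEM
    is the estimated intercept plus the clone's fixed effect; because
    all nuisance factors (environment, block, row, column) are random
    with zero mean, this marginal mean is directly estimable.  With
    ``use_blups=True`` clone effects are additionally taken from the
    random predictions (shrunken means, for models with random entries).
    """
    mu = float(fit.beta.get("(Intercept)", 0.0))
    prefix = f"{factor}["
    out = {}
    for lab, val in fit.beta.items():
        if lab.startswith(prefix):
            out[lab[len(prefix):-1]] = mu + float(val)
    if out:
        # a treatment-coded all-rows categorical has exactly one dropped
        # reference level whose coefficient is zero
        pr = fit._problem
        if factor in pr.df.columns:
            missing = [
                lev for lev in pd.unique(pr.df[factor].astype(str))
                if lev not in out
            ]
            if len(missing) == 1:
                out[missing[0]] = mu
    if use_blups:
        for name, series in (fit.blups or {}).items():
            tm = next(
                (t for t in fit.spec.random
                 if t.name == name and t.factor == factor),
                None,
            )
            if tm is not None:
                for lev, val in series.items():
                    out[lev] = mu + float(val)
    if not out:
        raise ReMLError(f"no effects found for factor {factor!r}")
    return pd.Series(out, dtype=float).sort_index()


def pairwise_difference_variance(
    fit: FitResult,
    factor: str = "clone_id",
    entries: list | None = None,
    max_exhaustive: int = 500,
    n_sample: int = 100_000,
    seed: int = 0,
) -> float:
    """Mean variance of a difference of two adjusted means of the entries.

    Exhaustive (closed form over all pairs) for up to ``max_exhaustive``
    entries, otherwise a seeded random sample of ``n_sample`` pairs.
    ``entries`` restricts the computation to the listed levels; by
    default all fixed levels of ``factor`` are used.
    """
    pr = fit._problem
    prefix = f"{factor}["
    labels = {
        n[len(prefix):-1]: i
        for i, n in enumerate(pr.fixed_names)
        if n.startswith(prefix)
    }
    if entries is None:
        entries = sorted(labels)
    # the dropped reference level has coefficient 0 with zero variance
    sel = np.array([labels.get(str(e), -1) for e in entries])
    k = sel.size
    if k < 2:
        raise ReMLError("need at least two entries for a pairwise variance")
    Vb = fit._Cinv[: pr.p, : pr.p]
    Vsub = np.zeros((k, k))
    ok = sel >= 0
    Vsub[np.ix_(ok, ok)] = Vb[np.ix_(sel[ok], sel[ok])]
    if k <= max_exhaustive:
        s1 = np.trace(Vsub)
        s2 = Vsub.sum()
        return float((2 * k * s1 - 2 * s2) / (k * (k - 1)))
    rng = np.random.default_rng(seed)
    i = rng.integers(0, k, n_sample)
    j = rng.integers(0, k - 1, n_sample)
    j = np.where(j >= i, j + 1, j)
    v = Vsub[i, i] + Vsub[j, j] - 2 * Vsub[i, j]
    return float(v.mean())
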