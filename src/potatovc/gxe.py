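"""Genotype-by-environment geometry: AMMI, company correction, GPA.

Environments are characterized through the replicated checks: an
additive main effects and multiplicative interaction (AMMI) analysis of
the check-mean table per trait, an optional removal of fixed breeding-
company effects from the check data, and a generalized Procrustes
analysis (GPA) that aligns the per-trait environment score
configurations to a consensus, so environments can be compared across
traits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes

from .ladder import prepare_frame
from .reml import RandomTerm, ReMLError, VarianceModelSpec, fit_reml

__all__ = [
    "AmmiResult",
    "ProcrustesResult",
    "check_cell_means",
    "ammi",
    "company_effect_correction",
    "generalized_procrustes",
    "ammi_gpa_pipeline",
]


@dataclass
class AmmiResult:
    """AMMI decomposition of one genotype x environment mean table."""

    trait: str
    grand_mean: float
    genotype_effects: pd.Series
    environment_effects: pd.Series
    singular_values: np.ndarray
    genotype_scores: pd.DataFrame      # genotypes x components
    environment_scores: pd.DataFrame   # environments x components
    proportions: np.ndarray            # interaction variance per component

    def interaction(self) -> pd.DataFrame:
        """Reconstructed doubly-centred interaction table."""
        vals = (self.genotype_scores.to_numpy()
                @ self.environment_scores.to_numpy().T)
        return pd.DataFrame(vals, index=self.genotype_scores.index,
                            columns=self.environment_scores.index)


def check_cell_means(df: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Check-mean table (genotype x environment) from plot data."""
    chk = df.loc[(df["is_check"] == 1) & df[trait].notna()]
    table = chk.pivot_table(index="clone_id", columns="environment_id",
                            values=trait, aggfunc="mean")
    if table.isna().any().any():
        missing = [
            (g, e) for g in table.index for e in table.columns
            if pd.isna(table.at[g, e])
        ]
        raise ValueError(f"check means missing for cells: {missing[:5]} ...")
    return table


def ammi(table: pd.DataFrame, trait: str = "") -> AmmiResult:
    """Additive main effects + multiplicative interaction decomposition.

    Row and column main effects are removed by double centring; the
    residual interaction is decomposed by SVD with the singular value
    split evenly between genotype and environment scores (symmetric
    scaling).
    """
    if table.isna().any().any():
        raise ValueError("AMMI requires a complete two-way table")
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("AMMI needs at least 2 genotypes and 2 environments")
    vals = table.to_numpy(dtype=float)
    mu = vals.mean()
    g_eff = vals.mean(axis=1) - mu
    e_eff = vals.mean(axis=0) - mu
    resid = vals - mu - g_eff[:, None] - e_eff[None, :]
    U, s, Vt = np.linalg.svd(resid, full_matrices=False)
    k = min(table.shape) - 1  # double centring removes one dimension
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    ss = s ** 2
    props = ss / ss.sum() if ss.sum() > 0 else np.zeros_like(ss)
    sq = np.sqrt(s)
    comp = [f"IPC{i + 1}" for i in range(k)]
    return AmmiResult(
        trait=trait,
        grand_mean=float(mu),
        genotype_effects=pd.Series(g_eff, index=table.index),
        environment_effects=pd.Series(e_eff, index=table.columns),
        singular_values=s,
        genotype_scores=pd.DataFrame(U * sq, index=table.index, columns=comp),
        environment_scores=pd.DataFrame(Vt.T * sq, index=table.columns,
                                        columns=comp),
        proportions=props,
    )


def company_effect_correction(
    df: pd.DataFrame, traits: list[str]
) -> pd.DataFrame:
    """Remove fixed breeding-company effects from the check data.

    A mixed model on the checks alone (clone and company fixed;
    environment, clone-by-environment, block, row, column random)
    estimates one effect per company, which is then subtracted from
    every check observation of that company.  With a single company the
    data are returned unchanged with a warning.
    """
    chk = df.loc[df["is_check"] == 1].copy()
    if chk["company"].nunique() < 2:
        import warnings

        warnings.warn("single company; company correction is the identity")
        return chk
    work = prepare_frame(chk)
    out = chk.copy()
    for trait in traits:
        if work[trait].notna().sum() == 0:
            continue
        spec = VarianceModelSpec(
            trait,
            ("1", "C(clone_id)", "C(company)"),
            (RandomTerm("environment", "environment_id"),
             RandomTerm("check_gxe", "clone_env"),
             RandomTerm("block", "block_id"),
             RandomTerm("row", "row_id"),
             RandomTerm("col", "col_id")),
        )
        fit = fit_reml(work, spec)
        comps = sorted(chk["company"].astype(str).unique())
        eff = {c: float(fit.beta.get(f"company[{c}]", 0.0)) for c in comps}
        out[trait] = out[trait] - out["company"].astype(str).map(eff)
    return out


@dataclass
class ProcrustesResult:
    """Consensus of several environment configurations."""

    consensus: pd.DataFrame            # environments x dimensions
    transformed: dict                  # trait -> aligned configuration
    explained: np.ndarray              # variance share per dimension
    residuals: pd.Series               # per trait
    n_iter: int


def _center_scale(mat: np.ndarray) -> np.ndarray:
    c = mat - mat.mean(axis=0, keepdims=True)
    norm = np.linalg.norm(c)
    if norm == 0:
        raise ValueError("degenerate (all-equal) configuration")
    return c / norm


def generalized_procrustes(
    configs: dict, tol: float = 1e-8, max_iter: int = 200
) -> ProcrustesResult:
    """Align several environment configurations to a consensus.

    ``configs`` maps trait -> DataFrame (environments x dimensions).
    Environments not shared by all configurations are dropped listwise.
    Each configuration is centred and isotropically scaled to unit
    norm (the size standardization), then iteratively rotated to the
    consensus — the plain mean of the aligned configurations — until
    the consensus changes by less than ``tol``.  The consensus is kept
    as the mean during iteration (renormalizing it each round is the
    classic scale-collapse pitfall); for reporting it is rotated to its
    principal axes, so explained variance per dimension is
    non-increasing, and rescaled to unit centroid size.  Residuals are
    sums of squares between each aligned configuration and the mean
    consensus, on the standardized scale.
    """
    if len(configs) < 2:
        raise ValueError("GPA needs at least two configurations")
    common = None
    for c in configs.values():
        common = set(c.index) if common is None else common & set(c.index)
    common = sorted(common)
    if len(common) < 3:
        raise ValueError("fewer than three common environments")
    mats = {
        t: _center_scale(c.loc[common].to_numpy(dtype=float))
        for t, c in configs.items()
    }
    names = list(mats)
    cur = {t: m.copy() for t, m in mats.items()}
    consensus = np.mean(list(cur.values()), axis=0)
    K = len(names)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        before = consensus
        for t in names:
            # align to the leave-one-out mean: aligning to a consensus
            # containing the configuration itself biases against
            # rotating and admits spurious fixed points
            others = (consensus * K - cur[t]) / (K - 1)
            R, _ = orthogonal_procrustes(mats[t], others)
            cur[t] = mats[t] @ R
            consensus = np.mean(list(cur.values()), axis=0)
        if np.linalg.norm(consensus - before) < tol:
            break

    # rotate everything to the consensus principal axes
    _, _, Vt = np.linalg.svd(consensus, full_matrices=False)
    rot = Vt.T
    consensus = consensus @ rot
    for t in names:
        cur[t] = cur[t] @ rot

    total = sum(np.sum(c ** 2) for c in cur.values())
    per_dim = sum(np.sum(c ** 2, axis=0) for c in cur.values())
    explained = per_dim / total if total > 0 else np.zeros(consensus.shape[1])
    residuals = pd.Series({
        t: float(np.sum((cur[t] - consensus) ** 2)) for t in names
    })
    norm = np.linalg.norm(consensus)
    out_consensus = consensus / norm if norm > 0 else consensus
    dims = [f"Dim{i + 1}" for i in range(consensus.shape[1])]
    return ProcrustesResult(
        consensus=pd.DataFrame(out_consensus, index=common, columns=dims),
        transformed={
            t: pd.DataFrame(cur[t], index=common, columns=dims) for t in names
        },
        explained=np.asarray(explained),
        residuals=residuals,
        n_iter=n_iter,
    )


def ammi_gpa_pipeline(
    df: pd.DataFrame,
    traits: list[str],
    correct_company: bool = False,
    n_components: int = 2,
) -> tuple[dict, ProcrustesResult]:
    """Per-trait AMMI on check means, then GPA over environment scores.

    Returns the AMMI results per trait and the Procrustes consensus of
    the first ``n_components`` environment interaction scores.
    """
    data = company_effect_correction(df, traits) if correct_company else df
    ammis = {}
    configs = {}
    for trait in traits:
        try:
            table = check_cell_means(data, trait)
        except ValueError:
            continue
        res = ammi(table, trait)
        ammis[trait] = res
        k = min(n_components, res.environment_scores.shape[1])
        configs[trait] = res.environment_scores.iloc[:, :k]
    if len(configs) < 2:
        raise ReMLError("fewer than two traits yield AMMI configurations")
    gpa = generalized_procrustes(configs)
    return ammis, gpa
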