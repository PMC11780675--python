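"""Effect of single-hills preselection on variances, means and
covariances.

Clones carry a discard status (0 = kept, 1 = discarded while siblings
were kept, 2 = whole family discarded) marking what an early visual
preselection would have removed.  The module quantifies what that
selection step would have done to the later-stage genetic parameters:
stratified resampling of the complete set to the reduced-set size (so
sample size is controlled), the percent change Delta of the genotypic
variance, adjusted-entry-mean comparisons between discard groups with
Bonferroni-corrected pairwise Welch t-tests, and the stability of the
genotypic correlation matrix across discard subsets via Mantel's test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from .covariance import correlation_matrices, mantel_test
from .ladder import model_spec, prepare_frame
from .reml import fit_reml

__all__ = [
    "stratified_sample",
    "variance_change",
    "delta_summary",
    "compare_group_means",
    "subset_correlation_stability",
    "PreselectionResult",
    "preselection_variance_study",
]


def stratified_sample(
    clones: pd.DataFrame,
    target_size: int,
    seed: int,
    composition: dict | None = None,
    checks: list | None = None,
) -> list:
    """Sample ``target_size`` entry clones preserving discard composition.

    ``clones`` needs columns ``clone_id`` and ``discard_status`` (one
    row per clone).  Per-status quotas are ``target_size`` times the
    complete-set proportions (or ``composition``), rounded by largest
    remainder so the total is met exactly.  Check clones are appended
    to every sample and do not count against the entry quota.
    """
    pool = clones.drop_duplicates("clone_id")
    if checks:
        pool = pool.loc[~pool["clone_id"].isin(checks)]
    statuses = sorted(pool["discard_status"].unique())
    if composition is None:
        counts = pool["discard_status"].value_counts()
        composition = {s: counts.get(s, 0) / len(pool) for s in statuses}
    if abs(sum(composition.values()) - 1.0) > 1e-9:
        raise ValueError("composition proportions must sum to 1")
    if target_size > len(pool):
        raise ValueError("target size exceeds the available clones")
    quota = np.array([composition.get(s, 0.0) * target_size for s in statuses])
    take = np.floor(quota).astype(int)
    rem = target_size - take.sum()
    order = np.argsort(-(quota - take))
    take[order[:rem]] += 1
    rng = np.random.default_rng(seed)
    sample: list = []
    for s, k in zip(statuses, take):
        ids = np.sort(pool.loc[pool["discard_status"] == s, "clone_id"].to_numpy())
        if k > len(ids):
            raise ValueError(
                f"stratum {s} holds {len(ids)} clones but needs {k}"
            )
        sample.extend(rng.choice(ids, size=k, replace=False))
    if checks:
        sample.extend(checks)
    return sorted(sample)


def variance_change(sigma_strat_mean: float, sigma_reduced: float) -> float:
    """Percent deviation Delta of the reduced-set genotypic variance from
    the stratified-sample mean of the complete set:
    ``(mean_strat - reduced) / mean_strat * 100``."""
    if sigma_strat_mean <= 0:
        raise ValueError("the stratified mean variance must be > 0")
    return (sigma_strat_mean - sigma_reduced) / sigma_strat_mean * 100.0


def delta_summary(deltas) -> tuple[float, float]:
    """Arithmetic mean and median of per-trait Delta values."""
    arr = np.asarray(list(deltas), dtype=float)
    if arr.size == 0:
        raise ValueError("no Delta values supplied")
    return float(arr.mean()), float(np.median(arr))


def compare_group_means(
    aems: pd.Series,
    groups: pd.DataFrame,
    alpha: float = 0.05,
    welch: bool = True,
) -> pd.DataFrame:
    """Pairwise t-tests of AEMs between discard statuses within segments.

    ``aems`` maps clone -> adjusted entry mean; ``groups`` has columns
    ``clone_id``, ``segment``, ``discard_status``.  Within each segment
    every pair of statuses is compared by a two-sided t-test (Welch by
    default) and Bonferroni-corrected over the comparisons of that
    segment.  Groups with fewer than two clones are skipped.
    """
    merged = groups.drop_duplicates("clone_id").copy()
    merged["aem"] = merged["clone_id"].map(aems)
    merged = merged.dropna(subset=["aem"])
    rows = []
    for seg, sub in merged.groupby("segment"):
        by_status = {
            s: g["aem"].to_numpy() for s, g in sub.groupby("discard_status")
        }
        pairs = [
            (a, b) for a, b in combinations(sorted(by_status), 2)
        ]
        usable = [
            (a, b) for a, b in pairs
            if len(by_status[a]) >= 2 and len(by_status[b]) >= 2
        ]
        skipped = set(pairs) - set(usable)
        for a, b in skipped:
            warnings.warn(
                f"segment {seg}: group pair ({a},{b}) skipped (size < 2)"
            )
        m = len(usable)
        for a, b in usable:
            stat, p = ttest_ind(
                by_status[a], by_status[b], equal_var=not welch
            )
            p_adj = min(1.0, float(p) * m)
            rows.append({
                "segment": seg, "status_a": a, "status_b": b,
                "mean_a": float(np.mean(by_status[a])),
                "mean_b": float(np.mean(by_status[b])),
                "t": float(stat), "p": float(p), "p_bonferroni": p_adj,
                "significant": p_adj < alpha,
            })
    return pd.DataFrame(rows)


def subset_correlation_stability(
    df: pd.DataFrame,
    traits: list[str],
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Mantel comparisons of genotypic correlations across discard subsets.

    Builds the genotypic correlation matrix for the complete set, the
    reduced set (status 0) and set D12 (statuses 1 and 2), with the
    checks appended to every subset, then returns the three pairwise
    Mantel tests.
    """
    work = prepare_frame(df)
    chk = work["is_check"] == 1
    subsets = {
        "complete": work,
        "reduced": work.loc[chk | (work["discard_status"] == 0)],
        "D12": work.loc[chk | (work["discard_status"].isin([1, 2]))],
    }
    for name, sub in subsets.items():
        if (sub["is_entry"] == 1).sum() == 0:
            raise ValueError(f"subset {name} holds no entries")
    mats = {
        name: correlation_matrices(sub, traits).matrix("r_g")
        for name, sub in subsets.items()
    }
    out = {"matrices": mats, "mantel": {}}
    for a, b in [("complete", "reduced"), ("complete", "D12"),
                 ("reduced", "D12")]:
        out["mantel"][(a, b)] = mantel_test(
            mats[a], mats[b], n_perm=n_perm, seed=seed
        )
    return out


@dataclass
class PreselectionResult:
    """Per-trait outcome of the stratified-sampling variance study."""

    trait: str
    sigma_strat_mean: float
    sigma_strat_rounds: list = field(default_factory=list)
    sigma_reduced: float = np.nan
    delta: float = np.nan


def preselection_variance_study(
    df: pd.DataFrame,
    traits: list[str],
    n_rounds: int = 50,
    seed: int = 0,
    heterogeneous_residuals: bool = True,
) -> tuple[list[PreselectionResult], tuple[float, float]]:
    """Compare reduced-set vs stratified complete-set genotypic variance.

    For each trait the genotypic-variance model (optionally with
    heterogeneous residuals) is fitted on the reduced set (status 0,
    checks kept) and on ``n_rounds`` stratified samples of the complete
    set sized like the reduced set; Delta is the percent deviation.
    Round seeds derive from the master ``seed``.  Returns the per-trait
    results and the (mean, median) Delta summary.
    """
    work = prepare_frame(df)
    model = "model3het" if heterogeneous_residuals else "model3"
    entries = work.loc[work["is_entry"] == 1,
                       ["clone_id", "discard_status"]].drop_duplicates()
    checks = sorted(work.loc[work["is_check"] == 1, "clone_id"].unique())
    reduced_ids = set(
        entries.loc[entries["discard_status"] == 0, "clone_id"]
    ) | set(checks)
    target = int((entries["discard_status"] == 0).sum())
    rng = np.random.default_rng(seed)
    round_seeds = rng.integers(0, 2 ** 31 - 1, size=n_rounds)

    results = []
    for trait in traits:
        red = work.loc[work["clone_id"].isin(reduced_ids)]
        fit_red = fit_reml(red, model_spec(model, trait))
        s_red = fit_red.varcomp["entries"]
        rounds = []
        for rs in round_seeds:
            ids = stratified_sample(entries, target, seed=int(rs),
                                    checks=checks)
            sub = work.loc[work["clone_id"].isin(ids)]
            fit_s = fit_reml(sub, model_spec(model, trait))
            rounds.append(fit_s.varcomp["entries"])
        s_strat = float(np.mean(rounds))
        res = PreselectionResult(
            trait=trait,
            sigma_strat_mean=s_strat,
            sigma_strat_rounds=rounds,
            sigma_reduced=s_red,
            delta=variance_change(s_strat, s_red),
        )
        results.append(res)
    summary = delta_summary([r.delta for r in results])
    return results, summary
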