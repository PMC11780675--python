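"""Data corrections applied before variance-component analysis.

The correction pipeline runs in a fixed order: yield normalization to a
16-plant plot, trial-effect correction of the split environment,
outlier removal on standardized residuals of the base model, and a
check-based block correction guarded by a likelihood-ratio test.  All
corrections are pure location shifts and are recorded in a
:class:`CorrectionLog`, including the removed outlier rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ladder import model_spec, prepare_frame
from .reml import FitResult, fit_reml, lrt

__all__ = [
    "CorrectionLog",
    "normalize_yield",
    "normalize_yield_column",
    "correct_trial_effect",
    "flag_outliers",
    "correct_block_effect",
    "preprocess_trait",
    "DegeneratePlotError",
]

MP_THRESHOLD = 0.20  # missing plants enter the denominator only above this
OUTLIER_THRESHOLD = 3.5


class DegeneratePlotError(ValueError):
    """A plot's effective plant count is not positive."""


@dataclass
class CorrectionLog:
    """Shift-by-shift record of every correction applied.

    ``shifts`` holds one row per (plot, trait) with the original value,
    the corrected value and the source of the correction; ``removed``
    retains outlier rows verbatim; ``check_means`` stores the check
    means used per environment/trial/block.
    """

    shifts: list = field(default_factory=list)
    removed: list = field(default_factory=list)
    check_means: list = field(default_factory=list)

    def shifts_frame(self) -> pd.DataFrame:
        cols = ["plot", "trait", "original", "corrected", "offset", "source"]
        return pd.DataFrame(self.shifts, columns=cols)

    def removed_frame(self) -> pd.DataFrame:
        cols = ["plot", "trait", "value", "standardized_residual"]
        return pd.DataFrame(self.removed, columns=cols)

    def check_means_frame(self) -> pd.DataFrame:
        cols = ["trait", "scope", "group", "check_mean"]
        return pd.DataFrame(self.check_means, columns=cols)


def normalize_yield(yld_raw: float, pn: int, mp: int) -> float:
    """Normalize a raw plot yield (kg) to a 16-plant plot.

    The denominator is the planted count ``pn`` unless the share of
    missing plants ``mp`` exceeds 20% of ``pn``, in which case the
    missing plants are subtracted (below that share the remaining
    plants are assumed to compensate fully).
    """
    if pn <= 0:
        raise DegeneratePlotError("planted plant count must be > 0")
    if mp < 0 or mp > pn:
        raise DegeneratePlotError("missing plants must lie in [0, PN]")
    denom = pn - mp if mp / pn > MP_THRESHOLD else pn
    if denom <= 0:
        raise DegeneratePlotError("no surviving plants in plot")
    return yld_raw / denom * 16.0


def normalize_yield_column(
    df: pd.DataFrame,
    raw: str = "raw_yield",
    out: str = "YLD",
    pn: str = "planted_plants",
    mp: str = "missing_plants",
) -> pd.DataFrame:
    """Vectorized 16-plant normalization of a raw yield column."""
    work = df.copy()
    pn_v = work[pn].to_numpy(dtype=float)
    mp_v = work[mp].to_numpy(dtype=float)
    if (pn_v <= 0).any() or (mp_v < 0).any() or (mp_v > pn_v).any():
        raise DegeneratePlotError("invalid plant counts in table")
    denom = np.where(mp_v / pn_v > MP_THRESHOLD, pn_v - mp_v, pn_v)
    if (denom <= 0).any():
        raise DegeneratePlotError("no surviving plants in some plot")
    work[out] = work[raw].to_numpy(dtype=float) / denom * 16.0
    return work


def correct_trial_effect(
    df: pd.DataFrame, traits: list[str], log: CorrectionLog | None = None
) -> tuple[pd.DataFrame, CorrectionLog]:
    """Remove the trial effect in environments split into several trials.

    For each such environment and trait, the check means of the two
    trials are compared and the absolute difference is subtracted from
    every plot (checks and entries) of the trial with the higher mean.
    """
    log = log if log is not None else CorrectionLog()
    work = df.copy()
    for env, env_rows in work.groupby("environment_id"):
        trials = sorted(env_rows["trial_id"].unique())
        if len(trials) < 2:
            continue
        if len(trials) != 2:
            raise ValueError(
                f"environment {env} has {len(trials)} trials; the trial "
                "correction is defined for two"
            )
        for trait in traits:
            means = {}
            for t in trials:
                sel = (env_rows["trial_id"] == t) & (env_rows["is_check"] == 1)
                vals = env_rows.loc[sel, trait].dropna()
                if vals.empty:
                    raise ValueError(
                        f"trial {t} of environment {env} has no check "
                        f"observations for {trait}"
                    )
                means[t] = float(vals.mean())
                log.check_means.append((trait, "trial", f"{env}/{t}", means[t]))
            hi = max(trials, key=lambda t: means[t])
            offset = abs(means[trials[0]] - means[trials[1]])
            if offset == 0.0:
                continue
            sel = (work["environment_id"] == env) & (work["trial_id"] == hi)
            for idx in work.index[sel]:
                orig = work.at[idx, trait]
                if pd.isna(orig):
                    continue
                work.at[idx, trait] = orig - offset
                log.shifts.append(
                    (idx, trait, orig, orig - offset, -offset, "trial")
                )
    return work, log


def flag_outliers(
    df: pd.DataFrame,
    trait: str,
    fit: FitResult | None = None,
    threshold: float = OUTLIER_THRESHOLD,
    log: CorrectionLog | None = None,
) -> tuple[pd.Index, CorrectionLog]:
    """Plots whose standardized base-model residual exceeds ``threshold``.

    Residuals are conditional (plot-level) residuals from the base
    model with all clones fixed; they are standardized by the
    environment-specific residual standard deviation when the fit used
    heterogeneous residuals, else by the pooled one.  Returns the index
    (into ``df``) of flagged plots.
    """
    log = log if log is not None else CorrectionLog()
    if fit is None:
        fit = fit_reml(prepare_frame(df), model_spec("model2", trait))
    resid = fit.residuals()
    sd = fit.residual_sd_per_row()
    if (sd <= 0).all():
        warnings.warn("zero residual variance; outliers cannot be standardized")
        return pd.Index([]), log
    z = (resid / sd.replace(0.0, np.nan)).abs()
    flagged_pos = z.index[z > threshold]
    # map positions in the fit's (NaN-dropped, reindexed) frame back to df
    fit_df = fit.data()
    mask = df[trait].notna()
    orig_index = df.index[mask]
    if len(orig_index) != len(fit_df):
        raise ValueError("fit does not match the supplied table")
    flagged = pd.Index([orig_index[i] for i in flagged_pos])
    for i in flagged_pos:
        log.removed.append(
            (orig_index[i], trait, fit_df[trait].iloc[i], float(z.iloc[i]))
        )
    return flagged, log


def correct_block_effect(
    df: pd.DataFrame,
    trait: str,
    alpha: float = 0.05,
    log: CorrectionLog | None = None,
) -> tuple[pd.DataFrame, CorrectionLog, dict]:
    """Check-based block correction, guarded by an LRT on the block term.

    The base model is fitted with and without the block variance; when
    the LRT is significant at ``alpha``, every block is centred on its
    environment's check mean: plots of block ``k`` are shifted by
    ``-(block check mean - environment check mean)``.  Blocks without
    checks are left uncorrected with a warning.  The two-group trial
    rule generalizes this way to ``k`` blocks.
    """
    log = log if log is not None else CorrectionLog()
    work = prepare_frame(df)
    full = fit_reml(work, model_spec("model2", trait))
    reduced = fit_reml(work, model_spec("model2_noblock", trait))
    stat, p = lrt(full, reduced, df=1)
    info = {"lrt": (stat, p), "applied": False}
    if p >= alpha:
        return df.copy(), log, info
    info["applied"] = True
    out = df.copy()
    for env, env_rows in out.groupby("environment_id"):
        chk = env_rows[(env_rows["is_check"] == 1)][trait].dropna()
        if chk.empty:
            warnings.warn(f"environment {env} has no checks; left unchanged")
            continue
        env_mean = float(chk.mean())
        log.check_means.append((trait, "environment", env, env_mean))
        blocks = env_rows["block_id"].unique()
        if len(blocks) < 2:
            continue  # single block: nothing to centre against
        for b in blocks:
            bsel = env_rows["block_id"] == b
            bchk = env_rows.loc[bsel & (env_rows["is_check"] == 1), trait].dropna()
            if bchk.empty:
                warnings.warn(f"block {b} has no checks; left uncorrected")
                continue
            offset = float(bchk.mean()) - env_mean
            log.check_means.append((trait, "block", b, float(bchk.mean())))
            if offset == 0.0:
                continue
            for idx in env_rows.index[bsel]:
                orig = out.at[idx, trait]
                if pd.isna(orig):
                    continue
                out.at[idx, trait] = orig - offset
                log.shifts.append(
                    (idx, trait, orig, orig - offset, -offset, "block")
                )
    return out, log, info


def preprocess_trait(
    df: pd.DataFrame,
    trait: str,
    alpha: float = 0.05,
    outlier_threshold: float = OUTLIER_THRESHOLD,
    iterate_outliers: bool = False,
) -> tuple[pd.DataFrame, CorrectionLog, dict]:
    """Full correction pipeline for one trait, in the fixed order
    trial correction -> outlier removal -> block correction.

    Outlier removal runs a single pass by default;
    ``iterate_outliers=True`` repeats it until no plot is flagged.
    """
    log = CorrectionLog()
    work, log = correct_trial_effect(df, [trait], log)
    while True:
        flagged, log = flag_outliers(work, trait, threshold=outlier_threshold,
                                     log=log)
        if len(flagged):
            work = work.drop(index=flagged)
        if not iterate_outliers or len(flagged) == 0:
            break
    work, log, info = correct_block_effect(work, trait, alpha=alpha, log=log)
    info["n_outliers"] = len(log.removed)
    return work, log, info
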