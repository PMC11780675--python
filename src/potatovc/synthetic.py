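"""Generation of synthetic augmented-design trials with known truth.

`generate_design` lays out the plot structure (companies, environments,
trials, blocks, rows, columns, checks and unreplicated entries) and
`simulate_trait` / `simulate_bivariate` fill in trait observations from
Gaussian effect draws whose variances are the scenario's ground truth.
All randomness flows from explicit seeds, so identical inputs give
byte-identical output.

The generator emulates the topology of an A-clone stage evaluation:
checks replicated in every environment (at least once per block),
entries grown once per environment of their own company, one designated
2021 environment split into two adjacent trials with the checks
replicated half as often in each, and plot-level plant counts with
occasional missing plants to exercise the yield normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scenario import FamilySpec, SyntheticScenario, TraitSpec

__all__ = [
    "PlotRecord",
    "generate_design",
    "simulate_trait",
    "simulate_bivariate",
    "LayoutError",
]


class LayoutError(ValueError):
    """The requested design does not fit the block/row/column capacity."""


@dataclass
class PlotRecord:
    """One field plot with its full design labels and trait values."""

    clone_id: str
    is_check: int
    is_entry: int
    is_population_entry: int
    is_single_entry: int
    discard_status: int
    segment: str
    family_id: str
    company: str
    year: int
    location: str
    environment_id: str
    trial_id: str
    block_id: str
    row_id: str
    col_id: str
    planted_plants: int
    missing_plants: int
    raw_yield: float | None = None
    trait_values: dict | None = None


DESIGN_COLUMNS = [
    "clone_id", "is_check", "is_entry", "is_population_entry",
    "is_single_entry", "discard_status", "segment", "family_id",
    "company", "year", "location", "environment_id", "trial_id",
    "block_id", "row_id", "col_id", "planted_plants", "missing_plants",
]


def _clone_table(scenario: SyntheticScenario, rng: np.random.Generator):
    """Per-clone metadata: family, segment, discard status, company."""
    companies = scenario.companies()
    rows = []
    for i, fam in enumerate(scenario.families):
        fam: FamilySpec
        company = companies[i % len(companies)]
        # deterministic largest-remainder split of the family into the
        # three discard statuses
        counts = _largest_remainder(fam.size, fam.discard_fractions)
        statuses = np.repeat([0, 1, 2], counts)
        is_pop = int(fam.size >= scenario.min_family_size_for_population)
        for j in range(fam.size):
            rows.append({
                "clone_id": f"{fam.family_id}_{j + 1:02d}",
                "family_id": fam.family_id,
                "segment": fam.segment,
                "discard_status": int(statuses[j]),
                "company": company,
                "is_population_entry": is_pop,
                "is_single_entry": 1 - is_pop,
            })
    columns = ["clone_id", "family_id", "segment", "discard_status",
               "company", "is_population_entry", "is_single_entry"]
    return pd.DataFrame(rows, columns=columns)


def _largest_remainder(total: int, fractions) -> np.ndarray:
    quota = np.asarray(fractions, dtype=float) * total
    counts = np.floor(quota).astype(int)
    rem = total - counts.sum()
    order = np.argsort(-(quota - counts))
    counts[order[:rem]] += 1
    return counts


def generate_design(scenario: SyntheticScenario) -> pd.DataFrame:
    """Lay out all plots of the scenario; trait values are not set.

    Returns a plot table (one row per plot) with the design columns;
    use :func:`as_records` for a ``PlotRecord`` view.

    Raises
    ------
    LayoutError
        if a block would need more plots than rows x columns provide.
    """
    rng = np.random.default_rng(scenario.seed)
    clones = _clone_table(scenario, rng)
    checks = [f"CHK{i + 1}" for i in range(scenario.n_checks)]
    split_env = scenario.split_env_id()

    plots = []
    for company in scenario.companies():
        entry_ids = clones.loc[clones["company"] == company, "clone_id"].tolist()
        n_blocks = scenario.blocks_for(company)
        for env_id, year, loc in scenario.environment_labels(company):
            pn = scenario.plants_for(env_id)
            if env_id == split_env and scenario.check_reps_per_env >= 2:
                trials = ["T1", "T2"]
                reps_per_trial = scenario.check_reps_per_env // 2
                halves = _split_list(entry_ids, 2, rng)
                blocks_per_trial = max(1, n_blocks // 2)
            else:
                trials = ["T1"]
                reps_per_trial = scenario.check_reps_per_env
                halves = [entry_ids]
                blocks_per_trial = n_blocks
            for trial, trial_entries in zip(trials, halves):
                blocks = [
                    f"{env_id}:{trial}:B{b + 1}" for b in range(blocks_per_trial)
                ]
                # checks: distributed so every block holds each check at
                # least once (requires reps >= blocks)
                if checks and reps_per_trial and reps_per_trial < len(blocks):
                    raise LayoutError(
                        f"{env_id}/{trial}: {reps_per_trial} check reps cannot "
                        f"cover {len(blocks)} blocks"
                    )
                content = {b: [] for b in blocks}
                for chk in checks:
                    reps = [blocks[i % len(blocks)] for i in range(reps_per_trial)]
                    for b in reps:
                        content[b].append(("check", chk))
                order = rng.permutation(len(trial_entries))
                for i, idx in enumerate(order):
                    content[blocks[i % len(blocks)]].append(
                        ("entry", trial_entries[idx])
                    )
                for b in blocks:
                    items = content[b]
                    cap = scenario.rows_per_block * scenario.cols_per_block
                    if len(items) > cap:
                        raise LayoutError(
                            f"block {b} needs {len(items)} plots but the "
                            f"grid capacity is {cap}"
                        )
                    perm = rng.permutation(len(items))
                    for pos, idx in enumerate(perm):
                        kind, cid = items[idx]
                        r = pos // scenario.cols_per_block
                        c = pos % scenario.cols_per_block
                        mp = int(rng.binomial(pn, scenario.missing_rate))
                        plots.append({
                            "clone_id": cid,
                            "is_check": int(kind == "check"),
                            "is_entry": int(kind == "entry"),
                            "company": company,
                            "year": year,
                            "location": loc,
                            "environment_id": env_id,
                            "trial_id": trial,
                            "block_id": b,
                            "row_id": f"{b}:R{r + 1}",
                            "col_id": f"{b}:C{c + 1}",
                            "planted_plants": pn,
                            "missing_plants": mp,
                        })

    df = pd.DataFrame(plots)
    meta = clones.set_index("clone_id")
    for col, default in [
        ("family_id", "CHECKS"), ("segment", "CHECK"),
        ("discard_status", 0), ("is_population_entry", 0),
        ("is_single_entry", 0),
    ]:
        mapped = df["clone_id"].map(meta[col]) if col in meta else None
        df[col] = np.where(df["is_entry"] == 1, mapped, default)
    df["discard_status"] = df["discard_status"].astype(int)
    df["is_population_entry"] = df["is_population_entry"].astype(int)
    df["is_single_entry"] = df["is_single_entry"].astype(int)
    return df[DESIGN_COLUMNS].reset_index(drop=True)


def _split_list(items, k, rng):
    order = rng.permutation(len(items))
    halves = [[] for _ in range(k)]
    for i, idx in enumerate(order):
        halves[i % k].append(items[idx])
    return halves


# ---------------------------------------------------------------------------
# trait simulation


def _standardize(x: np.ndarray, var: float) -> np.ndarray:
    """Rescale draws so their sample variance (ddof=1) is exactly ``var``."""
    if x.size < 2 or var == 0:
        return np.zeros_like(x) if var == 0 else x
    c = x - x.mean()
    sd = c.std(ddof=1)
    if sd == 0:
        return x
    return c / sd * np.sqrt(var)


def _draw_effects(levels, var, rng, standardize=False):
    x = rng.normal(0.0, np.sqrt(var), len(levels))
    if standardize:
        x = _standardize(x, var)
    return pd.Series(x, index=levels)


def _genotype_effects(design, trait: TraitSpec, rng, standardize=False):
    """Per-clone genotypic values following the scenario structure."""
    checks = sorted(design.loc[design["is_check"] == 1, "clone_id"].unique())
    eff = dict(_draw_effects(checks, trait.sigma_g2, rng, standardize))
    ent = design.loc[design["is_entry"] == 1,
                     ["clone_id", "family_id", "segment",
                      "is_population_entry"]].drop_duplicates("clone_id")
    if trait.sigma_p2 is not None:
        pop = ent.loc[ent["is_population_entry"] == 1]
        fams = sorted(pop["family_id"].unique())
        fam_eff = _draw_effects(fams, trait.sigma_p2, rng, standardize)
        hom = not isinstance(trait.sigma_a2, dict)
        devs = {}
        for fam in fams:
            members = sorted(pop.loc[pop["family_id"] == fam, "clone_id"])
            a2 = trait.sigma_a2_for(fam)
            d = rng.normal(0.0, np.sqrt(a2), len(members))
            if standardize and not hom:
                d = _standardize(d, a2)
            devs[fam] = (members, d)
        if standardize and hom and trait.sigma_a2:
            pooled = np.concatenate([d for _, d in devs.values()])
            alls = _standardize(pooled, float(trait.sigma_a2))
            k = 0
            for fam in fams:
                members, d = devs[fam]
                devs[fam] = (members, alls[k: k + len(d)])
                k += len(d)
        for fam in fams:
            members, d = devs[fam]
            for cid, dev in zip(members, d):
                eff[cid] = fam_eff[fam] + dev
        singles = ent.loc[ent["is_population_entry"] == 0]
    else:
        singles = ent
    # single (or all) entries: one variance per segment group, so the
    # standardization acts within each group
    for seg, grp in singles.groupby("segment"):
        g2 = trait.segment_g2.get(seg, trait.sigma_g2)
        ids = sorted(grp["clone_id"])
        vals = _draw_effects(ids, g2, rng, standardize)
        eff.update(dict(vals))
    return pd.Series(eff)


def simulate_trait(
    design: pd.DataFrame,
    trait: TraitSpec,
    seed: int,
    trial_offset: float = 0.0,
    standardize_effects: bool = False,
) -> pd.DataFrame:
    """Return a copy of ``design`` with a column for ``trait`` filled in.

    The observation model is the additive decomposition
    ``y = mu + genotype + environment + GxE(checks) + block + row +
    column + residual`` with the genotype drawn as family mean plus
    within-family deviation for population entries (when ``sigma_p2``
    is configured), a per-segment genotypic variance when configured,
    the residual scaled by the environment's heterogeneity multiplier,
    and family-environment deviations when ``sigma_pe2`` is set.
    ``trial_offset`` is added to every plot of trial T2 of a split
    environment, so the trial correction can be exercised.

    ``standardize_effects=True`` rescales each drawn effect vector so
    its sample variance equals the generating variance exactly (a
    variance-reduction device for parameter-recovery experiments on
    factors with few levels); the default keeps pure Gaussian draws.
    """
    rng = np.random.default_rng(seed)
    std = standardize_effects
    df = design.copy()
    n = len(df)

    g = _genotype_effects(df, trait, rng, standardize=std)
    y = df["clone_id"].map(g).to_numpy(dtype=float)

    envs = sorted(df["environment_id"].unique())
    y += df["environment_id"].map(
        _draw_effects(envs, trait.sigma_e2, rng, std)
    ).to_numpy()

    chk = df["is_check"] == 1
    ge_key = df["clone_id"].astype(str) + "@" + df["environment_id"].astype(str)
    ge_levels = sorted(ge_key[chk].unique())
    ge = _draw_effects(ge_levels, trait.sigma_ge2, rng, std)
    y += np.where(chk, ge_key.map(ge).fillna(0.0), 0.0)

    if trait.sigma_pe2 is not None:
        pop = df["is_population_entry"] == 1
        pe_key = df["family_id"].astype(str) + "@" + df["environment_id"].astype(str)
        pe_levels = sorted(pe_key[pop].unique())
        pe = _draw_effects(pe_levels, trait.sigma_pe2, rng, std)
        y += np.where(pop, pe_key.map(pe).fillna(0.0), 0.0)

    for col, var in [("block_id", trait.sigma_b2), ("row_id", trait.sigma_r2),
                     ("col_id", trait.sigma_h2)]:
        levels = sorted(df[col].unique())
        y += df[col].map(_draw_effects(levels, var, rng, std)).to_numpy()

    eps = rng.normal(0.0, 1.0, n)
    env_arr = df["environment_id"].to_numpy()
    if std:
        for e in envs:
            rows = np.flatnonzero(env_arr == e)
            eps[rows] = _standardize(eps[rows], 1.0)
    mult = df["environment_id"].map(
        lambda e: trait.residual_multipliers.get(e, 1.0)
    ).to_numpy(dtype=float)
    y += eps * np.sqrt(trait.sigma_eps2 * mult)

    if trial_offset:
        y += np.where(df["trial_id"] == "T2", trial_offset, 0.0)

    y = y + trait.mu
    if trait.discretize and trait.scale == "rating_1_9":
        y = np.clip(np.round(y), 1, 9)
    df[trait.name] = y
    if trait.scale == "kilograms":
        # invert the 16-plant normalization so the raw plot yield is
        # consistent with the plant counts
        pn = df["planted_plants"].to_numpy(dtype=float)
        mp = df["missing_plants"].to_numpy(dtype=float)
        denom = np.where(mp / pn > 0.20, pn - mp, pn)
        df["raw_yield"] = y * denom / 16.0
    return df


def simulate_bivariate(
    design: pd.DataFrame,
    trait_a: TraitSpec,
    trait_b: TraitSpec,
    rho_g: float,
    rho_ge: float,
    rho_eps: float,
    seed: int,
) -> pd.DataFrame:
    """Simulate two traits with correlated genotype, GxE and residual effects.

    Genotype, check-GxE and residual effects are drawn from bivariate
    normal distributions with the given correlations; environment,
    block, row and column effects are independent between traits.  The
    marginal structure of each trait matches :func:`simulate_trait`
    (population and segment structure are not applied here; every
    genotype draws from ``sigma_g2``).
    """
    for rho in (rho_g, rho_ge, rho_eps):
        if abs(rho) > 1:
            raise ValueError("correlations must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    df = design.copy()
    n = len(df)

    def biv_draw(levels, v_a, v_b, rho):
        cov = rho * np.sqrt(v_a * v_b)
        S = np.array([[v_a, cov], [cov, v_b]])
        # guard: numerical PSD check for the 2x2
        if np.linalg.eigvalsh(S).min() < -1e-12:
            raise ValueError("non-positive-semidefinite covariance")
        L = np.linalg.cholesky(S + 1e-15 * np.eye(2))
        z = rng.standard_normal((len(levels), 2)) @ L.T
        return (pd.Series(z[:, 0], index=levels),
                pd.Series(z[:, 1], index=levels))

    clones = sorted(df["clone_id"].unique())
    ga, gb = biv_draw(clones, trait_a.sigma_g2, trait_b.sigma_g2, rho_g)
    ya = df["clone_id"].map(ga).to_numpy()
    yb = df["clone_id"].map(gb).to_numpy()

    envs = sorted(df["environment_id"].unique())
    ya += df["environment_id"].map(_draw_effects(envs, trait_a.sigma_e2, rng)).to_numpy()
    yb += df["environment_id"].map(_draw_effects(envs, trait_b.sigma_e2, rng)).to_numpy()

    chk = df["is_check"] == 1
    ge_key = df["clone_id"].astype(str) + "@" + df["environment_id"].astype(str)
    ge_levels = sorted(ge_key[chk].unique())
    gea, geb = biv_draw(ge_levels, trait_a.sigma_ge2, trait_b.sigma_ge2, rho_ge)
    ya += np.where(chk, ge_key.map(gea).fillna(0.0), 0.0)
    yb += np.where(chk, ge_key.map(geb).fillna(0.0), 0.0)

    for col, va, vb in [
        ("block_id", trait_a.sigma_b2, trait_b.sigma_b2),
        ("row_id", trait_a.sigma_r2, trait_b.sigma_r2),
        ("col_id", trait_a.sigma_h2, trait_b.sigma_h2),
    ]:
        levels = sorted(df[col].unique())
        ya += df[col].map(_draw_effects(levels, va, rng)).to_numpy()
        yb += df[col].map(_draw_effects(levels, vb, rng)).to_numpy()

    cov = rho_eps * np.sqrt(trait_a.sigma_eps2 * trait_b.sigma_eps2)
    S = np.array([[trait_a.sigma_eps2, cov], [cov, trait_b.sigma_eps2]])
    L = np.linalg.cholesky(S + 1e-15 * np.eye(2))
    z = rng.standard_normal((n, 2)) @ L.T
    ya += z[:, 0]
    yb += z[:, 1]

    df[trait_a.name] = ya + trait_a.mu
    df[trait_b.name] = yb + trait_b.mu
    return df


def as_records(df: pd.DataFrame, trait_names=()) -> list[PlotRecord]:
    """PlotRecord view of a plot table."""
    recs = []
    for _, row in df.iterrows():
        recs.append(PlotRecord(
            clone_id=row["clone_id"],
            is_check=int(row["is_check"]),
            is_entry=int(row["is_entry"]),
            is_population_entry=int(row["is_population_entry"]),
            is_single_entry=int(row["is_single_entry"]),
            discard_status=int(row["discard_status"]),
            segment=row["segment"],
            family_id=row["family_id"],
            company=row["company"],
            year=int(row["year"]),
            location=row["location"],
            environment_id=row["environment_id"],
            trial_id=row["trial_id"],
            block_id=row["block_id"],
            row_id=row["row_id"],
            col_id=row["col_id"],
            planted_plants=int(row["planted_plants"]),
            missing_plants=int(row["missing_plants"]),
            raw_yield=row.get("raw_yield"),
            trait_values={t: row[t] for t in trait_names if t in row},
        ))
    return recs
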