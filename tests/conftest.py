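"""Shared fixtures: small synthetic trial networks with known truth."""

import numpy as np
import pandas as pd
import pytest

from potatovc import ladder
from potatovc.scenario import FamilySpec, SyntheticScenario, TraitSpec
from potatovc.synthetic import generate_design, simulate_trait


def mixed_families(n_pop=20, pop_size=8, n_single=10, single_size=4):
    """Families above and below the population threshold."""
    segs = ["ST", "TA", "CR", "FF"]
    fams = [
        FamilySpec(f"P{i:02d}", pop_size, segs[i % 4],
                   (0.7, 0.2, 0.1) if i % 2 == 0 else (1.0, 0.0, 0.0))
        for i in range(n_pop)
    ]
    fams += [
        FamilySpec(f"S{i:02d}", single_size, segs[i % 4])
        for i in range(n_single)
    ]
    return tuple(fams)


@pytest.fixture(scope="session")
def tiny_scenario():
    """Two environments, two checks; the smallest fit-able network."""
    return SyntheticScenario(
        n_companies=1, environments_per_company=2, n_checks=2,
        check_reps_per_env=2,
        families=tuple(FamilySpec(f"F{i}", 6, "TA") for i in range(5)),
        blocks_per_env=2, rows_per_block=6, cols_per_block=6,
        split_trial=False, seed=0,
    )


@pytest.fixture(scope="session")
def tiny_design(tiny_scenario):
    return generate_design(tiny_scenario)


@pytest.fixture(scope="session")
def recovery_scenario():
    """One company, 6 environments, 200 entries (160 in large families)."""
    return SyntheticScenario(
        n_companies=1, environments_per_company=6,
        families=mixed_families(),
        blocks_per_env=2, rows_per_block=12, cols_per_block=12,
        split_trial=False, seed=1,
    )


@pytest.fixture(scope="session")
def recovery_design(recovery_scenario):
    return generate_design(recovery_scenario)


@pytest.fixture(scope="session")
def small_trait():
    return TraitSpec(
        "T", sigma_g2=0.6, sigma_e2=0.3, sigma_ge2=0.2, sigma_b2=0.05,
        sigma_r2=0.05, sigma_h2=0.05, sigma_eps2=0.4,
    )


@pytest.fixture(scope="session")
def simulated_small(recovery_design, small_trait):
    """One simulated dataset on the recovery design, model-3 structure."""
    sim = simulate_trait(recovery_design, small_trait, seed=42)
    return ladder.prepare_frame(sim)


def one_way(n_groups=50, reps=4, sg2=2.0, se2=1.0, seed=0, mu=3.0):
    """Balanced one-way layout with random group effects."""
    rng = np.random.default_rng(seed)
    grp = np.repeat(np.arange(n_groups), reps)
    y = mu + rng.normal(0, np.sqrt(sg2), n_groups)[grp] \
        + rng.normal(0, np.sqrt(se2), n_groups * reps)
    return pd.DataFrame({"y": y, "grp": [f"g{i:03d}" for i in grp]})


def anova_one_way(df):
    """Closed-form ANOVA (method of moments) estimators; REML oracle
    on balanced data."""
    reps = df.groupby("grp").size().iloc[0]
    means = df.groupby("grp")["y"].mean()
    msb = reps * means.var(ddof=1)
    within = df["y"] - df["grp"].map(means)
    mse = float((within ** 2).sum() / (len(df) - len(means)))
    return (msb - mse) / reps, mse
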