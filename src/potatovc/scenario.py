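"""Scenario descriptions for synthetic augmented multi-environment trials.

A :class:`SyntheticScenario` captures the design topology of an
A-clone-stage potato evaluation network: several breeding companies,
each testing its own unreplicated entries in its own year-location
combinations (environments), tied together by a common set of
replicated check varieties.  A :class:`TraitSpec` carries the
ground-truth variance components used to simulate trait values on that
design, so parameter recovery can be scored against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

MARKET_SEGMENTS = ("ST", "TA", "CR", "FF")


@dataclass(frozen=True)
class FamilySpec:
    """One full-sib family (segregating population) of entry clones."""

    family_id: str
    size: int
    segment: str = "TA"
    # fraction of the family's clones carrying discard status 0/1/2
    discard_fractions: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self):
        if self.size < 1:
            raise ValueError("family size must be >= 1")
        if self.segment not in MARKET_SEGMENTS:
            raise ValueError(
                f"segment must be one of {MARKET_SEGMENTS}, got {self.segment!r}"
            )
        if abs(sum(self.discard_fractions) - 1.0) > 1e-9:
            raise ValueError("discard fractions must sum to 1")
        if any(f < 0 for f in self.discard_fractions):
            raise ValueError("discard fractions must be non-negative")


@dataclass(frozen=True)
class TraitSpec:
    """Ground-truth stochastic structure of one trait.

    Variances follow the standard decomposition of plot values into
    genotype, environment, genotype-environment interaction (checks),
    block, row, column and residual.  Optional structure: per-environment
    residual multipliers (heterogeneity), per-segment genotypic
    variances, an inter-population variance ``sigma_p2`` with
    within-family variances ``sigma_a2`` (scalar, or dict per family),
    and a population-environment interaction variance ``sigma_pe2``.
    """

    name: str
    scale: str = "rating_1_9"  # rating_1_9 | percentage | kilograms
    mu: float = 5.0
    sigma_g2: float = 1.0
    sigma_e2: float = 0.5
    sigma_ge2: float = 0.3
    sigma_b2: float = 0.05
    sigma_r2: float = 0.05
    sigma_h2: float = 0.05
    sigma_eps2: float = 0.5
    residual_multipliers: dict = field(default_factory=dict)
    segment_g2: dict = field(default_factory=dict)
    sigma_p2: float | None = None
    sigma_a2: float | dict | None = None
    sigma_pe2: float | None = None
    trait_class: str = "agronomic"  # agronomic | quality
    discretize: bool = False

    def __post_init__(self):
        for nm in ("sigma_g2", "sigma_e2", "sigma_ge2", "sigma_b2",
                   "sigma_r2", "sigma_h2", "sigma_eps2"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be >= 0")
        if any(m <= 0 for m in self.residual_multipliers.values()):
            raise ValueError("residual multipliers must be > 0")
        if any(v < 0 for v in self.segment_g2.values()):
            raise ValueError("segment genotypic variances must be >= 0")
        if self.sigma_p2 is not None and self.sigma_p2 < 0:
            raise ValueError("sigma_p2 must be >= 0")
        if self.sigma_pe2 is not None and self.sigma_pe2 < 0:
            raise ValueError("sigma_pe2 must be >= 0")
        if isinstance(self.sigma_a2, dict):
            if any(v < 0 for v in self.sigma_a2.values()):
                raise ValueError("sigma_a2 values must be >= 0")
        elif self.sigma_a2 is not None and self.sigma_a2 < 0:
            raise ValueError("sigma_a2 must be >= 0")
        if self.scale not in ("rating_1_9", "percentage", "kilograms"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.trait_class not in ("agronomic", "quality"):
            raise ValueError(f"unknown trait class {self.trait_class!r}")
        total = (self.sigma_g2 + self.sigma_e2 + self.sigma_ge2
                 + self.sigma_b2 + self.sigma_r2 + self.sigma_h2
                 + self.sigma_eps2)
        if total <= 0:
            raise ValueError("sum of component variances must be > 0")

    def sigma_a2_for(self, family_id: str) -> float:
        if isinstance(self.sigma_a2, dict):
            return self.sigma_a2[family_id]
        return 0.0 if self.sigma_a2 is None else float(self.sigma_a2)


@dataclass(frozen=True)
class SyntheticScenario:
    """Design topology plus traits for one synthetic trial network.

    The default topology mirrors the study design the package targets:
    3 companies x 5 year-location combinations = 15 environments, with
    8 common checks replicated 8 times per environment, and one 2021
    environment of the first company split into two adjacent trials in
    which the checks are replicated half as often each.
    """

    n_companies: int = 3
    environments_per_company: int = 5
    n_checks: int = 8
    check_reps_per_env: int = 8
    families: tuple = ()
    blocks_per_env: int | dict = 4
    rows_per_block: int = 12
    cols_per_block: int = 12
    plants_per_plot: int | dict = 16
    missing_rate: float = 0.02
    split_trial: bool = True
    trial_offset: float = 0.5
    min_family_size_for_population: int = 6
    traits: tuple = ()
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "families", tuple(self.families))
        object.__setattr__(self, "traits", tuple(self.traits))
        if self.n_companies < 1 or self.environments_per_company < 1:
            raise ValueError("need at least one company and one environment")
        if self.n_checks < 0 or self.check_reps_per_env < 0:
            raise ValueError("check counts must be >= 0")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be in [0, 1]")

    # -- derived layout -----------------------------------------------------

    def companies(self) -> list[str]:
        return [f"B{i + 1}" for i in range(self.n_companies)]

    def environment_labels(self, company: str) -> list[tuple[str, int, str]]:
        """(environment_id, year, location) labels for one company.

        Years and locations follow the study pattern: one location in
        the first year, two locations in each later year.
        """
        base = [(19, "L1"), (20, "L1"), (20, "L2"), (21, "L1"), (21, "L2")]
        labels = []
        for k in range(self.environments_per_company):
            if k < len(base):
                year, loc = base[k]
            else:  # extend the pattern beyond five environments
                year = 22 + (k - len(base)) // 2
                loc = f"L{(k - len(base)) % 2 + 1}"
            labels.append((f"{company}_{year}_{loc}", 2000 + year, loc))
        return labels

    def blocks_for(self, company: str) -> int:
        if isinstance(self.blocks_per_env, dict):
            return int(self.blocks_per_env[company])
        return int(self.blocks_per_env)

    def plants_for(self, env_id: str) -> int:
        if isinstance(self.plants_per_plot, dict):
            return int(self.plants_per_plot[env_id])
        return int(self.plants_per_plot)

    def split_env_id(self) -> str | None:
        """The designated split-trial environment (first company, 2021)."""
        if not self.split_trial:
            return None
        comp = self.companies()[0]
        for env_id, year, _ in self.environment_labels(comp):
            if year == 2021:
                return env_id
        return None

    def with_traits(self, *traits: TraitSpec) -> "SyntheticScenario":
        return replace(self, traits=tuple(traits))


def default_families(
    n_families: int = 45,
    segments: tuple = MARKET_SEGMENTS,
    max_size: int = 38,
    discarded_share: float = 0.3,
) -> tuple[FamilySpec, ...]:
    """A deterministic family list echoing a realistic size spectrum.

    Sizes cycle from 1 up to ``max_size`` so that singleton families,
    small families (below the population threshold) and large families
    are all represented.  Roughly ``discarded_share`` of the clones
    carry a discard status, split 4:1 between status 1 and status 2.
    """
    sizes = [((7 * i) % max_size) + 1 for i in range(n_families)]
    fams = []
    for i, size in enumerate(sizes):
        seg = segments[i % len(segments)]
        if i % 3 == 0:
            d1 = discarded_share * 0.8
            d2 = discarded_share * 0.2
            frac = (1.0 - d1 - d2, d1, d2)
        elif i % 3 == 1:
            frac = (1.0 - discarded_share, discarded_share, 0.0)
        else:
            frac = (1.0, 0.0, 0.0)
        fams.append(FamilySpec(f"F{i + 1:03d}", size, seg, frac))
    return tuple(fams)


def default_scenario(seed: int = 0, **overrides) -> SyntheticScenario:
    """The study-like default: 3 companies x 5 environments, 8 checks x 8."""
    kwargs = dict(
        families=default_families(),
        blocks_per_env={"B1": 8, "B2": 4, "B3": 4},
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticScenario(**kwargs)
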