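"""Reading and writing plot tables, trait catalogs, configs and reports.

The on-disk plot table is a comma-delimited file with a header, one row
per plot, traits as wide columns and ``NA`` as the missing-value token.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import DESIGN_COLUMNS, PlotRecord, as_records

__all__ = [
    "SchemaError",
    "TraitCatalog",
    "TraitInfo",
    "RunConfig",
    "read_plot_table",
    "read_plot_records",
    "write_plot_table",
    "write_report",
    "DEFAULT_CATALOG",
]

NA_TOKEN = "NA"

REQUIRED_COLUMNS = DESIGN_COLUMNS

_INT_COLUMNS = [
    "is_check", "is_entry", "is_population_entry", "is_single_entry",
    "discard_status", "year", "planted_plants", "missing_plants",
]


class SchemaError(ValueError):
    """The plot table violates the expected schema."""


@dataclass(frozen=True)
class TraitInfo:
    abbreviation: str
    name: str
    unit: str
    trait_class: str  # "A" (agronomic) or "Q" (quality)
    years: tuple = (2019, 2020, 2021)
    good_direction: str = "high"  # which end of the scale is desirable

    def __post_init__(self):
        if self.trait_class not in ("A", "Q"):
            raise ValueError("trait class must be 'A' or 'Q'")


@dataclass
class TraitCatalog:
    """Registry of trait abbreviations, units, classes and directions."""

    traits: dict = field(default_factory=dict)

    def add(self, info: TraitInfo):
        if info.abbreviation in self.traits:
            raise ValueError(f"duplicate abbreviation {info.abbreviation!r}")
        self.traits[info.abbreviation] = info

    def __getitem__(self, abbr: str) -> TraitInfo:
        return self.traits[abbr]

    def __contains__(self, abbr: str) -> bool:
        return abbr in self.traits

    def abbreviations(self) -> list:
        return list(self.traits)

    def of_class(self, trait_class: str) -> list:
        return [a for a, t in self.traits.items()
                if t.trait_class == trait_class]


def _default_catalog() -> TraitCatalog:
    """The 26 standard potato evaluation traits."""
    late = (2020, 2021)
    entries = [
        ("STA", "starch content", "%", "Q"),
        ("SHL", "tuber shape longitudinally", "1-9", "A"),
        ("PPO", "polyphenol oxidase activity", "1-9", "Q"),
        ("FLE", "flesh color", "1-9", "Q"),
        ("BRU", "susceptibility to bruising", "%", "Q", late),
        ("TUL", "proportion of large tubers >65mm", "%", "A", late),
        ("SKC", "skin color", "1-9", "A"),
        ("CR8", "crisps color after storage at 8C", "1-9", "Q", late),
        ("MAT", "maturity", "1-9", "A"),
        ("TUS", "proportion of small tubers <35mm", "%", "A", late),
        ("EYE", "eye depth", "1-9", "A"),
        ("SKT", "skin texture", "1-4", "A"),
        ("TUN", "proportion of normal tubers 35-65mm", "%", "A", late),
        ("YLD", "total tuber yield", "kg", "A"),
        ("SIZ", "tuber size", "1-9", "A"),
        ("CR4", "crisps color after storage at 4C", "1-9", "Q", late),
        ("FRI", "french fry color", "1-9", "Q", late),
        ("EMR", "emergence", "1-9", "A"),
        ("DEV", "foliage development", "1-9", "A"),
        ("IMP", "general impression", "1-9", "A"),
        ("DSC", "after cooking discoloration", "1-9", "Q", late),
        ("TEX", "texture", "1-9", "Q", late),
        ("TST", "taste", "1-9", "Q", late),
        ("RHI", "rhizoctonia symptoms", "1-9", "A"),
        ("SHD", "tuber shape diagonally", "1-9", "A"),
        ("SCA", "scab symptoms", "1-9", "A"),
    ]
    cat = TraitCatalog()
    for e in entries:
        years = e[4] if len(e) > 4 else (2019, 2020, 2021)
        cat.add(TraitInfo(e[0], e[1], e[2], e[3], years))
    return cat


DEFAULT_CATALOG = _default_catalog()


@dataclass
class RunConfig:
    """Pipeline configuration with the analysis defaults."""

    input: str | None = None
    traits: list = field(default_factory=list)
    alpha: float = 0.05
    outlier_threshold: float = 3.5
    n_perm: int = 100
    sampling_rounds: int = 50
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.outlier_threshold <= 0:
            raise ValueError("outlier threshold must be > 0")
        if self.n_perm < 0 or self.sampling_rounds < 0:
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


def read_plot_table(path) -> pd.DataFrame:
    """Read a plot table, validating the required design columns.

    Unknown columns are preserved as trait columns and must be numeric
    (or NA); a non-numeric cell raises with its row index.
    """
    df = pd.read_csv(path, na_values=[NA_TOKEN], keep_default_na=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"plot table misses required columns: {missing}")
    for col in _INT_COLUMNS:
        try:
            df[col] = df[col].astype(int)
        except (TypeError, ValueError) as err:
            raise SchemaError(f"column {col!r} is not integral: {err}")
    trait_cols = [
        c for c in df.columns
        if c not in REQUIRED_COLUMNS and c != "raw_yield"
    ]
    for col in trait_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(
                f"non-numeric value in trait column {col!r} at row "
                f"{int(bad[0])}: {df[col].iloc[bad[0]]!r}"
            )
        df[col] = coerced
    return df


def read_plot_records(path) -> list[PlotRecord]:
    df = read_plot_table(path)
    trait_cols = [c for c in df.columns if c not in REQUIRED_COLUMNS
                  and c != "raw_yield"]
    return as_records(df, trait_cols)


def write_plot_table(df: pd.DataFrame, path):
    df.to_csv(path, index=False, na_rep=NA_TOKEN)


def _varcomp_frame(fit) -> pd.DataFrame:
    rows = []
    for name, val in fit.varcomp.items():
        if isinstance(val, dict):
            for g, v in val.items():
                rows.append({"component": name, "group": g, "variance": v})
        else:
            rows.append({"component": name, "group": "", "variance": val})
    if isinstance(fit.resid, dict):
        for g, v in fit.resid.items():
            rows.append({"component": "residual", "group": g, "variance": v})
    else:
        rows.append({"component": "residual", "group": "",
                     "variance": fit.resid})
    out = pd.DataFrame(rows)
    flagged = {(n, g) for n, g in fit.boundary}
    out["boundary"] = [
        (r["component"], r["group"]) in flagged for _, r in out.iterrows()
    ]
    return out


def write_report(results: dict, outdir) -> list[Path]:
    """Write machine-readable tables for any stage results.

    ``results`` maps names to stage outputs: REML fits become
    variance-component tables, DataFrames/Series are written as CSV,
    dicts of scalars become two-column tables.  A ``log`` entry (dict)
    is written as YAML.  Returns the written paths; an empty mapping
    yields an empty report directory.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, obj in results.items():
        if hasattr(obj, "varcomp"):
            path = outdir / f"{name}_varcomp.csv"
            _varcomp_frame(obj).to_csv(path, index=False, na_rep=NA_TOKEN)
        elif isinstance(obj, pd.DataFrame):
            path = outdir / f"{name}.csv"
            obj.to_csv(path, na_rep=NA_TOKEN)
        elif isinstance(obj, pd.Series):
            path = outdir / f"{name}.csv"
            obj.rename(name).to_csv(path, na_rep=NA_TOKEN)
        elif isinstance(obj, dict):
            path = outdir / f"{name}.yaml"
            with open(path, "w") as fh:
                yaml.safe_dump(_plain(obj), fh, sort_keys=False)
        else:
            path = outdir / f"{name}.txt"
            path.write_text(repr(obj) + "\n")
        written.append(path)
    return written


def _plain(obj):
    """YAML-serializable view of nested results."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (pd.Series, pd.DataFrame, np.ndarray)):
        return _plain(np.asarray(obj).tolist())
    return obj
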