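"""File formats and run configuration.

Cohort CSV (long format, one row per examination)::

    child_id,sex,birth_date,exam_date,height_cm,weight_kg

with sex in {M, F} (case-insensitive on read), ISO-8601 dates, "." decimals.
Duplicate (child_id, exam_date) pairs are rejected; rows failing the
plausibility gates (30 < height < 230 cm, 5 < weight < 250 kg) are excluded
and reported with their line numbers, never silently dropped.

LMS reference CSV::

    sex,age_years,L,M,S

validated on read (S > 0, strictly increasing age grid per sex).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .anthro import HEIGHT_RANGE_CM, LMSReference, WEIGHT_RANGE_KG
from .synthetic_cohort import SimCohortConfig

__all__ = [
    "CohortReadError",
    "read_cohort",
    "write_cohort",
    "read_lms",
    "write_lms",
    "RunConfig",
    "load_config",
]

COHORT_COLUMNS = ["child_id", "sex", "birth_date", "exam_date", "height_cm", "weight_kg"]
LMS_COLUMNS = ["sex", "age_years", "L", "M", "S"]

_FLOAT_FORMAT = "%.6f"


class CohortReadError(ValueError):
    """Raised when a cohort file has structural problems; carries the full
    list of row-level messages."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("cohort file invalid:\n" + "\n".join(errors))


def read_cohort(path) -> tuple[pd.DataFrame, list[str]]:
    """Read and validate a cohort CSV.

    Returns (table, warnings): the typed table of accepted rows and the list
    of per-row warnings for excluded implausible rows (with 1-based data line
    numbers counted after the header). Structural errors — missing columns,
    unparseable dates/numbers, duplicate (child_id, exam_date) — raise
    :class:`CohortReadError` listing every offence.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"child_id": str, "sex": str})
    errors: list[str] = []
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortReadError([f"missing column(s): {', '.join(missing)}"])
    df = df[COHORT_COLUMNS].copy()
    df["sex"] = df["sex"].str.upper().str.strip()
    bad_sex = ~df["sex"].isin(["M", "F"])
    for i in df.index[bad_sex]:
        errors.append(f"line {i + 2}: sex must be M or F, got {df.at[i, 'sex']!r}")
    for col in ("birth_date", "exam_date"):
        parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
        for i in df.index[parsed.isna()]:
            errors.append(f"line {i + 2}: unparseable {col} {df.at[i, col]!r}")
        df[col] = parsed
    for col in ("height_cm", "weight_kg"):
        vals = pd.to_numeric(df[col], errors="coerce")
        for i in df.index[vals.isna() & df[col].notna()]:
            errors.append(f"line {i + 2}: non-numeric {col} {df.at[i, col]!r}")
        for i in df.index[df[col].isna()]:
            errors.append(f"line {i + 2}: missing {col}")
        df[col] = vals
    dup = df.duplicated(subset=["child_id", "exam_date"], keep=False)
    if dup.any():
        for (cid, d), grp in df[dup].groupby(["child_id", "exam_date"], dropna=False):
            lines = ", ".join(str(i + 2) for i in grp.index)
            errors.append(f"duplicate (child_id={cid}, exam_date={d.date() if pd.notna(d) else d}) at lines {lines}")
    if errors:
        raise CohortReadError(errors)

    warnings: list[str] = []
    h, w = df["height_cm"], df["weight_kg"]
    implausible = ~(
        (h > HEIGHT_RANGE_CM[0]) & (h < HEIGHT_RANGE_CM[1])
        & (w > WEIGHT_RANGE_KG[0]) & (w < WEIGHT_RANGE_KG[1])
    )
    for i in df.index[implausible]:
        warnings.append(
            f"line {i + 2}: implausible measurement (height={h[i]}, weight={w[i]}); row excluded"
        )
    df = df[~implausible].reset_index(drop=True)
    df["birth_date"] = df["birth_date"].dt.strftime("%Y-%m-%d")
    df["exam_date"] = df["exam_date"].dt.strftime("%Y-%m-%d")
    return df, warnings


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write the cohort CSV with a fixed column order and float format."""
    out = cohort[COHORT_COLUMNS].copy()
    out.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_lms(path) -> LMSReference:
    """Read and validate an LMS reference CSV."""
    df = pd.read_csv(path)
    missing = [c for c in LMS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"LMS file missing column(s): {', '.join(missing)}")
    if df.empty:
        raise ValueError("LMS file is empty")
    df["sex"] = df["sex"].astype(str).str.upper().str.strip()
    return LMSReference(df[LMS_COLUMNS])


def write_lms(reference: LMSReference, path) -> None:
    reference.to_frame().to_csv(path, index=False, float_format="%.10g")


@dataclass
class RunConfig:
    """Pipeline configuration with defaults matching the study protocol:
    at least 8 measurements, endpoint window [16, 18], AUC floor 0.7,
    age split 16, merge resolution 0.1 kg/m^3."""

    cohort_path: str | None = None
    lms_path: str | None = None
    output_dir: str = "tmiscreen-output"
    min_measurements: int = 8
    endpoint_window: tuple[float, float] = (16.0, 18.0)
    min_cases: int = 10
    auc_floor: float = 0.7
    resolution: float = 0.1
    age_split: int = 16
    ages: tuple[int, int] = (7, 18)
    simulation: SimCohortConfig = field(default_factory=SimCohortConfig)
    seed: int = 0
    verbose: bool = False

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        sim = data.pop("simulation", {})
        if isinstance(sim, dict):
            sim_fields = {f.name for f in dataclasses.fields(SimCohortConfig)}
            unknown = set(sim) - sim_fields
            if unknown:
                raise ValueError(f"unknown simulation key(s): {sorted(unknown)}")
            if "last_age_range" in sim:
                sim["last_age_range"] = tuple(sim["last_age_range"])
            sim = SimCohortConfig(**sim)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "endpoint_window" in data:
            data["endpoint_window"] = tuple(data["endpoint_window"])
        if "ages" in data:
            data["ages"] = tuple(data["ages"])
        cfg = cls(simulation=sim, **data)
        # one seed drives everything unless the simulation block overrides it
        if "seed" not in getattr(sim, "__dict__", {}) or sim.seed == 0:
            cfg.simulation = dataclasses.replace(cfg.simulation, seed=cfg.seed)
        return cfg


def load_config(path) -> RunConfig:
    """Load a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return RunConfig.from_dict(data)
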