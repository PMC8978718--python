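"""Anthropometric core: decimal ages, BMI/TMI, LMS z-scores, weight-status
classification, cohort eligibility, endpoint extraction and summary tables.

The central object is :class:`LMSReference`, a sex- and age-indexed table of
LMS parameters (skewness L, median M, coefficient of variation S) against
which a raw index value is standardized:

    z = ((x/M)**L - 1) / (L*S)          (L != 0)
    z = ln(x/M) / S                     (L -> 0)

Overweight is a BMI z-score above +1 SD, obesity above +2 SD, following the
WHO school-age convention. Decimal age is the calendar-day difference between
examination and birth divided by 365.25, and integer age is its floor.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "DAYS_PER_YEAR",
    "OVERWEIGHT_Z",
    "OBESITY_Z",
    "compute_age",
    "bmi",
    "tmi",
    "lms_zscore",
    "lms_inverse",
    "LMSReference",
    "classify_status",
    "add_derived_columns",
    "eligibility_filter",
    "endpoint_outcomes",
    "summarize_cohort",
    "round_half_up",
]

DAYS_PER_YEAR = 365.25

#: z-score bands: overweight 1 < z <= 2, obesity z > 2 (exclusive categories)
OVERWEIGHT_Z = 1.0
OBESITY_Z = 2.0

#: switch to the log form of the LMS transform below this |L|
_L_EPS = 1e-6

HEIGHT_RANGE_CM = (30.0, 230.0)
WEIGHT_RANGE_KG = (5.0, 250.0)


def _as_date(d) -> _dt.date:
    if isinstance(d, _dt.datetime):
        return d.date()
    if isinstance(d, _dt.date):
        return d
    return pd.Timestamp(d).date()


def compute_age(exam_date, birth_date) -> float:
    """Decimal age in years: calendar days between dates divided by 365.25."""
    exam = _as_date(exam_date)
    birth = _as_date(birth_date)
    days = (exam - birth).days
    if days < 0:
        raise ValueError(f"examination date {exam} precedes birth date {birth}")
    return days / DAYS_PER_YEAR


def bmi(weight_kg, height_cm):
    """Body mass index, weight (kg) / height (m)^2."""
    weight_kg = np.asarray(weight_kg, dtype=float)
    height_cm = np.asarray(height_cm, dtype=float)
    if np.any(weight_kg <= 0) or np.any(height_cm <= 0):
        raise ValueError("weight and height must be positive")
    out = weight_kg / (height_cm / 100.0) ** 2
    return float(out) if out.ndim == 0 else out


def tmi(weight_kg, height_cm):
    """Tri-ponderal mass index, weight (kg) / height (m)^3."""
    weight_kg = np.asarray(weight_kg, dtype=float)
    height_cm = np.asarray(height_cm, dtype=float)
    if np.any(weight_kg <= 0) or np.any(height_cm <= 0):
        raise ValueError("weight and height must be positive")
    out = weight_kg / (height_cm / 100.0) ** 3
    return float(out) if out.ndim == 0 else out


def lms_zscore(x, L, M, S):
    """LMS z-score of measurement ``x`` against parameters (L, M, S)."""
    x = np.asarray(x, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(x <= 0):
        raise ValueError("measurement must be positive")
    ratio = x / M
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(
            np.abs(L) < _L_EPS,
            np.log(ratio) / S,
            (np.power(ratio, L) - 1.0) / (L * S),
        )
    return float(z) if z.ndim == 0 else z


def lms_inverse(z, L, M, S):
    """Measurement with z-score ``z``: x = M (1 + L S z)^(1/L), log form for L -> 0."""
    z = np.asarray(z, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    base = 1.0 + L * S * z
    if np.any((np.abs(L) >= _L_EPS) & (base <= 0)):
        raise ValueError("inverse LMS undefined: 1 + L*S*z <= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(
            np.abs(L) < _L_EPS,
            M * np.exp(S * z),
            M * np.power(base, 1.0 / np.where(np.abs(L) < _L_EPS, 1.0, L)),
        )
    return float(x) if x.ndim == 0 else x


class LMSReference:
    """Sex-specific LMS parameter grids with linear age interpolation.

    Parameters
    ----------
    table : DataFrame with columns ``sex`` ('M'/'F'), ``age_years``, ``L``,
        ``M``, ``S``; within each sex the age grid must be strictly
        increasing and S positive.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"sex", "age_years", "L", "M", "S"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"LMS table missing columns: {sorted(missing)}")
        self._grids: dict[str, pd.DataFrame] = {}
        for sex, grp in table.groupby("sex"):
            grp = grp.sort_values("age_years").reset_index(drop=True)
            ages = grp["age_years"].to_numpy(float)
            if np.any(np.diff(ages) <= 0):
                raise ValueError(f"age grid for sex {sex!r} is not strictly increasing")
            if np.any(grp["S"].to_numpy(float) <= 0):
                raise ValueError(f"non-positive S in LMS table for sex {sex!r}")
            if np.any(grp["M"].to_numpy(float) <= 0):
                raise ValueError(f"non-positive M in LMS table for sex {sex!r}")
            self._grids[str(sex)] = grp

    @property
    def sexes(self) -> list[str]:
        return sorted(self._grids)

    def age_range(self, sex: str) -> tuple[float, float]:
        grid = self._grid(sex)
        ages = grid["age_years"].to_numpy(float)
        return float(ages[0]), float(ages[-1])

    def _grid(self, sex: str) -> pd.DataFrame:
        try:
            return self._grids[sex]
        except KeyError:
            raise ValueError(f"no LMS parameters for sex {sex!r}") from None

    def params(self, sex: str, age):
        """Interpolated (L, M, S) at decimal ``age`` (scalar or array)."""
        grid = self._grid(sex)
        ages = grid["age_years"].to_numpy(float)
        age_arr = np.asarray(age, dtype=float)
        lo, hi = ages[0], ages[-1]
        if np.any(age_arr < lo) or np.any(age_arr > hi):
            bad = age_arr[(age_arr < lo) | (age_arr > hi)]
            raise ValueError(
                f"age {np.atleast_1d(bad)[0]:.3f} outside LMS reference grid "
                f"[{lo:g}, {hi:g}] for sex {sex!r}"
            )
        L = np.interp(age_arr, ages, grid["L"].to_numpy(float))
        M = np.interp(age_arr, ages, grid["M"].to_numpy(float))
        S = np.interp(age_arr, ages, grid["S"].to_numpy(float))
        return L, M, S

    def zscore(self, sex: str, age, value):
        L, M, S = self.params(sex, age)
        return lms_zscore(value, L, M, S)

    def value_at_z(self, sex: str, age, z):
        """Index value whose z-score equals ``z`` at this sex and age."""
        L, M, S = self.params(sex, age)
        return lms_inverse(z, L, M, S)

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(
            [g.assign(sex=s) for s, g in sorted(self._grids.items())],
            ignore_index=True,
        )[["sex", "age_years", "L", "M", "S"]]


def classify_status(z) -> str:
    """Weight status from a BMI z-score: normal (z<=1), overweight (1<z<=2), obesity (z>2)."""
    z = float(z)
    if not np.isfinite(z):
        raise ValueError("z-score must be finite")
    if z > OBESITY_Z:
        return "obesity"
    if z > OVERWEIGHT_Z:
        return "overweight"
    return "normal"


def add_derived_columns(cohort: pd.DataFrame, reference: LMSReference) -> pd.DataFrame:
    """Attach decimal age, integer age, BMI, TMI, BMI z-score and a plausibility flag.

    Rows whose height/weight fall outside broad physiologic gates are flagged
    (``plausible == False``) rather than dropped.
    """
    df = cohort.copy()
    exam = pd.to_datetime(df["exam_date"])
    birth = pd.to_datetime(df["birth_date"])
    days = (exam - birth).dt.days
    if (days < 0).any():
        bad = df.loc[days < 0].iloc[0]
        raise ValueError(
            f"examination before birth for child {bad['child_id']!r}"
        )
    df["age"] = days / DAYS_PER_YEAR
    df["age_int"] = np.floor(df["age"]).astype(int)
    h = df["height_cm"].to_numpy(float)
    w = df["weight_kg"].to_numpy(float)
    df["plausible"] = (
        (h > HEIGHT_RANGE_CM[0])
        & (h < HEIGHT_RANGE_CM[1])
        & (w > WEIGHT_RANGE_KG[0])
        & (w < WEIGHT_RANGE_KG[1])
    )
    df["bmi"] = w / (h / 100.0) ** 2
    df["tmi"] = w / (h / 100.0) ** 3
    z = np.full(len(df), np.nan)
    for sex, idx in df.groupby("sex").groups.items():
        sub = df.loc[idx]
        lo, hi = reference.age_range(str(sex))
        in_range = (sub["age"] >= lo) & (sub["age"] <= hi)
        if in_range.any():
            sel = sub.loc[in_range]
            z_vals = reference.zscore(str(sex), sel["age"].to_numpy(), sel["bmi"].to_numpy())
            z[df.index.get_indexer(sel.index)] = np.atleast_1d(z_vals)
    df["bmi_z"] = z
    return df


@dataclass(frozen=True)
class EligibilityReport:
    """Per-child keep/drop decision with the reason for a drop."""

    n_total: int
    n_kept: int
    reasons: pd.DataFrame  # child_id, kept, reason


def eligibility_filter(
    cohort: pd.DataFrame,
    min_measurements: int = 8,
    endpoint_window: tuple[float, float] = (16.0, 18.0),
) -> tuple[pd.DataFrame, EligibilityReport]:
    """Keep children with >= ``min_measurements`` complete rows and at least one
    measurement inside the (closed) endpoint age window.

    Returns the filtered cohort and a per-child report with drop reasons
    (``too_few`` / ``no_endpoint_window``).
    """
    lo, hi = endpoint_window
    rows = []
    kept_ids = []
    for child_id, grp in cohort.groupby("child_id", sort=False):
        n = len(grp)
        in_window = ((grp["age"] >= lo) & (grp["age"] <= hi)).any()
        if n < min_measurements:
            rows.append((child_id, False, "too_few"))
        elif not in_window:
            rows.append((child_id, False, "no_endpoint_window"))
        else:
            rows.append((child_id, True, ""))
            kept_ids.append(child_id)
    reasons = pd.DataFrame(rows, columns=["child_id", "kept", "reason"])
    kept = cohort[cohort["child_id"].isin(kept_ids)].copy()
    report = EligibilityReport(
        n_total=reasons.shape[0], n_kept=len(kept_ids), reasons=reasons
    )
    return kept, report


def endpoint_outcomes(
    cohort: pd.DataFrame,
    endpoint_window: tuple[float, float] = (16.0, 18.0),
) -> pd.DataFrame:
    """Outcome status at late adolescence, one row per child.

    The endpoint is the last measurement whose age falls inside the window;
    its BMI z-score defines the status and the two binary screening outcomes:
    ``ow_incl_ob`` (z > 1, overweight including obesity) and ``ob`` (z > 2).
    """
    lo, hi = endpoint_window
    window = cohort[(cohort["age"] >= lo) & (cohort["age"] <= hi)]
    if window.empty:
        raise ValueError("no measurements inside the endpoint window")
    last = window.sort_values("age").groupby("child_id", sort=False).tail(1)
    out = pd.DataFrame(
        {
            "child_id": last["child_id"].to_numpy(),
            "sex": last["sex"].to_numpy(),
            "endpoint_age": last["age"].to_numpy(),
            "endpoint_bmi_z": last["bmi_z"].to_numpy(),
        }
    )
    out["status"] = [classify_status(z) for z in out["endpoint_bmi_z"]]
    out["ow_incl_ob"] = out["endpoint_bmi_z"] > OVERWEIGHT_Z
    out["ob"] = out["endpoint_bmi_z"] > OBESITY_Z
    return out.reset_index(drop=True)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (the convention of printed clinical tables)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def summarize_cohort(
    cohort: pd.DataFrame, endpoints: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Cohort characteristics by sex: sample sizes, baseline age/BMI/TMI means
    (baseline = chronologically first measurement per child), follow-up time,
    endpoint age and the exclusive normal/overweight/obesity counts with
    percentages rounded half-up to one decimal.
    """
    if cohort.empty:
        raise ValueError("empty cohort")
    if endpoints is None:
        endpoints = endpoint_outcomes(cohort)
    first = cohort.sort_values("age").groupby("child_id", sort=False).head(1)
    last = cohort.sort_values("age").groupby("child_id", sort=False).tail(1)
    followup = (
        last.set_index("child_id")["age"] - first.set_index("child_id")["age"]
    )
    n_total = cohort["child_id"].nunique()
    rows = []
    for sex in sorted(cohort["sex"].unique()):
        f = first[first["sex"] == sex]
        ep = endpoints[endpoints["sex"] == sex]
        n = f["child_id"].nunique()
        counts = ep["status"].value_counts()
        n_ep = len(ep)
        row = {
            "sex": sex,
            "n": n,
            "pct_of_total": round_half_up(100.0 * n / n_total),
            "baseline_age_mean": f["age"].mean(),
            "baseline_age_sd": f["age"].std(),
            "baseline_bmi_mean": f["bmi"].mean(),
            "baseline_bmi_sd": f["bmi"].std(),
            "baseline_tmi_mean": f["tmi"].mean(),
            "baseline_tmi_sd": f["tmi"].std(),
            "followup_years_mean": followup.loc[f["child_id"]].mean(),
            "followup_years_sd": followup.loc[f["child_id"]].std(),
            "endpoint_age_mean": ep["endpoint_age"].mean(),
            "endpoint_age_sd": ep["endpoint_age"].std(),
        }
        for status in ("normal", "overweight", "obesity"):
            c = int(counts.get(status, 0))
            row[f"{status}_n"] = c
            row[f"{status}_pct"] = round_half_up(100.0 * c / n_ep) if n_ep else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def format_summary(summary: pd.DataFrame) -> str:
    """Plain-text rendering of :func:`summarize_cohort` in the usual
    characteristics-by-sex layout."""
    labels = {"M": "Boys", "F": "Girls"}
    lines = []
    header = f"{'Variable':44s}" + "".join(
        f"{labels.get(r.sex, r.sex):>16s}" for r in summary.itertuples()
    )
    lines.append(header)
    lines.append("-" * len(header))

    def row(label, fmt):
        lines.append(f"{label:44s}" + "".join(f"{fmt(r):>16s}" for r in summary.itertuples()))

    row("Participants, n (%)", lambda r: f"{r.n:,} ({r.pct_of_total:.1f})")
    row("Baseline age, years, mean (SD)", lambda r: f"{r.baseline_age_mean:.1f} ({r.baseline_age_sd:.1f})")
    row("Baseline BMI, kg/m2, mean (SD)", lambda r: f"{r.baseline_bmi_mean:.1f} ({r.baseline_bmi_sd:.1f})")
    row("Baseline TMI, kg/m3, mean (SD)", lambda r: f"{r.baseline_tmi_mean:.1f} ({r.baseline_tmi_sd:.1f})")
    row("Follow-up time, years, mean (SD)", lambda r: f"{r.followup_years_mean:.1f} ({r.followup_years_sd:.1f})")
    row("Endpoint age, years, mean (SD)", lambda r: f"{r.endpoint_age_mean:.1f} ({r.endpoint_age_sd:.1f})")
    for status in ("normal", "overweight", "obesity"):
        row(
            f"{status.capitalize()} at endpoint, n (%)",
            lambda r, s=status: f"{getattr(r, s + '_n'):,} ({getattr(r, s + '_pct'):.1f})",
        )
    return "\n".join(lines)
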