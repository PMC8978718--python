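"""Head-to-head evaluation of cutoff systems.

Four systems are made comparable on a common footing: cohort-derived BMI
cutoffs, cohort-derived TMI cutoffs, reference-based BMI cutoffs (the index
value at z = +1 / +2 of an LMS reference), and the simplified four-threshold
TMI scheme.  Each supplies, for a sex and integer age, a single dichotomizing
threshold; the resulting binary score has a two-point ROC whose area is
(sensitivity + specificity)/2, which is the AUC reported for every scheme so
comparisons are internally consistent.

Equality of two schemes' ROC curves on the same subjects is tested with the
paired DeLong method applied to the binary scores; per-age comparisons are
reported with raw and Holm-adjusted p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .anthro import LMSReference, OBESITY_Z, OVERWEIGHT_Z
from .cutoff_derivation import delong_placements, predictor_at_age
from .cutoff_models import SimplifiedScheme, binary_cutoff_rates

__all__ = [
    "CohortCutoffScheme",
    "ReferenceBMIScheme",
    "SimplifiedTMIScheme",
    "evaluate_scheme",
    "evaluate_schemes_table",
    "compare_schemes_delong",
    "empirical_centiles",
    "screening_diagram",
    "format_screening_flowchart",
]


# --------------------------------------------------------------------------
# Scheme adapters: anything with .scheme_id, .index, .threshold(sex, age, outcome)
# --------------------------------------------------------------------------


class CohortCutoffScheme:
    """Thresholds from a derived cutoff table (one per sex/age/outcome)."""

    def __init__(self, cutoff_table: pd.DataFrame, scheme_id: str | None = None):
        if cutoff_table.empty:
            raise ValueError("empty cutoff table")
        indices = cutoff_table["index"].unique()
        if len(indices) != 1:
            raise ValueError("cutoff table must concern a single index")
        self.index = str(indices[0])
        self.scheme_id = scheme_id or f"{self.index}-cohort"
        self._tab = cutoff_table.set_index(["sex", "age_int", "outcome"])["cutoff"]

    def threshold(self, sex: str, age_int: int, outcome: str) -> float:
        try:
            return float(self._tab.loc[(sex, age_int, outcome)])
        except KeyError:
            raise KeyError(
                f"scheme {self.scheme_id!r} has no threshold for "
                f"sex={sex} age={age_int} outcome={outcome}"
            ) from None


class ReferenceBMIScheme:
    """BMI thresholds read off an LMS reference at z = +1 (overweight) and
    z = +2 (obesity), evaluated at the midpoint of the integer-age year."""

    index = "bmi"

    def __init__(self, reference: LMSReference, scheme_id: str = "bmi-reference"):
        self.reference = reference
        self.scheme_id = scheme_id

    def threshold(self, sex: str, age_int: int, outcome: str) -> float:
        z = OVERWEIGHT_Z if outcome == "ow_incl_ob" else OBESITY_Z
        return float(self.reference.value_at_z(sex, age_int + 0.5, z))


class SimplifiedTMIScheme:
    """The merged four-threshold TMI scheme (sex-free, two age bands)."""

    index = "tmi"

    def __init__(self, scheme: SimplifiedScheme, scheme_id: str = "tmi-simplified"):
        self.scheme = scheme
        self.scheme_id = scheme_id

    def threshold(self, sex: str, age_int: int, outcome: str) -> float:
        return self.scheme.threshold(age_int, outcome)


# --------------------------------------------------------------------------
# Evaluation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SchemeEvaluation:
    scheme_id: str
    sex: str
    age_int: int
    outcome: str
    threshold: float
    auc: float
    auc_se: float
    sensitivity: float
    specificity: float
    correctly_classified: float
    n: int
    n_cases: int


def _marker_and_outcome(cohort, endpoints, index, sex, age_int, outcome):
    sub = cohort[cohort["sex"] == sex]
    ep = endpoints[endpoints["sex"] == sex].set_index("child_id")
    marker = predictor_at_age(sub, age_int, index)
    marker = marker[marker.index.isin(ep.index)]
    if marker.empty:
        raise ValueError(f"no measurements for sex={sex} at integer age {age_int}")
    y = ep.loc[marker.index, outcome].to_numpy(bool)
    return marker, y


def evaluate_scheme(
    cohort: pd.DataFrame,
    endpoints: pd.DataFrame,
    scheme,
    sex: str,
    age_int: int,
    outcome: str,
) -> SchemeEvaluation:
    """Evaluate one scheme cell: dichotomize the scheme's index at its
    threshold, report sensitivity/specificity, the fixed-cutoff AUC
    (sens+spec)/2, its DeLong SE on the binary score, and the correctly
    classified proportion (TP+TN)/n."""
    thr = scheme.threshold(sex, age_int, outcome)
    marker, y = _marker_and_outcome(cohort, endpoints, scheme.index, sex, age_int, outcome)
    vals = marker.to_numpy(float)
    sens, spec, auc = binary_cutoff_rates(vals, y, thr)
    score = (vals >= thr).astype(float)
    if y.sum() >= 2 and (~y).sum() >= 2:
        v10, v01 = delong_placements(score[y], score[~y])
        var = v10.var(ddof=1) / y.sum() + v01.var(ddof=1) / (~y).sum()
        se = float(np.sqrt(max(var, 0.0)))
    else:
        se = float("nan")
    correct = float(((score >= 1) == y).mean())
    return SchemeEvaluation(
        scheme_id=scheme.scheme_id,
        sex=sex,
        age_int=age_int,
        outcome=outcome,
        threshold=float(thr),
        auc=auc,
        auc_se=se,
        sensitivity=sens,
        specificity=spec,
        correctly_classified=correct,
        n=len(vals),
        n_cases=int(y.sum()),
    )


def evaluate_schemes_table(
    cohort, endpoints, schemes, outcomes=("ow_incl_ob", "ob"), ages=range(7, 19)
) -> pd.DataFrame:
    """Evaluate several schemes over all sex × age × outcome cells where they
    supply a threshold and the cohort has both cases and controls."""
    rows = []
    for scheme in schemes:
        for sex in sorted(cohort["sex"].unique()):
            for age_int in ages:
                for outcome in outcomes:
                    try:
                        rows.append(
                            evaluate_scheme(
                                cohort, endpoints, scheme, sex, age_int, outcome
                            ).__dict__
                        )
                    except (KeyError, ValueError):
                        continue
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ROCComparison:
    scheme_a: str
    scheme_b: str
    sex: str
    age_int: int
    outcome: str
    auc_a: float
    auc_b: float
    auc_diff: float
    se_diff: float
    z_stat: float
    p_value: float
    n: int


def compare_schemes_delong(
    cohort: pd.DataFrame,
    endpoints: pd.DataFrame,
    scheme_a,
    scheme_b,
    sex: str,
    age_int: int,
    outcome: str,
) -> ROCComparison:
    """Paired DeLong test of equality of the two schemes' (binary-score) ROC
    curves on the common subjects.

    var(AUC_a − AUC_b) = S10_a/m + S01_a/n + S10_b/m + S01_b/n − 2(S10_ab/m +
    S01_ab/n) with the placement covariance terms S10_ab, S01_ab.  Identical
    scores give p = 1; a zero-variance nonzero difference gives p = 0.
    """
    thr_a = scheme_a.threshold(sex, age_int, outcome)
    thr_b = scheme_b.threshold(sex, age_int, outcome)
    marker_a, y = _marker_and_outcome(cohort, endpoints, scheme_a.index, sex, age_int, outcome)
    marker_b, y_b = _marker_and_outcome(cohort, endpoints, scheme_b.index, sex, age_int, outcome)
    common = marker_a.index.intersection(marker_b.index)
    marker_a = marker_a.loc[common]
    marker_b = marker_b.loc[common]
    ep = endpoints[endpoints["sex"] == sex].set_index("child_id")
    y = ep.loc[common, outcome].to_numpy(bool)
    score_a = (marker_a.to_numpy(float) >= thr_a).astype(float)
    score_b = (marker_b.to_numpy(float) >= thr_b).astype(float)
    return _paired_delong(
        score_a, score_b, y,
        scheme_a.scheme_id, scheme_b.scheme_id, sex, age_int, outcome,
    )


def _paired_delong(score_a, score_b, y, id_a, id_b, sex, age_int, outcome) -> ROCComparison:
    m = int(y.sum())
    n = int((~y).sum())
    if m < 2 or n < 2:
        raise ValueError("paired DeLong needs >= 2 cases and >= 2 controls")
    v10_a, v01_a = delong_placements(score_a[y], score_a[~y])
    v10_b, v01_b = delong_placements(score_b[y], score_b[~y])
    auc_a = float(v10_a.mean())
    auc_b = float(v10_b.mean())
    diff = auc_a - auc_b
    s10 = np.cov(v10_a, v10_b, ddof=1)
    s01 = np.cov(v01_a, v01_b, ddof=1)
    var = (
        s10[0, 0] / m + s01[0, 0] / n
        + s10[1, 1] / m + s01[1, 1] / n
        - 2 * (s10[0, 1] / m + s01[0, 1] / n)
    )
    se = float(np.sqrt(max(var, 0.0)))
    if np.array_equal(score_a, score_b):
        z, p = 0.0, 1.0
    elif se == 0.0:
        z = np.inf if diff != 0 else 0.0
        p = 0.0 if diff != 0 else 1.0
    else:
        z = diff / se
        p = float(2.0 * norm.sf(abs(z)))
    return ROCComparison(
        scheme_a=id_a,
        scheme_b=id_b,
        sex=sex,
        age_int=age_int,
        outcome=outcome,
        auc_a=auc_a,
        auc_b=auc_b,
        auc_diff=float(diff),
        se_diff=se,
        z_stat=float(z),
        p_value=float(min(max(p, 0.0), 1.0)),
        n=m + n,
    )


def compare_schemes_table(
    cohort, endpoints, scheme_a, scheme_b, outcomes=("ow_incl_ob", "ob"), ages=range(7, 19)
) -> pd.DataFrame:
    """All per-sex/age/outcome paired comparisons, with a Holm-adjusted
    p-value column alongside the raw one."""
    from statsmodels.stats.multitest import multipletests

    rows = []
    for sex in sorted(cohort["sex"].unique()):
        for age_int in ages:
            for outcome in outcomes:
                try:
                    rows.append(
                        compare_schemes_delong(
                            cohort, endpoints, scheme_a, scheme_b, sex, age_int, outcome
                        ).__dict__
                    )
                except (KeyError, ValueError):
                    continue
    df = pd.DataFrame(rows)
    if not df.empty:
        df["p_holm"] = multipletests(df["p_value"], method="holm")[1]
    return df


# --------------------------------------------------------------------------
# Centiles and the screening diagram
# --------------------------------------------------------------------------


def empirical_centiles(
    cohort: pd.DataFrame,
    index: str = "tmi",
    percentiles=(5, 15, 50, 85, 95),
    ages=range(7, 19),
) -> pd.DataFrame:
    """Empirical (median-unbiased, Hyndman-Fan type 8) percentiles of the
    index per sex × integer age; empty cells are absent."""
    rows = []
    for sex in sorted(cohort["sex"].unique()):
        sub = cohort[cohort["sex"] == sex]
        for age_int in ages:
            vals = predictor_at_age(sub, age_int, index)
            if vals.empty:
                continue
            row = {"sex": sex, "age_int": age_int, "n": len(vals)}
            q = np.quantile(
                vals.to_numpy(float),
                np.asarray(percentiles) / 100.0,
                method="median_unbiased",
            )
            for p, v in zip(percentiles, np.atleast_1d(q)):
                row[f"p{p}"] = float(v)
            rows.append(row)
    return pd.DataFrame(rows)


def screening_diagram(scheme: SimplifiedScheme) -> dict:
    """Machine-readable risk-screening decision table for the simplified TMI
    scheme: per age band, TMI ranges mapping to low / overweight / obesity
    risk.  Ranges partition [0, inf); lower bounds inclusive."""
    bands = []
    for band, lo_age, hi_age, ow, ob in (
        ("young", 7, scheme.age_split - 1, scheme.ow_young, scheme.ob_young),
        ("old", scheme.age_split, 18, scheme.ow_old, scheme.ob_old),
    ):
        bands.append(
            {
                "band": band,
                "age_min": lo_age,
                "age_max": hi_age,
                "rules": [
                    {"tmi_min": 0.0, "tmi_max": ow, "risk": "low risk"},
                    {"tmi_min": ow, "tmi_max": ob, "risk": "overweight risk"},
                    {"tmi_min": ob, "tmi_max": None, "risk": "obesity risk"},
                ],
            }
        )
    return {"index": "tmi", "units": "kg/m^3", "age_split": scheme.age_split, "bands": bands}


def classify_risk(diagram: dict, age: float, tmi_value: float) -> str:
    """Risk label for one child under the decision table (tmi_min inclusive,
    tmi_max exclusive)."""
    band = diagram["bands"][0] if age < diagram["age_split"] else diagram["bands"][1]
    for rule in band["rules"]:
        hi = rule["tmi_max"]
        if tmi_value >= rule["tmi_min"] and (hi is None or tmi_value < hi):
            return rule["risk"]
    raise AssertionError("decision table does not partition the TMI axis")


def format_screening_flowchart(diagram: dict) -> str:
    """Plain-text flowchart of the screening diagram."""
    lines = [
        "Measure weight (kg) and height (m); TMI = weight / height^3",
        "|",
    ]
    for band in diagram["bands"]:
        lines.append(f"+- age {band['age_min']}-{band['age_max']} years:")
        for rule in band["rules"]:
            lo, hi = rule["tmi_min"], rule["tmi_max"]
            span = f"TMI >= {lo:.1f}" if hi is None else f"{lo:.1f} <= TMI < {hi:.1f}"
            if lo == 0.0:
                span = f"TMI < {hi:.1f}"
            lines.append(f"|    {span:24s} -> {rule['risk']}")
    return "\n".join(lines)
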