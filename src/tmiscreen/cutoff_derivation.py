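"""ROC analysis and optimal-cutoff derivation per sex and integer age.

A childhood index value (BMI or TMI at integer age ``a``) is used as a
continuous marker for the binary late-adolescent outcome. The classification
rule throughout is "positive (at risk) if index >= threshold".

* AUC is the Mann-Whitney probability that a random case outranks a random
  control, ties half-weighted; it equals the trapezoidal area under the
  empirical ROC curve.
* Standard errors and confidence intervals come from DeLong's placement-value
  estimator.
* The optimal cutoff maximizes Youden's J = sensitivity + specificity - 1
  over observed marker values, with ties broken first by higher sensitivity
  (lower false-negative rate — the clinically conservative choice for a
  screening tool) and then by the lower threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "roc_curve",
    "auc_mann_whitney",
    "delong_placements",
    "auc_se_delong",
    "optimal_cutoff",
    "predictor_at_age",
    "derive_cutoff_table",
    "CutoffResult",
]

AGE_RANGE = range(7, 19)


def _validate_groups(cases, controls, min_size=1):
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    if len(cases) < min_size or len(controls) < min_size:
        raise ValueError(
            f"need at least {min_size} case(s) and {min_size} control(s); "
            f"got {len(cases)} and {len(controls)}"
        )
    return cases, controls


def roc_curve(cases, controls):
    """Empirical ROC under the rule "positive if value >= threshold".

    Returns (thresholds, sensitivity, specificity) over the sorted unique
    observed values, augmented with -inf (sens 1, spec 0) and +inf (sens 0,
    spec 1).
    """
    cases, controls = _validate_groups(cases, controls)
    thr = np.concatenate(([-np.inf], np.unique(np.concatenate([cases, controls])), [np.inf]))
    sens = np.array([(cases >= t).mean() for t in thr])
    spec = np.array([(controls < t).mean() for t in thr])
    return thr, sens, spec


def auc_trapezoid(cases, controls):
    """Trapezoidal area under the empirical ROC curve (oracle route).

    ROC points tied on FPR are ordered by (FPR, sensitivity) so vertical
    segments contribute no area and tie-diagonals are halved correctly.
    """
    _, sens, spec = roc_curve(cases, controls)
    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))
    return float(np.trapezoid(sens[order], fpr[order]))


def auc_mann_whitney(cases, controls) -> float:
    """AUC as the Mann-Whitney U statistic over case/control pairs,
    ties counted half."""
    cases, controls = _validate_groups(cases, controls)
    m, n = len(cases), len(controls)
    combined = np.concatenate([cases, controls])
    from scipy.stats import rankdata

    ranks = rankdata(combined)
    r_cases = ranks[:m].sum()
    u = r_cases - m * (m + 1) / 2.0
    return float(u / (m * n))


def delong_placements(cases, controls):
    """DeLong placement values: per-case V10 (fraction of controls it beats,
    ties half) and per-control V01."""
    cases, controls = _validate_groups(cases, controls)
    v10 = np.array([np.mean((c > controls) + 0.5 * (c == controls)) for c in cases])
    v01 = np.array([np.mean((cases > y) + 0.5 * (cases == y)) for y in controls])
    return v10, v01


def auc_se_delong(cases, controls, logit_ci: bool = False):
    """AUC with DeLong standard error and 95% CI.

    var(AUC) = S10/m + S01/n with S10, S01 the sample variances of the
    placement values. The CI is a normal interval on the AUC scale clipped to
    [0, 1]; with ``logit_ci=True`` it is computed on the logit scale instead.
    """
    cases, controls = _validate_groups(cases, controls, min_size=2)
    v10, v01 = delong_placements(cases, controls)
    auc = float(v10.mean())
    var = v10.var(ddof=1) / len(cases) + v01.var(ddof=1) / len(controls)
    se = float(np.sqrt(max(var, 0.0)))
    zq = norm.ppf(0.975)
    if logit_ci and 0.0 < auc < 1.0 and se > 0:
        logit = np.log(auc / (1 - auc))
        se_logit = se / (auc * (1 - auc))
        lo, hi = logit - zq * se_logit, logit + zq * se_logit
        ci = (float(1 / (1 + np.exp(-lo))), float(1 / (1 + np.exp(-hi))))
    else:
        ci = (
            float(np.clip(auc - zq * se, 0.0, 1.0)),
            float(np.clip(auc + zq * se, 0.0, 1.0)),
        )
    return auc, se, ci


def optimal_cutoff(cases, controls):
    """Youden-optimal threshold over observed values.

    Returns (cutoff, sensitivity, specificity). Ties in J are resolved in
    favour of higher sensitivity, then the lower threshold.
    """
    cases, controls = _validate_groups(cases, controls)
    candidates = np.unique(np.concatenate([cases, controls]))
    sens = np.array([(cases >= c).mean() for c in candidates])
    spec = np.array([(controls < c).mean() for c in candidates])
    j = sens + spec - 1.0
    # lexicographic: max J, then max sens, then min threshold
    best = 0
    for k in range(1, len(candidates)):
        if (j[k], sens[k], -candidates[k]) > (j[best], sens[best], -candidates[best]):
            best = k
    return float(candidates[best]), float(sens[best]), float(spec[best])


def predictor_at_age(
    cohort: pd.DataFrame, age_int: int, index: str = "tmi"
) -> pd.Series:
    """Per-child marker value at integer age ``age_int``: the earliest
    measurement whose floored age equals ``age_int``; children without one
    are absent from the result."""
    if index not in ("bmi", "tmi"):
        raise ValueError(f"unknown index {index!r}")
    sel = cohort[cohort["age_int"] == age_int]
    if sel.empty:
        return pd.Series(dtype=float, name=index)
    earliest = sel.sort_values("age").groupby("child_id", sort=False).head(1)
    return earliest.set_index("child_id")[index].rename(index)


@dataclass(frozen=True)
class CutoffResult:
    sex: str
    age_int: int
    index: str
    outcome: str
    cutoff: float
    auc: float
    auc_se: float
    auc_ci_low: float
    auc_ci_high: float
    sensitivity: float
    specificity: float
    false_negative_rate: float
    n_cases: int
    n_controls: int


def derive_cutoff_table(
    cohort: pd.DataFrame,
    endpoints: pd.DataFrame,
    index: str = "tmi",
    outcome: str = "ob",
    ages=AGE_RANGE,
    min_cases: int = 10,
) -> pd.DataFrame:
    """Optimal cutoff with AUC/SE/CI per sex and integer age.

    ``outcome`` is an endpoint column: ``"ow_incl_ob"`` (overweight including
    obesity, z > 1) or ``"ob"`` (obesity, z > 2). Cells with fewer than
    ``min_cases`` cases (or controls) are omitted.
    """
    if outcome not in ("ow_incl_ob", "ob"):
        raise ValueError(f"unknown outcome {outcome!r}")
    ep = endpoints.set_index("child_id")
    rows = []
    for sex in sorted(cohort["sex"].unique()):
        sub = cohort[cohort["sex"] == sex]
        ep_sex = ep[ep["sex"] == sex]
        for age_int in ages:
            marker = predictor_at_age(sub, age_int, index)
            marker = marker[marker.index.isin(ep_sex.index)]
            if marker.empty:
                continue
            y = ep_sex.loc[marker.index, outcome].to_numpy(bool)
            cases = marker.to_numpy(float)[y]
            controls = marker.to_numpy(float)[~y]
            if len(cases) < min_cases or len(controls) < min_cases:
                continue
            cutoff, sens, spec = optimal_cutoff(cases, controls)
            auc, se, ci = auc_se_delong(cases, controls)
            rows.append(
                CutoffResult(
                    sex=sex,
                    age_int=age_int,
                    index=index,
                    outcome=outcome,
                    cutoff=cutoff,
                    auc=auc,
                    auc_se=se,
                    auc_ci_low=ci[0],
                    auc_ci_high=ci[1],
                    sensitivity=sens,
                    specificity=spec,
                    false_negative_rate=1.0 - sens,
                    n_cases=len(cases),
                    n_controls=len(controls),
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])
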