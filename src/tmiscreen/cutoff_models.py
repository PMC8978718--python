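"""Cutoff-age regression models and merging of age-specific TMI cutoffs into
a simplified four-threshold screening scheme.

Two steps sit on top of the per-age cutoff table:

1. :func:`fit_cutoff_age_models` describes how a cutoff varies with age using
   five ordinary-least-squares forms (linear, quadratic, logarithmic,
   log-linear, log-log) and selects the best by adjusted R².  For the two
   log-response forms R² is computed on the transformed (log) scale; adjusted
   R² values are therefore comparable only within a response scale, a caveat
   carried into the output.

2. :func:`simplify_cutoffs` merges the age- and sex-specific cutoffs into a
   single threshold per (outcome, age band), chosen by grid search at 0.1
   resolution.  A candidate threshold is scored by dichotomizing the index at
   every age in the band (sexes pooled) and computing the fixed-cutoff AUC
   (sensitivity + specificity)/2 per age; feasible candidates keep every
   per-age AUC at or above the floor (default 0.7), and among them the scheme
   takes the maximal mean AUC, ties broken by the lower mean false-negative
   rate, then the lower threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cutoff_derivation import predictor_at_age

__all__ = [
    "CutoffAgeFit",
    "fit_cutoff_age_models",
    "SimplifiedScheme",
    "simplify_cutoffs",
    "binary_cutoff_rates",
]

MODEL_FORMS = ("linear", "quadratic", "logarithmic", "log_linear", "log_log")

#: number of slope terms per form (for the adjusted-R² penalty)
_N_SLOPES = {
    "linear": 1,
    "quadratic": 2,
    "logarithmic": 1,
    "log_linear": 1,
    "log_log": 1,
}


@dataclass(frozen=True)
class CutoffAgeFit:
    """One fitted cutoff-vs-age regression form."""

    form: str
    coefficients: tuple[float, ...]  # intercept first
    r2: float
    adj_r2: float
    n: int
    log_response: bool
    best: bool = False

    def predict(self, age) -> np.ndarray:
        t = np.asarray(age, dtype=float)
        c = self.coefficients
        if self.form == "linear":
            y = c[0] + c[1] * t
        elif self.form == "quadratic":
            y = c[0] + c[1] * t + c[2] * t**2
        elif self.form == "logarithmic":
            y = c[0] + c[1] * np.log(t)
        elif self.form == "log_linear":
            y = np.exp(c[0] + c[1] * t)
        elif self.form == "log_log":
            y = np.exp(c[0] + c[1] * np.log(t))
        else:  # pragma: no cover
            raise ValueError(self.form)
        return y


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least squares with intercept; returns (coefficients, R²)."""
    A = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    sst = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / sst if sst > 0 else 1.0
    return coef, float(r2)


def fit_cutoff_age_models(
    ages, cutoffs, parsimony_tol: float = 1e-3
) -> list[CutoffAgeFit]:
    """Fit the five regression forms of cutoff on age; flag the best by
    adjusted R² (adj R² = 1 − (1−R²)(n−1)/(n−p−1), p = slope terms).

    Selection is by maximal adjusted R² with one practical-equivalence rule:
    when the quadratic form wins but the linear form (its nested sub-model on
    the same response scale) is within ``parsimony_tol`` of it, the linear
    form is preferred.  Without this rule a spurious quadratic term outranks
    the true linear form in roughly a third of small-noise replicates (it
    gains adjusted R² whenever its t² > 1), while the gain it offers is then
    an order of magnitude below ``parsimony_tol``.  Non-nested forms are
    never demoted: genuinely equivalent descriptions (e.g. a parabola that is
    also a near-perfect power law) resolve to the higher adjusted R².

    Log-response and log-age forms require positive cutoffs/ages; a form that
    cannot be fitted is skipped. Needs at least 4 points.
    """
    t = np.asarray(ages, dtype=float)
    y = np.asarray(cutoffs, dtype=float)
    if len(t) != len(y):
        raise ValueError("ages and cutoffs must have equal length")
    if len(t) < 4:
        raise ValueError("need at least 4 points to fit cutoff-age models")
    n = len(t)
    fits: list[CutoffAgeFit] = []
    designs = {
        "linear": (t[:, None], y, False),
        "quadratic": (np.column_stack([t, t**2]), y, False),
    }
    if np.all(t > 0):
        designs["logarithmic"] = (np.log(t)[:, None], y, False)
    if np.all(y > 0):
        designs["log_linear"] = (t[:, None], np.log(y), True)
        if np.all(t > 0):
            designs["log_log"] = (np.log(t)[:, None], np.log(y), True)
    for form in MODEL_FORMS:
        if form not in designs:
            continue
        X, resp, logy = designs[form]
        p = _N_SLOPES[form]
        if n - p - 1 <= 0:
            continue
        coef, r2 = _ols(X, resp)
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
        fits.append(
            CutoffAgeFit(
                form=form,
                coefficients=tuple(float(c) for c in coef),
                r2=r2,
                adj_r2=float(adj),
                n=n,
                log_response=logy,
            )
        )
    if not fits:
        raise ValueError("no regression form could be fitted")
    by_form = {f.form: f for f in fits}
    winner = max(fits, key=lambda f: f.adj_r2)
    if winner.form == "quadratic" and "linear" in by_form:
        linear = by_form["linear"]
        if linear.adj_r2 >= winner.adj_r2 - parsimony_tol:
            winner = linear
    return [
        CutoffAgeFit(**{**f.__dict__, "best": f.form == winner.form}) for f in fits
    ]


def fits_to_frame(fits: list[CutoffAgeFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "form": f.form,
                "coefficients": ",".join(f"{c:.6g}" for c in f.coefficients),
                "r2": f.r2,
                "adj_r2": f.adj_r2,
                "n": f.n,
                "log_response_scale": f.log_response,
                "best": f.best,
            }
            for f in fits
        ]
    )


def binary_cutoff_rates(values: np.ndarray, y: np.ndarray, threshold: float):
    """Sensitivity, specificity and fixed-cutoff AUC = (sens+spec)/2 for the
    rule "positive if value >= threshold"."""
    pos = values >= threshold
    n_case = int(y.sum())
    n_ctrl = int((~y).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("need both cases and controls")
    sens = float((pos & y).sum() / n_case)
    spec = float((~pos & ~y).sum() / n_ctrl)
    return sens, spec, (sens + spec) / 2.0


@dataclass(frozen=True)
class BandResult:
    outcome: str
    band: str  # "young" | "old"
    ages: tuple[int, ...]
    threshold: float
    mean_auc: float
    mean_fnr: float
    per_age_auc: dict[int, float]
    feasible: bool


@dataclass(frozen=True)
class SimplifiedScheme:
    """The merged TMI screening scheme: one overweight and one obesity
    threshold per age band (below / at-or-above the split age)."""

    age_split: int
    ow_young: float
    ob_young: float
    ow_old: float
    ob_old: float
    auc_floor: float
    resolution: float
    bands: tuple[BandResult, ...] = field(default_factory=tuple)

    @property
    def feasible(self) -> bool:
        return all(b.feasible for b in self.bands)

    def threshold(self, age_int: int, outcome: str) -> float:
        young = age_int < self.age_split
        if outcome == "ow_incl_ob":
            return self.ow_young if young else self.ow_old
        if outcome == "ob":
            return self.ob_young if young else self.ob_old
        raise ValueError(f"unknown outcome {outcome!r}")


def _search_band(
    cohort: pd.DataFrame,
    endpoints: pd.DataFrame,
    index: str,
    outcome: str,
    ages: list[int],
    candidates: np.ndarray,
    auc_floor: float,
):
    ep = endpoints.set_index("child_id")
    # per-age pooled-sex marker/outcome arrays
    per_age = []
    for a in ages:
        marker = predictor_at_age(cohort, a, index)
        marker = marker[marker.index.isin(ep.index)]
        if marker.empty:
            continue
        y = ep.loc[marker.index, outcome].to_numpy(bool)
        if y.sum() == 0 or (~y).sum() == 0:
            continue
        per_age.append((a, marker.to_numpy(float), y))
    if not per_age:
        raise ValueError(f"no usable ages in band {ages}")
    best = None  # (mean_auc, -mean_fnr, -threshold, record)
    for c in candidates:
        aucs, fnrs = {}, []
        for a, vals, y in per_age:
            sens, spec, auc = binary_cutoff_rates(vals, y, c)
            aucs[a] = auc
            fnrs.append(1.0 - sens)
        mean_auc = float(np.mean(list(aucs.values())))
        mean_fnr = float(np.mean(fnrs))
        feasible = all(v >= auc_floor for v in aucs.values())
        key = (feasible, mean_auc, -mean_fnr, -c)
        rec = (float(c), mean_auc, mean_fnr, aucs, feasible)
        if best is None or key > best[0]:
            best = (key, rec)
    return best[1]


def simplify_cutoffs(
    cohort: pd.DataFrame,
    endpoints: pd.DataFrame,
    cutoff_table: pd.DataFrame,
    index: str = "tmi",
    age_split: int = 16,
    resolution: float = 0.1,
    auc_floor: float = 0.7,
    ages=range(7, 19),
) -> SimplifiedScheme:
    """Merge the age- and sex-specific cutoffs into the simplified scheme.

    ``cutoff_table`` must hold both outcomes for ``index`` (output of
    :func:`~tmiscreen.cutoff_derivation.derive_cutoff_table`, concatenated).
    The candidate grid per (outcome, band) spans floor(min) .. ceil(max) of
    the band's age-sex-specific cutoffs in steps of ``resolution``.
    Infeasible bands (no candidate keeps all per-age AUCs >= ``auc_floor``)
    return the best-effort candidate flagged infeasible.
    """
    ages = list(ages)
    young = [a for a in ages if a < age_split]
    old = [a for a in ages if a >= age_split]
    results = []
    values = {}
    for outcome in ("ow_incl_ob", "ob"):
        tab = cutoff_table[
            (cutoff_table["outcome"] == outcome) & (cutoff_table["index"] == index)
        ]
        if tab.empty:
            raise ValueError(f"cutoff table has no rows for outcome {outcome!r}")
        for band_name, band_ages in (("young", young), ("old", old)):
            band_tab = tab[tab["age_int"].isin(band_ages)]
            src = band_tab if not band_tab.empty else tab
            lo = math.floor(src["cutoff"].min() / resolution) * resolution
            hi = math.ceil(src["cutoff"].max() / resolution) * resolution
            n_steps = int(round((hi - lo) / resolution))
            candidates = np.round(lo + resolution * np.arange(n_steps + 1), 10)
            if len(candidates) == 0:
                raise ValueError("empty candidate range")
            thr, mean_auc, mean_fnr, per_age_auc, feasible = _search_band(
                cohort, endpoints, index, outcome, band_ages, candidates, auc_floor
            )
            results.append(
                BandResult(
                    outcome=outcome,
                    band=band_name,
                    ages=tuple(band_ages),
                    threshold=thr,
                    mean_auc=mean_auc,
                    mean_fnr=mean_fnr,
                    per_age_auc=per_age_auc,
                    feasible=feasible,
                )
            )
            values[(outcome, band_name)] = thr
    return SimplifiedScheme(
        age_split=age_split,
        ow_young=values[("ow_incl_ob", "young")],
        ob_young=values[("ob", "young")],
        ow_old=values[("ow_incl_ob", "old")],
        ob_old=values[("ob", "old")],
        auc_floor=auc_floor,
        resolution=resolution,
        bands=tuple(results),
    )


def scheme_to_frame(scheme: SimplifiedScheme) -> pd.DataFrame:
    rows = []
    for b in scheme.bands:
        rows.append(
            {
                "outcome": b.outcome,
                "band": b.band,
                "ages": f"{min(b.ages)}-{max(b.ages)}",
                "threshold": b.threshold,
                "mean_auc": b.mean_auc,
                "mean_false_negative_rate": b.mean_fnr,
                "min_per_age_auc": min(b.per_age_auc.values()),
                "feasible": b.feasible,
            }
        )
    return pd.DataFrame(rows)
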