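"""Scheme evaluation, paired equality-of-ROC tests, centiles and the
screening decision table."""

import numpy as np
import pandas as pd
import pytest

from tmiscreen.cutoff_models import SimplifiedScheme
from tmiscreen.evaluation import (
    CohortCutoffScheme,
    ReferenceBMIScheme,
    SimplifiedTMIScheme,
    classify_risk,
    compare_schemes_delong,
    empirical_centiles,
    evaluate_scheme,
    format_screening_flowchart,
    screening_diagram,
    _paired_delong,
)

from conftest import make_planted_cohort


def _scheme(ow_young=13.1, ob_young=14.1, ow_old=14.0, ob_old=15.8):
    return SimplifiedScheme(
        age_split=16,
        ow_young=ow_young,
        ob_young=ob_young,
        ow_old=ow_old,
        ob_old=ob_old,
        auc_floor=0.7,
        resolution=0.1,
    )


class TestEvaluateScheme:
    def test_perfect_scheme_on_separable_cohort(self):
        cohort, endpoints = make_planted_cohort(ob_threshold=14.0, n_per_sex=300)
        scheme = SimplifiedTMIScheme(_scheme(ob_young=14.0, ob_old=14.0))
        ev = evaluate_scheme(cohort, endpoints, scheme, "M", 9, "ob")
        assert ev.auc == 1.0
        assert ev.correctly_classified == 1.0
        assert ev.sensitivity == 1.0 and ev.specificity == 1.0

    def test_threshold_below_all_values(self):
        cohort, endpoints = make_planted_cohort(ob_threshold=14.0, n_per_sex=300)
        scheme = SimplifiedTMIScheme(_scheme(ob_young=0.1, ob_old=0.1))
        ev = evaluate_scheme(cohort, endpoints, scheme, "F", 10, "ob")
        assert ev.sensitivity == 1.0 and ev.specificity == 0.0
        assert ev.auc == 0.5

    def test_auc_equals_pair_counting_on_binary_scores(self, small_cohort):
        from tmiscreen.cutoff_derivation import auc_mann_whitney, predictor_at_age

        cohort, endpoints = small_cohort
        scheme = SimplifiedTMIScheme(_scheme())
        ev = evaluate_scheme(cohort, endpoints, scheme, "M", 9, "ow_incl_ob")
        sub = cohort[cohort["sex"] == "M"]
        ep = endpoints[endpoints["sex"] == "M"].set_index("child_id")
        marker = predictor_at_age(sub, 9, "tmi")
        marker = marker[marker.index.isin(ep.index)]
        y = ep.loc[marker.index, "ow_incl_ob"].to_numpy(bool)
        score = (marker.to_numpy(float) >= ev.threshold).astype(float)
        assert ev.auc == pytest.approx(auc_mann_whitney(score[y], score[~y]), abs=1e-12)

    def test_missing_threshold_names_cell(self, small_cohort):
        cohort, endpoints = small_cohort
        table = pd.DataFrame(
            [{"sex": "M", "age_int": 9, "index": "tmi", "outcome": "ob", "cutoff": 14.0}]
        )
        scheme = CohortCutoffScheme(table)
        with pytest.raises(KeyError, match="age=10"):
            evaluate_scheme(cohort, endpoints, scheme, "M", 10, "ob")


class TestPairedDeLong:
    def test_scheme_compared_to_itself(self, small_cohort):
        cohort, endpoints = small_cohort
        scheme = SimplifiedTMIScheme(_scheme())
        comp = compare_schemes_delong(cohort, endpoints, scheme, scheme, "M", 9, "ow_incl_ob")
        assert comp.auc_diff == 0.0
        assert comp.p_value == 1.0

    def test_dominant_scheme_rejected_with_positive_z(self):
        rng = np.random.default_rng(11)
        y = rng.random(400) < 0.3
        latent = rng.normal(size=400) + y * 1.6
        score_a = (latent > 0.8).astype(float)
        # b flips a random 30% of a's labels: strictly noisier
        flip = rng.random(400) < 0.3
        score_b = np.where(flip, rng.random(400) < 0.5, score_a).astype(float)
        comp = _paired_delong(score_a, score_b, y, "a", "b", "M", 9, "ob")
        assert comp.z_stat > 0
        assert comp.p_value < 0.05

    def test_type_i_error_calibrated_under_null(self):
        """Independent binary scores with no signal: rejection rate at
        alpha=0.05 stays within [0.03, 0.07] over 1,000 replicates."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            y = rng.random(500) < 0.3
            # guard against degenerate draws
            if y.sum() < 2 or (~y).sum() < 2:
                continue
            score_a = (rng.random(500) < 0.4).astype(float)
            score_b = (rng.random(500) < 0.4).astype(float)
            comp = _paired_delong(score_a, score_b, y, "a", "b", "M", 9, "ob")
            rejections += comp.p_value < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07


class TestCentiles:
    def test_constant_index(self):
        cohort, _ = make_planted_cohort(n_per_sex=50)
        cohort["tmi"] = 12.5
        table = empirical_centiles(cohort, "tmi")
        for p in (5, 15, 50, 85, 95):
            assert (table[f"p{p}"] == 12.5).all()

    def test_median_of_five(self):
        df = pd.DataFrame(
            {
                "child_id": [f"c{i}" for i in range(5)],
                "sex": "M",
                "age": [9.5] * 5,
                "age_int": [9] * 5,
                "tmi": [10.0, 11.0, 12.0, 13.0, 14.0],
                "bmi": [15.0] * 5,
            }
        )
        table = empirical_centiles(df, "tmi", percentiles=(50,), ages=[9])
        assert table.iloc[0]["p50"] == 12.0

    def test_tmi_flat_while_bmi_rises(self, default_cohort_10k):
        """Median TMI stays within a narrow band over ages 7-18 while median
        BMI climbs by several units."""
        cohort, _ = default_cohort_10k
        tmi_c = empirical_centiles(cohort, "tmi")
        bmi_c = empirical_centiles(cohort, "bmi")
        for sex in ("M", "F"):
            t50 = tmi_c[tmi_c["sex"] == sex].set_index("age_int")["p50"]
            b50 = bmi_c[bmi_c["sex"] == sex].set_index("age_int")["p50"]
            assert t50.max() - t50.min() <= 1.5
            assert b50.max() - b50.min() > 3.0


class TestScreeningDiagram:
    @pytest.mark.parametrize(
        "age, value, risk",
        [
            (10, 13.5, "overweight risk"),
            (17, 16.0, "obesity risk"),
            (10, 12.9, "low risk"),
            (10, 14.1, "obesity risk"),
            (16, 13.9, "low risk"),
            (16, 14.0, "overweight risk"),
        ],
    )
    def test_published_scheme_semantics(self, age, value, risk):
        diagram = screening_diagram(_scheme(13.1, 14.1, 14.0, 15.8))
        assert classify_risk(diagram, age, value) == risk

    def test_ranges_partition_tmi_axis(self):
        diagram = screening_diagram(_scheme())
        for band in diagram["bands"]:
            rules = band["rules"]
            assert rules[0]["tmi_min"] == 0.0
            assert rules[-1]["tmi_max"] is None
            for a, b in zip(rules, rules[1:]):
                assert a["tmi_max"] == b["tmi_min"]

    def test_flowchart_mentions_all_thresholds(self):
        diagram = screening_diagram(_scheme(13.1, 14.1, 14.0, 15.8))
        text = format_screening_flowchart(diagram)
        for v in ("13.1", "14.1", "14.0", "15.8"):
            assert v in text


class TestDirectionalComparison:
    def test_simplified_tmi_outperforms_reference_bmi_at_young_ages(
        self, default_cohort_10k, reference
    ):
        """With reference cutoffs pitched above the cohort's outcome-optimal
        thresholds at young ages, the merged TMI scheme discriminates
        better on average below the age split."""
        from tmiscreen.cutoff_derivation import derive_cutoff_table
        from tmiscreen.cutoff_models import simplify_cutoffs
        from tmiscreen.evaluation import evaluate_schemes_table

        cohort, endpoints = default_cohort_10k
        table = pd.concat(
            [derive_cutoff_table(cohort, endpoints, "tmi", o) for o in ("ow_incl_ob", "ob")],
            ignore_index=True,
        )
        scheme = simplify_cutoffs(cohort, endpoints, table)
        ev = evaluate_schemes_table(
            cohort,
            endpoints,
            [SimplifiedTMIScheme(scheme), ReferenceBMIScheme(reference)],
            ages=range(7, 16),
        )
        mean_auc = ev.groupby("scheme_id")["auc"].mean()
        assert mean_auc["tmi-simplified"] >= mean_auc["bmi-reference"]
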