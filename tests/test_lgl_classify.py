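"""Threshold derivation, criteria evaluation, persistence, classification."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from lglpheno.lgl_classify import (ABERRANCY_FEATURES, ThresholdSet,
                                   assess_persistence, classify_cohort,
                                   derive_thresholds, evaluate_criteria)


def _hc_frame(values) -> pd.DataFrame:
    rows = []
    for i, v in enumerate(values):
        row = {"donor_id": f"HC{i}", "pct_cd8cd57_of_lymph": v}
        row.update({f: v for f in ABERRANCY_FEATURES})
        rows.append(row)
    return pd.DataFrame(rows)


def _thresholds(cd8cd57=3.0, dim=10.0, cd94=10.0, cd56=10.0, klrg1=10.0):
    return ThresholdSet(pct_cd8cd57_cutoff=cd8cd57, aberrancy_cutoffs={
        "pct_cd5dim_cd8cd57": dim, "pct_cd94_cd8cd57": cd94,
        "pct_cd56_cd8cd57": cd56, "pct_klrg1_cd8cd57": klrg1})


class TestDeriveThresholds:
    def test_constant_feature_gives_its_own_value(self):
        ts = derive_thresholds(_hc_frame([5.0] * 12))
        assert ts.aberrancy_cutoffs["pct_cd94_cd8cd57"] == pytest.approx(5.0)

    def test_hand_computed_mean_plus_2sd(self):
        """HC values 0..9: cutoff = 4.5 + 2 x 3.02765 = 10.5553 (sample SD)."""
        ts = derive_thresholds(_hc_frame(np.arange(10.0)))
        for f in ABERRANCY_FEATURES:
            assert ts.aberrancy_cutoffs[f] == pytest.approx(10.5553, abs=1e-3)

    def test_expansion_cutoff_floors_at_3_when_fixed(self):
        ts = derive_thresholds(_hc_frame([1.0] * 12))
        assert ts.pct_cd8cd57_cutoff == 3.0
        ts2 = derive_thresholds(_hc_frame([1.0] * 12), provenance="derived_from_HC")
        assert ts2.pct_cd8cd57_cutoff == pytest.approx(1.0)

    def test_p95_diagnostic_recorded_not_reconciled(self):
        ts = derive_thresholds(_hc_frame(np.arange(20.0)))
        d = ts.diagnostics["pct_cd5dim_cd8cd57"]
        assert d["p95"] != pytest.approx(d["mean_plus_2sd"])

    def test_too_few_donors_rejected(self):
        with pytest.raises(ValueError, match="10"):
            derive_thresholds(_hc_frame([1.0] * 5))

    def test_synthetic_hc_p95_near_3(self, small_features):
        """The HC cohort is calibrated so its 95th percentile of
        %CD8+CD57+ sits near the 3% expansion cutoff."""
        hc = small_features[(small_features["group"] == "HC")
                            & (small_features["visit"] == 0)]
        ts = derive_thresholds(hc)
        assert 1.5 < ts.diagnostics["pct_cd8cd57_of_lymph"]["p95"] < 5.0


class TestEvaluateCriteria:
    def test_high_profile_meets_c1_c2_c3(self):
        feats = {"pct_cd8cd57_of_lymph": 9.12, "cd4_cd8_ratio": 0.8,
                 "pct_cd5dim_cd8cd57": 40.0, "pct_klrg1_cd8cd57": 80.0,
                 "pct_cd94_cd8cd57": 5.0, "pct_cd56_cd8cd57": 5.0}
        flags = evaluate_criteria(feats, _thresholds())
        assert flags == {"c1_expansion": True, "c2_ratio": True,
                         "c3_aberrant": True}

    def test_hc_profile_meets_none(self):
        feats = {"pct_cd8cd57_of_lymph": 1.10, "cd4_cd8_ratio": 2.8,
                 "pct_cd5dim_cd8cd57": 5.0, "pct_klrg1_cd8cd57": 5.0,
                 "pct_cd94_cd8cd57": 5.0, "pct_cd56_cd8cd57": 5.0}
        flags = evaluate_criteria(feats, _thresholds())
        assert flags == {"c1_expansion": False, "c2_ratio": False,
                         "c3_aberrant": False}

    def test_boundary_equality_is_false(self):
        feats = {"pct_cd8cd57_of_lymph": 3.0, "cd4_cd8_ratio": 1.5,
                 "pct_cd5dim_cd8cd57": 10.0, "pct_klrg1_cd8cd57": 10.0,
                 "pct_cd94_cd8cd57": 10.0, "pct_cd56_cd8cd57": 10.0}
        flags = evaluate_criteria(feats, _thresholds())
        assert flags == {"c1_expansion": False, "c2_ratio": False,
                         "c3_aberrant": False}

    def test_missing_feature_is_indeterminate_not_false(self):
        feats = {"cd4_cd8_ratio": 0.9, "pct_cd5dim_cd8cd57": 40.0,
                 "pct_klrg1_cd8cd57": float("nan"),
                 "pct_cd94_cd8cd57": float("nan"),
                 "pct_cd56_cd8cd57": float("nan")}
        flags = evaluate_criteria(feats, _thresholds())
        assert flags["c1_expansion"] is None
        assert flags["c3_aberrant"] is None  # CD5 dim yes, receptors unknown

    def test_cd5dim_required_for_aberrancy(self):
        feats = {"pct_cd8cd57_of_lymph": 9.0, "cd4_cd8_ratio": 0.9,
                 "pct_cd5dim_cd8cd57": 2.0, "pct_klrg1_cd8cd57": 90.0,
                 "pct_cd94_cd8cd57": 90.0, "pct_cd56_cd8cd57": 90.0}
        assert evaluate_criteria(feats, _thresholds())["c3_aberrant"] is False


class TestPersistence:
    def test_qualifying_pair_599_days_apart(self):
        flags = [(date(2018, 1, 1), True, True),
                 (date(2019, 8, 23), True, True)]  # 599 days
        assert assess_persistence(flags) is True

    def test_single_visit_indeterminate(self):
        assert assess_persistence([(date(2018, 1, 1), True, True)]) is None

    def test_pair_inside_window_indeterminate(self):
        flags = [(date(2018, 1, 1), True, True),
                 (date(2018, 4, 1), True, True)]  # 90 days
        assert assess_persistence(flags) is None

    def test_nonqualifying_visits_ignored(self):
        flags = [(date(2018, 1, 1), True, True),
                 (date(2019, 1, 1), False, True),
                 (date(2020, 1, 1), True, True)]
        assert assess_persistence(flags) is True

    def test_unordered_dates_rejected(self):
        flags = [(date(2019, 1, 1), True, True), (date(2018, 1, 1), True, True)]
        with pytest.raises(ValueError, match="increasing"):
            assess_persistence(flags)


def _feature_row(donor="P1", visit="2018-01-01", pct=9.0, ratio=0.8,
                 dim=40.0, klrg1=80.0):
    return {"donor_id": donor, "visit_date": visit,
            "pct_cd8cd57_of_lymph": pct, "cd4_cd8_ratio": ratio,
            "pct_cd5dim_cd8cd57": dim, "pct_klrg1_cd8cd57": klrg1,
            "pct_cd94_cd8cd57": 1.0, "pct_cd56_cd8cd57": 1.0}


class TestClassifyCohort:
    def test_three_of_three_with_indeterminate_c4_is_high(self):
        df = pd.DataFrame([_feature_row()])
        out = classify_cohort(df, _thresholds())
        assert out.loc[0, "label"] == "HIGH"
        assert out.loc[0, "c4_persistent"] is None
        assert out.loc[0, "n_met"] == 3

    def test_two_criteria_is_low(self):
        df = pd.DataFrame([_feature_row(ratio=2.5)])
        out = classify_cohort(df, _thresholds())
        assert out.loc[0, "label"] == "LOW"
        assert out.loc[0, "n_met"] == 2

    def test_persistence_completes_three_without_ratio(self):
        df = pd.DataFrame([
            _feature_row(visit="2018-01-01", ratio=2.5),
            _feature_row(visit="2019-08-23", ratio=2.5)])
        out = classify_cohort(df, _thresholds())
        assert bool(out.loc[0, "c4_persistent"])
        assert out.loc[0, "label"] == "HIGH"

    def test_row_order_invariance(self):
        rows = [_feature_row(donor=f"P{i}", pct=float(p))
                for i, p in enumerate([1, 5, 9, 2])]
        a = classify_cohort(pd.DataFrame(rows), _thresholds())
        b = classify_cohort(pd.DataFrame(rows[::-1]), _thresholds())
        merged = a.merge(b, on="donor_id", suffixes=("_a", "_b"))
        assert (merged["label_a"] == merged["label_b"]).all()

    @given(pct=st.floats(0.1, 50), ratio=st.floats(0.1, 5),
           dim=st.floats(0, 99), klrg1=st.floats(0, 99),
           bump=st.floats(0.01, 50))
    def test_monotonicity_raising_feature_never_demotes(self, pct, ratio,
                                                        dim, klrg1, bump):
        """Raising any feature that enters a '>' criterion can flip LOW
        to HIGH but never HIGH to LOW."""
        ts = _thresholds()
        base = pd.DataFrame([_feature_row(pct=pct, ratio=ratio, dim=dim,
                                          klrg1=klrg1)])
        label0 = classify_cohort(base, ts).loc[0, "label"]
        for col in ("pct_cd8cd57_of_lymph", "pct_cd5dim_cd8cd57",
                    "pct_klrg1_cd8cd57"):
            up = base.copy()
            up[col] = up[col] + bump
            label1 = classify_cohort(up, ts).loc[0, "label"]
            assert not (label0 == "HIGH" and label1 == "LOW")

    def test_planted_labels_recovered(self, small_cohort, small_features):
        """On synthetic data the classifier recovers >= 90% of planted
        HIGH/LOW labels."""
        first = small_features[small_features["visit"] == 0]
        hc = first[first["group"] == "HC"]
        ts = derive_thresholds(hc)
        patients = small_features[small_features["group"] != "HC"]
        out = classify_cohort(patients, ts)
        truth = {d.donor_id: d.group_true for d in small_cohort.donors}
        acc = (out["label"] == out["donor_id"].map(truth)).mean()
        assert acc >= 0.90
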