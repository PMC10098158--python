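"""Gating, cutpoints, absolute counts and feature extraction."""

import math

import numpy as np
import pandas as pd
import pytest

from lglpheno.config import SURFACE_CHANNELS, FluorModel
from lglpheno.cyto_gating import (EventTable, GateSpec, absolute_count,
                                  apply_gates, compute_features, default_gates,
                                  fit_cutpoint)


class TestFitCutpoint:
    def test_valley_between_two_modes(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(1, 0.2, 1500), rng.normal(3, 0.2, 1500)])
        cut = fit_cutpoint(x, "valley")
        assert 1.6 < cut < 2.4

    def test_fixed_returns_configured_value(self):
        assert fit_cutpoint([1, 2, 3], "fixed", {"value": 2.0}) == 2.0

    def test_quantile_on_constant_vector(self):
        assert fit_cutpoint(np.full(50, 7.0), "quantile", {"q": 0.5}) == 7.0

    def test_unimodal_falls_back_with_warning(self):
        rng = np.random.default_rng(2)
        x = rng.normal(5, 1, 1000)
        with pytest.warns(UserWarning, match="unimodal"):
            cut = fit_cutpoint(x, "valley", {"default": 9.0})
        assert cut == 9.0

    def test_valley_needs_enough_events(self):
        with pytest.raises(ValueError, match="100"):
            fit_cutpoint(np.arange(10), "valley")


def _one_event_table(overrides=None) -> EventTable:
    fl = FluorModel()
    row = {"FSC-A": 100_000.0, "SSC-A": 30_000.0}
    for ch in SURFACE_CHANNELS[2:]:
        row[ch] = fl.channels[ch].state_median(2 if ch == "CD5" else 1)
    row.update(overrides or {})
    return EventTable("one", "surface", pd.DataFrame([row]))


class TestApplyGates:
    def test_event_above_all_cutpoints_in_full_chain(self):
        """A bright CD3+TCRab+CD8+CD57+ event is a member of every gate
        along its chain."""
        ev = _one_event_table({"CD4": 1.0})
        m = apply_gates(ev, default_gates("surface"))
        for gate in ("lymph", "t", "ab", "cd8", "cd8_cd57", "cd8_cd57_klrg1"):
            assert m[gate].iloc[0], gate
        assert not m["cd4"].iloc[0]
        assert not m["gd"].iloc[0]

    def test_empty_table_all_counts_zero(self):
        ev = EventTable("empty", "surface",
                        pd.DataFrame(columns=list(SURFACE_CHANNELS), dtype=float))
        m = apply_gates(ev, default_gates("surface"))
        assert (m.sum() == 0).all()

    def test_missing_channel_named_in_error(self):
        ev = _one_event_table()
        with pytest.raises(KeyError, match="NOPE"):
            apply_gates(ev, [GateSpec("g", "NOPE", "above", 1.0)])

    def test_cyclic_parents_rejected(self):
        ev = _one_event_table()
        gates = [GateSpec("a", "CD3", "above", 1.0, parent="b"),
                 GateSpec("b", "CD3", "above", 1.0, parent="a")]
        with pytest.raises(ValueError, match="cyclic"):
            apply_gates(ev, gates)

    def test_child_never_exceeds_parent(self, small_cohort):
        ev = small_cohort.events("HIGH001", 0, "surface")
        gates = default_gates("surface")
        m = apply_gates(ev, gates)
        by_name = {g.name: g for g in gates}
        for g in gates:
            if g.parent is not None:
                assert (m[g.name] <= m[g.parent]).all(), g.name
        assert by_name["cd8_cd57"].parent == "cd8"

    def test_gate_membership_matches_ground_truth(self, small_cohort):
        """With 10-fold mixture separation, threshold gating agrees with
        the hidden event labels for >= 99% of lymphocyte events."""
        ev = small_cohort.events("HIGH000", 0, "surface")
        m = apply_gates(ev, default_gates("surface"))
        truth = ev.truth
        lymph = (truth["celltype"] == "lymphocyte").to_numpy()
        called = (m["cd8_cd57"]).to_numpy()
        wanted = (truth["cd8"] & truth["cd57"]).to_numpy()
        agree = (called == wanted)[lymph].mean()
        assert agree >= 0.99


class TestAbsoluteCount:
    def test_hand_arithmetic(self):
        assert absolute_count(5000, 2500, 50.0) == pytest.approx(1.0e8)

    def test_zero_gated_events(self):
        assert absolute_count(0, 1000, 50.0) == 0.0

    def test_doubling_beads_halves_count(self):
        one = absolute_count(4000, 1000, 50.0)
        two = absolute_count(4000, 2000, 50.0)
        assert two == pytest.approx(one / 2)

    def test_zero_beads_rejected(self):
        with pytest.raises(ValueError, match="bead"):
            absolute_count(100, 0, 50.0)


class TestComputeFeatures:
    def test_all_cd4_sample_flags_ratio_missing(self):
        """No CD8+ events: the CD4:CD8 ratio is flagged missing, not 0."""
        fl = FluorModel()
        rng = np.random.default_rng(3)
        n = 500
        data = pd.DataFrame({
            "FSC-A": rng.normal(100_000, 5_000, n),
            "SSC-A": rng.normal(30_000, 5_000, n),
            "CD3": np.full(n, fl.channels["CD3"].state_median(1)),
            "CD4": np.full(n, fl.channels["CD4"].state_median(1)),
            "CD5": np.full(n, fl.channels["CD5"].state_median(2)),
            "CD8": np.full(n, fl.channels["CD8"].state_median(0)),
            "CD56": np.full(n, fl.channels["CD56"].state_median(0)),
            "CD57": np.full(n, fl.channels["CD57"].state_median(0)),
            "CD94": np.full(n, fl.channels["CD94"].state_median(0)),
            "TCRab": np.full(n, fl.channels["TCRab"].state_median(1)),
            "KLRG1": np.full(n, fl.channels["KLRG1"].state_median(0)),
        })
        ev = EventTable("cd4only", "surface", data,
                        is_bead=np.arange(n) < 10)  # a few beads for counts
        feats = compute_features(ev)
        assert math.isnan(feats["cd4_cd8_ratio"])
        assert math.isnan(feats["pct_cd5dim_cd8cd57"])  # empty subset flagged
        assert feats["pct_cd4_of_ab"] == pytest.approx(100.0)

    def test_lineage_fractions_sum_to_100(self, small_cohort):
        from lglpheno.cyto_gating import extract_cohort_features
        f = extract_cohort_features(small_cohort, panels=("surface",),
                                    visits="first")
        total = (f["pct_cd4_of_ab"] + f["pct_cd8_of_ab"]
                 + f["pct_dn_of_ab"] + f["pct_dp_of_ab"])
        np.testing.assert_allclose(total, 100.0, atol=1e-9)

    def test_planted_fraction_recovery_within_3se(self, small_cohort,
                                                  small_features):
        """Measured %CD8+CD57+ of lymphocytes recovers the planted donor
        fraction within 3 binomial SE for >= 95% of donor-visits."""
        first = small_features
        n_lymph = (small_cohort.config.events_per_sample
                   * small_cohort.config.lymph_frac_of_events)
        ok = 0
        for _, row in first.iterrows():
            p = small_cohort.donor(row["donor_id"]).planted["pct_cd8cd57_of_lymph"]
            se_pct = 100 * math.sqrt(p * (1 - p) / n_lymph)
            ok += abs(row["pct_cd8cd57_of_lymph"] - 100 * p) < 3 * se_pct
        assert ok / len(first) >= 0.95

    def test_gd_surrogate_tracks_true_gd_labels(self, small_cohort,
                                                small_features):
        """The CD3+TCRab- surrogate frequency correlates > 0.99 with the
        ground-truth gammadelta labels across donors."""
        surrogate, true = [], []
        for _, row in small_features.iterrows():
            ev = small_cohort.events(row["donor_id"], int(row["visit"]), "surface")
            t = ev.truth
            true.append(100 * t["is_gd_true"].sum() / max(1, t["is_t"].sum()))
            surrogate.append(row["pct_gd_of_t"])
        r = np.corrcoef(surrogate, true)[0, 1]
        assert r > 0.99

    def test_ki67_and_intracellular_features_present(self, small_features):
        patients = small_features[small_features["group"] != "HC"]
        for col in ("pct_ki67_cd57pos_klrg1pos", "pct_ifng_cd8",
                    "pct_perforin_cd4_ra_pos", "pct_dual_cd8"):
            assert patients[col].notna().mean() > 0.9, col
        pcts = [c for c in small_features.columns if c.startswith("pct_")]
        stacked = small_features[pcts].to_numpy(dtype=float)
        finite = stacked[np.isfinite(stacked)]
        assert ((finite >= 0) & (finite <= 100)).all()
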