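"""Anchor classification, ROC construction, cutoff selection, reconciliation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from facit_mcid.mcid_estimation import (
    AnchorSpec,
    McidPair,
    McidResult,
    classify_by_anchor,
    classify_patients_by_mcid,
    compute_change_scores,
    estimate_mcid,
    oriented_delta,
    reconcile_anchors,
    roc_curve,
    select_cutoff,
)

VAS = AnchorSpec("vas_fatigue", higher_is_better=False,
                 mcid_worsen=-10, mcid_improve=10, primary=True)
MCS = AnchorSpec("sf36_mcs", higher_is_better=True,
                 mcid_worsen=-5, mcid_improve=5)


def brute_force_auc(deltas, positive, direction):
    """Exhaustive concordant-pair counting (ties half credit)."""
    score = -np.asarray(deltas, float) if direction == "worsened" \
        else np.asarray(deltas, float)
    pos = score[np.asarray(positive, bool)]
    neg = score[~np.asarray(positive, bool)]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestOrientation:
    def test_higher_better_and_lower_better_agree_after_orientation(self):
        up = oriented_delta([30.0], [40.0], higher_is_better=True)
        down = oriented_delta([40.0], [30.0], higher_is_better=False)
        assert up[0] == down[0] == 10.0

    def test_change_scores_orient_every_anchor(self, default_cohort):
        scores = compute_change_scores(default_cohort, (VAS, MCS))
        vas_raw = (default_cohort["vas_fatigue_fu"]
                   - default_cohort["vas_fatigue_base"])
        assert np.allclose(scores["delta_vas_fatigue"], -vas_raw)


class TestAnchorClassification:
    @pytest.mark.parametrize("delta,label", [
        (-15.0, "worsened"),
        (0.0, "unchanged"),
        (10.0, "improved"),   # threshold inclusive
        (-10.0, "worsened"),  # threshold inclusive
        (9.9, "unchanged"),
        (np.nan, "excluded"),
    ])
    def test_threshold_rule(self, delta, label):
        assert classify_by_anchor(delta, VAS) == label


class TestRocCurve:
    def test_perfect_separation_has_unit_auc(self):
        curve = roc_curve([3, 4, 1, 2], [True, True, False, False], "improved")
        assert curve.auc == 1.0

    def test_identical_distributions_give_half_auc(self):
        curve = roc_curve([1, 2, 1, 2], [True, True, False, False], "improved")
        assert curve.auc == 0.5

    def test_tie_half_credit_matches_pair_counting(self):
        curve = roc_curve([2, 3, 1, 2], [True, True, False, False], "improved")
        assert curve.auc == pytest.approx(3.5 / 4)

    def test_degenerate_labels_raise_with_direction_named(self):
        with pytest.raises(ValueError, match="improved"):
            roc_curve([1, 2, 3], [True, True, True], "improved")

    @settings(max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_auc_equals_bruteforce_on_random_instances(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(5, 60))
        deltas = r.integers(-10, 11, n).astype(float)
        labels = r.random(n) < 0.4
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        direction = "worsened" if r.random() < 0.5 else "improved"
        curve = roc_curve(deltas, labels, direction)
        assert curve.auc == pytest.approx(
            brute_force_auc(deltas, labels, direction), abs=1e-12)

    @settings(max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_label_swap_flips_auc(self, seed):
        r = np.random.default_rng(seed)
        deltas = r.integers(-8, 9, 40).astype(float)
        labels = r.random(40) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        a = roc_curve(deltas, labels, "improved").auc
        b = roc_curve(deltas, ~labels, "improved").auc
        assert a + b == pytest.approx(1.0)

    @settings(max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_sensitivity_falls_and_specificity_rises_with_cutoff_magnitude(self, seed):
        r = np.random.default_rng(seed)
        deltas = r.integers(-10, 11, 60).astype(float)
        labels = r.random(60) < 0.3
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        for direction in ("worsened", "improved"):
            curve = roc_curve(deltas, labels, direction)
            order = np.argsort(np.abs(curve.cutoffs), kind="stable")
            sens = curve.sensitivity[order]
            spec = curve.specificity[order]
            assert np.all(np.diff(sens) <= 1e-12)
            assert np.all(np.diff(spec) >= -1e-12)


class TestSelectCutoff:
    def _curve(self, cutoffs, sens, spec, direction="improved"):
        from facit_mcid.mcid_estimation import RocCurve
        return RocCurve(np.asarray(cutoffs, float), np.asarray(sens),
                        np.asarray(spec), 0.7, direction, 10, 10)

    def test_single_candidate_passes_through(self):
        res = select_cutoff(self._curve([3], [0.5], [0.9]), anchor_name="a")
        assert res.cutoff == 3

    def test_argmax_of_youden_index(self):
        res = select_cutoff(self._curve([2, 4], [0.8, 0.7], [0.5, 0.8]))
        assert res.cutoff == 4            # J: 0.3 vs 0.5

    def test_ties_resolve_toward_smaller_magnitude(self):
        res = select_cutoff(self._curve([2, 5], [0.7, 0.6], [0.6, 0.7]))
        assert res.cutoff == 2

    def test_zero_selected_only_when_alone(self):
        res = select_cutoff(self._curve([0, 3], [0.9, 0.5], [0.5, 0.9]))
        assert res.cutoff == 3            # J(0)=0.4 matched but 0 excluded
        lone = select_cutoff(self._curve([0], [0.9], [0.5]))
        assert lone.cutoff == 0


class TestReconciliation:
    def _res(self, direction, anchor, cutoff):
        return McidResult(direction, anchor, cutoff, 0.5, 0.8, 0.7)

    def test_agreement_passes_the_common_value(self):
        pair = reconcile_anchors({
            "worsened": [self._res("worsened", "vas_fatigue", -3),
                         self._res("worsened", "sf36_mcs", -3)],
            "improved": [self._res("improved", "vas_fatigue", 4),
                         self._res("improved", "sf36_mcs", 4)],
        })
        assert (pair.mcid_worsen, pair.mcid_improve) == (-3, 4)

    def test_primary_anchor_wins_on_disagreement(self):
        pair = reconcile_anchors({
            "worsened": [self._res("worsened", "vas_fatigue", -3),
                         self._res("worsened", "sf36_mcs", -3)],
            "improved": [self._res("improved", "vas_fatigue", 4),
                         self._res("improved", "sf36_mcs", 2)],
        })
        assert pair.mcid_improve == 4

    def test_single_anchor_passes_through(self):
        pair = reconcile_anchors({
            "worsened": [self._res("worsened", "vas_fatigue", -2)],
            "improved": [self._res("improved", "vas_fatigue", 5)],
        })
        assert (pair.mcid_worsen, pair.mcid_improve) == (-2, 5)

    def test_alternative_policies(self):
        results = {
            "worsened": [self._res("worsened", "vas_fatigue", -3),
                         self._res("worsened", "sf36_mcs", -5)],
            "improved": [self._res("improved", "vas_fatigue", 4),
                         self._res("improved", "sf36_mcs", 2)],
        }
        assert reconcile_anchors(results, policy="max").mcid_improve == 4
        assert reconcile_anchors(results, policy="min").mcid_worsen == -3
        assert reconcile_anchors(results, policy="mean").mcid_improve == 3

    def test_missing_direction_errors(self):
        with pytest.raises(ValueError, match="improved"):
            reconcile_anchors({"worsened": [self._res("worsened", "a", -3)]})


class TestClassification:
    @pytest.mark.parametrize("delta,label", [
        (-3, "worsened"), (4, "improved"), (3, "unchanged"),
        (-2, "unchanged"), (np.nan, "excluded"),
    ])
    def test_final_pair_thresholds_inclusive(self, delta, label):
        scores = pd.DataFrame({"patient_id": ["p"], "delta_target": [delta]})
        labels, counts = classify_patients_by_mcid(scores, McidPair(-3, 4))
        assert labels["label"].iloc[0] == label
        assert sum(counts.values()) == 1

    @settings(max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_labels_partition_all_patients(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(1, 80))
        deltas = r.integers(-15, 16, n).astype(float)
        deltas[r.random(n) < 0.1] = np.nan
        scores = pd.DataFrame({"patient_id": [f"p{i}" for i in range(n)],
                               "delta_target": deltas})
        pair = McidPair(-float(r.integers(1, 6)), float(r.integers(1, 6)))
        labels, counts = classify_patients_by_mcid(scores, pair)
        assert sum(counts.values()) == n
        assert len(labels) == n


def test_full_estimate_produces_consistent_analysis(default_cohort):
    analysis = estimate_mcid(default_cohort)
    assert analysis.pair.mcid_worsen < 0 < analysis.pair.mcid_improve
    assert sum(analysis.counts.values()) == len(default_cohort)
    frame = analysis.results_frame()
    assert set(frame["direction"]) == {"worsened", "improved"}
    assert set(frame["anchor"]) == {"vas_fatigue", "sf36_mcs"}
    assert frame["auc"].between(0, 1).all()
    roc = analysis.roc_frame()
    assert {"direction", "anchor", "cutoff", "sensitivity", "specificity"} \
        <= set(roc.columns)
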