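"""Follow-up trajectory trees, relapse detection and sustainment."""

import pytest

from ttoutcomes import (
    ChangeClass,
    RelapseStatus,
    StructuralError,
    VsEndCategory,
    VsStartCategory,
    analyze_patient,
    classify_vs_end,
    classify_vs_start,
    detect_followup_recovery,
    detect_relapse,
    findings_frame,
    timepoint_outcomes,
    treatment_outcome,
)


RECOVERY = dict(pre=(16, 12), post=(6, 5))       # reliable recovery in treatment
IMPROVE_ONLY = dict(pre=(20, 12), post=(12, 5))  # improved, still a PHQ-9 case
NO_CHANGE = dict(pre=(16, 12), post=(14, 11))


class TestTimepointOutcomes:
    def test_no_followup_gives_empty_list(self, registry, policy, make_series):
        assert timepoint_outcomes(make_series(), "pre", registry, policy) == []

    def test_months_returned_in_order(self, registry, policy, make_series):
        s = make_series(followup={3: (6, 5), 1: (7, 6)})
        months = [m for m, _ in timepoint_outcomes(s, "pre", registry, policy)]
        assert months == [1, 3]

    def test_month_with_partial_pair_is_omitted(self, registry, policy, make_series):
        s = make_series(followup={1: (6, 5)})
        s.scores[2] = {"PHQ-9": 6}  # anxiety missing
        months = [m for m, _ in timepoint_outcomes(s, "pre", registry, policy)]
        assert months == [1]

    def test_absent_anchor_is_structural_error(self, registry, policy, make_series):
        s = make_series(post=None, followup={1: (6, 5)})
        with pytest.raises(StructuralError):
            timepoint_outcomes(s, "post", registry, policy)


class TestVsStart:
    def _treated(self, make_series, registry, policy, base, followup):
        s = make_series(**base, followup=followup)
        return s, treatment_outcome(s, registry, policy)

    def test_stayed_reliably_improved(self, registry, policy, make_series):
        s, t = self._treated(make_series, registry, policy, RECOVERY, {m: (6, 5) for m in (1, 2, 3)})
        assert classify_vs_start(s, t, registry, policy, group="improved") \
            is VsStartCategory.STAYED_RELIABLY_IMPROVED

    def test_lost_improvement_at_least_once(self, registry, policy, make_series):
        s, t = self._treated(
            make_series, registry, policy, RECOVERY, {1: (6, 5), 2: (13, 10), 3: (6, 5)}
        )
        assert classify_vs_start(s, t, registry, policy, group="improved") \
            is VsStartCategory.LOST_IMPROVEMENT_AT_LEAST_ONCE

    def test_deterioration_takes_precedence(self, registry, policy, make_series):
        s, t = self._treated(
            make_series, registry, policy, RECOVERY, {1: (6, 5), 2: (14, 11), 3: (24, 18)}
        )
        assert classify_vs_start(s, t, registry, policy, group="improved") \
            is VsStartCategory.DETERIORATED_AT_LEAST_ONCE

    def test_insufficient_data(self, registry, policy, make_series):
        s, t = self._treated(make_series, registry, policy, RECOVERY, None)
        assert classify_vs_start(s, t, registry, policy) is VsStartCategory.INSUFFICIENT_DATA

    def test_recovered_tree_distinguishes_recovered_from_improved(
        self, registry, policy, make_series
    ):
        s, t = self._treated(make_series, registry, policy, RECOVERY, {1: (6, 5), 2: (6, 5)})
        assert classify_vs_start(s, t, registry, policy, group="recovered") \
            is VsStartCategory.REMAINED_RELIABLY_RECOVERED
        # month 2 improved from pre but PHQ-9 back above caseness
        s2, t2 = self._treated(make_series, registry, policy, RECOVERY, {1: (6, 5), 2: (10, 5)})
        assert classify_vs_start(s2, t2, registry, policy, group="recovered") \
            is VsStartCategory.REMAINED_RECOVERED_OR_IMPROVED

    def test_recovered_tree_guard(self, registry, policy, make_series):
        s, t = self._treated(make_series, registry, policy, NO_CHANGE, {1: (6, 5)})
        with pytest.raises(StructuralError):
            classify_vs_start(s, t, registry, policy, group="recovered")

    def test_not_improved_sustained_gain(self, registry, policy, make_series):
        s, t = self._treated(
            make_series, registry, policy, NO_CHANGE, {1: (15, 11), 2: (6, 5), 3: (7, 5)}
        )
        assert classify_vs_start(s, t, registry, policy, group="not_improved") \
            is VsStartCategory.SUSTAINED_GAIN

    def test_not_improved_transient_gain(self, registry, policy, make_series):
        s, t = self._treated(
            make_series, registry, policy, NO_CHANGE, {1: (6, 5), 2: (15, 11)}
        )
        assert classify_vs_start(s, t, registry, policy, group="not_improved") \
            is VsStartCategory.TRANSIENT_GAIN

    def test_not_improved_no_changes_and_deterioration(self, registry, policy, make_series):
        s, t = self._treated(make_series, registry, policy, NO_CHANGE, {1: (15, 11), 2: (14, 12)})
        assert classify_vs_start(s, t, registry, policy, group="not_improved") \
            is VsStartCategory.NO_RELIABLE_CHANGES
        s2, t2 = self._treated(make_series, registry, policy, NO_CHANGE, {1: (24, 18)})
        assert classify_vs_start(s2, t2, registry, policy, group="not_improved") \
            is VsStartCategory.DETERIORATED_AT_ANY_POINT


class TestVsEnd:
    def test_all_months_equal_to_post_is_always_stable(self, registry, policy, make_series):
        s = make_series(**RECOVERY, followup={m: (6, 5) for m in range(1, 7)})
        assert classify_vs_end(s, registry, policy) is VsEndCategory.ALWAYS_STABLE

    def test_single_improving_month_is_always_improved(self, registry, policy, make_series):
        s = make_series(pre=(20, 12), post=(14, 10), followup={2: (7, 5)})
        assert classify_vs_end(s, registry, policy) is VsEndCategory.ALWAYS_IMPROVED

    def test_improvement_and_deterioration_fluctuates(self, registry, policy, make_series):
        s = make_series(pre=(20, 12), post=(14, 10), followup={1: (7, 5), 2: (21, 15)})
        assert classify_vs_end(s, registry, policy) is VsEndCategory.FLUCTUATING

    def test_improved_or_stable_and_stable_or_deteriorated(self, registry, policy, make_series):
        s = make_series(pre=(20, 12), post=(14, 10), followup={1: (7, 5), 2: (14, 10)})
        assert classify_vs_end(s, registry, policy) is VsEndCategory.IMPROVED_OR_STABLE
        s2 = make_series(pre=(20, 12), post=(10, 8), followup={1: (10, 8), 2: (17, 13)})
        assert classify_vs_end(s2, registry, policy) is VsEndCategory.STABLE_OR_DETERIORATED

    def test_no_followup_is_insufficient_data(self, registry, policy, make_series):
        assert classify_vs_end(make_series(), registry, policy) is VsEndCategory.INSUFFICIENT_DATA


class TestRelapse:
    def test_not_applicable_for_non_recovered(self, registry, policy, make_series):
        s = make_series(**NO_CHANGE, followup={1: (20, 15)})
        t = treatment_outcome(s, registry, policy)
        assert detect_relapse(s, t, registry, policy) == (RelapseStatus.NOT_APPLICABLE, [])

    def test_no_relapse_when_followup_equals_post(self, registry, policy, make_series):
        s = make_series(**RECOVERY, followup={m: (6, 5) for m in range(1, 7)})
        t = treatment_outcome(s, registry, policy)
        assert detect_relapse(s, t, registry, policy) == (RelapseStatus.NO_RELAPSE, [])

    def test_transient_relapse_not_sustained(self, registry, policy, make_series):
        s = make_series(**RECOVERY, followup={1: (7, 6), 2: (16, 12), 3: (8, 6)})
        t = treatment_outcome(s, registry, policy)
        status, months = detect_relapse(s, t, registry, policy)
        assert months == [2]
        assert status is RelapseStatus.RELAPSE_NOT_SUSTAINED

    def test_relapse_at_last_available_month_is_sustained(self, registry, policy, make_series):
        s = make_series(**RECOVERY, followup={1: (7, 6), 3: (16, 12)})
        t = treatment_outcome(s, registry, policy)
        status, months = detect_relapse(s, t, registry, policy)
        assert months == [3]
        assert status is RelapseStatus.RELAPSE_SUSTAINED

    def test_latest_month_arbitrates_sustainment(self, registry, policy, make_series):
        # relapse at 2, recovered-looking at 3, relapsed again at 4 (latest)
        s = make_series(**RECOVERY, followup={2: (16, 12), 3: (7, 5), 4: (17, 12)})
        t = treatment_outcome(s, registry, policy)
        status, months = detect_relapse(s, t, registry, policy)
        assert months == [2, 4]
        assert status is RelapseStatus.RELAPSE_SUSTAINED
        # the alternative rule treats any later non-relapse month as contradiction
        status_any, _ = detect_relapse(s, t, registry, policy, sustained_rule="any_later")
        assert status_any is RelapseStatus.RELAPSE_NOT_SUSTAINED

    def test_relapse_status_implies_a_relapse_month(self, registry, policy, make_series):
        s = make_series(**RECOVERY, followup={1: (16, 12)})
        t = treatment_outcome(s, registry, policy)
        status, months = detect_relapse(s, t, registry, policy)
        assert status in (RelapseStatus.RELAPSE_SUSTAINED, RelapseStatus.RELAPSE_NOT_SUSTAINED)
        assert months


class TestFollowupRecovery:
    def test_first_qualifying_month_returned(self, registry, policy, make_series):
        s = make_series(**IMPROVE_ONLY, followup={1: (12, 6), 2: (7, 5), 3: (6, 5)})
        t = treatment_outcome(s, registry, policy)
        assert not t.recovery and t.change is ChangeClass.RELIABLE_IMPROVEMENT
        assert detect_followup_recovery(s, t, registry, policy) == 2

    def test_absent_when_no_month_qualifies(self, registry, policy, make_series):
        s = make_series(**IMPROVE_ONLY, followup={1: (12, 6)})
        t = treatment_outcome(s, registry, policy)
        assert detect_followup_recovery(s, t, registry, policy) is None

    def test_guard_for_wrong_stratum(self, registry, policy, make_series):
        s = make_series(**RECOVERY, followup={1: (6, 5)})
        t = treatment_outcome(s, registry, policy)
        with pytest.raises(StructuralError):
            detect_followup_recovery(s, t, registry, policy)


class TestAnalyzePatient:
    def test_full_finding_for_recovered_patient(self, registry, policy, make_series):
        s = make_series(**RECOVERY, followup={1: (7, 6), 2: (16, 12), 3: (8, 6)})
        f = analyze_patient(s, registry, policy)
        assert f.treatment_recovery
        assert f.vs_start_group == "recovered"
        assert f.relapse_status is RelapseStatus.RELAPSE_NOT_SUSTAINED
        assert f.relapse_months == (2,)
        assert f.followup_recovery_month is None

    def test_missing_followup_degrades_gracefully(self, registry, policy, make_series):
        s = make_series(**RECOVERY)
        f = analyze_patient(s, registry, policy)
        assert f.vs_start_category is VsStartCategory.INSUFFICIENT_DATA
        assert f.vs_end_category is VsEndCategory.INSUFFICIENT_DATA
        assert f.relapse_status is RelapseStatus.NO_RELAPSE

    def test_findings_frame_serialises_months(self, registry, policy, make_series):
        s = make_series(**RECOVERY, followup={2: (16, 12), 4: (17, 12)})
        df = findings_frame([analyze_patient(s, registry, policy)])
        assert df.loc[0, "relapse_months"] == "2;4"

    def test_adsm_user_classified_on_adsm(self, registry, policy, make_series):
        s = make_series(pre=(16, 12), post=(6, 5), adsm_name="SPIN", followup={1: (6, 5)})
        s.scores["pre"]["SPIN"] = 40
        s.scores["post"]["SPIN"] = 10
        s.scores[1]["SPIN"] = 12
        f = analyze_patient(s, registry, policy)
        assert f.treatment_recovery
        t = treatment_outcome(s, registry, policy)
        assert t.pair_used == ("PHQ-9", "SPIN")
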