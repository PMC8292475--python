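"""Qualification logic and the transition-rule cascade."""

import datetime as dt
from dataclasses import replace

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from therapylines.datamodel import (
    AgentRecord,
    ClinicalSetting,
    Modality,
    ModalityClass,
    StopReason,
    SubCategory,
    TherapySegment,
    TreatmentIntent,
)
from therapylines.rules import (
    Action,
    EngineConfig,
    Guideline,
    LineState,
    SameClassSource,
    Track,
    assign_track,
    classify_transition,
    counted_agents,
    is_new_progression,
    qualifies_for_lot,
)

CYTO = SubCategory.CYTOTOXIC
SACT = Modality(ModalityClass.SACT, CYTO)


def make_segment(agents, *, setting=ClinicalSetting.METASTATIC,
                 intent=TreatmentIntent.PALLIATIVE, cpd=None,
                 start=dt.date(2020, 7, 1), stop=None, stop_reason=None,
                 modalities=frozenset({SACT}), preplanned=False, serial=2):
    return TherapySegment(
        serial_no=serial, clinical_setting=setting, treatment_intent=intent,
        most_recent_cpd_date=cpd, modalities=modalities, agents=tuple(agents),
        start_date=start, stop_date=stop, stop_reason=stop_reason,
        preplanned_with_previous=preplanned)


def make_line(agents, *, opened=dt.date(2020, 2, 1), stop_reason=None,
              stop=dt.date(2020, 6, 1), track=Track.PALLIATIVE):
    return LineState(
        line_number=1, track=track, opening_segment_start=opened,
        opening_intent=TreatmentIntent.PALLIATIVE,
        opening_setting=ClinicalSetting.METASTATIC,
        clot_at_open=0, plot_at_open=1, current_agents=tuple(agents),
        member_serials=[1], last_stop_reason=stop_reason, last_stop_date=stop)


A = AgentRecord("alpha-drug", "alpha", CYTO)
B = AgentRecord("beta-drug", "beta", CYTO)
B2 = AgentRecord("beta-mate", "beta", CYTO)
C = AgentRecord("gamma-drug", "gamma", CYTO)
D = AgentRecord("delta-drug", "delta", CYTO)


class TestQualification:
    def test_experimental_sact_qualifies_with_prefix(self):
        seg = make_segment(
            [AgentRecord("novel molecule", None, SubCategory.TARGETED,
                         experimental=True)],
            modalities=frozenset({Modality(ModalityClass.EXPERIMENTAL_SACT,
                                           SubCategory.TARGETED)}))
        decision = qualifies_for_lot(seg)
        assert decision.qualifies and decision.experimental

    def test_mixed_regimen_is_not_experimental(self):
        seg = make_segment([A, replace(C, experimental=True)])
        decision = qualifies_for_lot(seg)
        assert decision.qualifies and not decision.experimental

    @pytest.mark.parametrize("code", [ModalityClass.SURGERY,
                                      ModalityClass.RADIOTHERAPY,
                                      ModalityClass.OTHER])
    def test_local_modalities_never_qualify(self, code):
        seg = make_segment([], modalities=frozenset({Modality(code)}))
        decision = qualifies_for_lot(seg)
        assert not decision.qualifies
        assert "local" in decision.clause

    def test_placebo_only_does_not_qualify(self):
        seg = make_segment([AgentRecord("blinded arm", placebo=True)])
        assert not qualifies_for_lot(seg).qualifies

    def test_unblinded_placebo_flag_cleared_counts(self):
        seg = make_segment([AgentRecord("unblinded drug", "alpha", CYTO)])
        assert qualifies_for_lot(seg).qualifies

    def test_supportive_only_does_not_qualify(self):
        seg = make_segment([AgentRecord("dexamethasone", "corticosteroid", CYTO,
                                        supportive_only=True)])
        decision = qualifies_for_lot(seg)
        assert not decision.qualifies
        assert not decision.experimental

    def test_subclinical_exposure_does_not_qualify(self):
        seg = make_segment([replace(A, clinically_relevant_exposure=False)])
        assert not qualifies_for_lot(seg).qualifies

    def test_supportive_agents_are_excluded_from_counting(self):
        seg = make_segment([A, AgentRecord("antiemetic", supportive_only=True)])
        assert [a.name for a in counted_agents(seg)] == ["alpha-drug"]


class TestNewProgression:
    def test_cpd_before_line_opening_is_not_new(self):
        line = make_line([A], opened=dt.date(2017, 2, 1))
        seg = make_segment([A], cpd=dt.date(2017, 1, 7), start=dt.date(2017, 8, 9))
        assert not is_new_progression(line, seg)

    def test_cpd_after_line_opening_is_new(self):
        line = make_line([A], opened=dt.date(2017, 2, 1))
        seg = make_segment([A], cpd=dt.date(2017, 12, 17), start=dt.date(2018, 1, 8))
        assert is_new_progression(line, seg)

    def test_absent_cpd_is_not_new(self):
        assert not is_new_progression(make_line([A]), make_segment([A]))


class TestTransitionCascade:
    def test_first_segment_opens_line(self):
        decision = classify_transition(None, make_segment([A]))
        assert (decision.action, decision.guideline) == (
            Action.NEW_LINE, Guideline.FIRST_SEGMENT)

    def test_same_class_substitution_after_toxicity_continues(self):
        """Taxane-for-taxane swap after neuropathy keeps the line."""
        pac = AgentRecord("paclitaxel", "taxane", CYTO)
        doc = AgentRecord("docetaxel", "taxane", CYTO)
        line = make_line([pac], opened=dt.date(2017, 2, 1),
                         stop_reason=StopReason.TOXICITY)
        seg = make_segment([doc], cpd=dt.date(2017, 1, 7),
                           start=dt.date(2017, 8, 9))
        decision = classify_transition(line, seg)
        assert (decision.action, decision.guideline) == (
            Action.CONTINUE_LINE, Guideline.G2)

    def test_progression_dominates_substitution(self):
        line = make_line([B], stop_reason=StopReason.TOXICITY)
        seg = make_segment([B2], cpd=dt.date(2020, 5, 1))
        decision = classify_transition(line, seg)
        assert decision.guideline is Guideline.G1
        assert decision.action is Action.NEW_LINE

    def test_progression_after_continuation_opens_new_line(self):
        """A cPD later than the line opening is new even if the line has
        continued through later segments."""
        line = make_line([A], opened=dt.date(2017, 2, 1))
        line.member_serials.append(2)
        seg = make_segment([C], cpd=dt.date(2017, 12, 17),
                           start=dt.date(2018, 1, 8), serial=3)
        assert classify_transition(line, seg).guideline is Guideline.G1

    def test_agent_added_without_progression_is_new_line(self):
        decision = classify_transition(make_line([A]), make_segment([A, B]))
        assert (decision.action, decision.guideline) == (
            Action.NEW_LINE, Guideline.G3)

    def test_preplanned_addition_continues(self):
        decision = classify_transition(make_line([A]),
                                       make_segment([A, B], preplanned=True))
        assert (decision.action, decision.guideline) == (
            Action.CONTINUE_LINE, Guideline.PREPLANNED)

    def test_preplanned_does_not_override_progression(self):
        seg = make_segment([A, B], preplanned=True, cpd=dt.date(2020, 5, 1))
        assert classify_transition(make_line([A]), seg).guideline is Guideline.G1

    def test_agent_dropped_continues(self):
        decision = classify_transition(make_line([A, B]), make_segment([A]))
        assert (decision.action, decision.guideline) == (
            Action.CONTINUE_LINE, Guideline.G4)

    def test_dose_change_same_agents_continues(self):
        decision = classify_transition(make_line([A]), make_segment([A]))
        assert (decision.action, decision.guideline) == (
            Action.CONTINUE_LINE, Guideline.G5)

    def test_wholesale_switch_without_progression_warns_new_line(self):
        decision = classify_transition(make_line([A, B]), make_segment([C, D]))
        assert decision.action is Action.NEW_LINE
        assert decision.warnings

    def test_substitution_for_choice_reason_is_new_line_by_default(self):
        line = make_line([B], stop_reason=StopReason.CHOICE)
        decision = classify_transition(line, make_segment([B2]))
        assert decision.action is Action.NEW_LINE
        assert decision.warnings

    def test_g2_trigger_reasons_are_configurable(self):
        config = EngineConfig(substitution_reasons_for_g2=frozenset(
            {StopReason.TOXICITY, StopReason.OTHER}))
        line = make_line([B], stop_reason=StopReason.OTHER)
        decision = classify_transition(line, make_segment([B2]), config)
        assert decision.guideline is Guideline.G2

    def test_class_fallback_to_subcategory_warns(self):
        no_class = AgentRecord("mystery-1", None, CYTO)
        swap = AgentRecord("mystery-2", None, CYTO)
        line = make_line([no_class], stop_reason=StopReason.TOXICITY)
        decision = classify_transition(line, make_segment([swap]))
        assert decision.guideline is Guideline.G2
        assert any("subcategory" in w for w in decision.warnings)

    def test_subcategory_source_ignores_class_strings(self):
        config = EngineConfig(same_class_source=SameClassSource.SUBCATEGORY_FALLBACK)
        line = make_line([A], stop_reason=StopReason.TOXICITY)
        decision = classify_transition(line, make_segment([C]), config)
        assert decision.guideline is Guideline.G2  # both cytotoxic

    def test_gap_resumption_policy(self):
        strict = EngineConfig(treat_gap_resumption_as_continuation=False)
        line = make_line([A], stop_reason=StopReason.CHOICE)
        decision = classify_transition(line, make_segment([A]), strict)
        assert decision.action is Action.NEW_LINE
        # default: the identical regimen resuming keeps its line
        assert classify_transition(line, make_segment([A])).guideline is Guideline.G5

    def test_decision_is_deterministic(self):
        line_args = dict(stop_reason=StopReason.TOXICITY)
        seg = make_segment([B2], cpd=dt.date(2020, 1, 7))
        first = classify_transition(make_line([B], **line_args), seg)
        second = classify_transition(make_line([B], **line_args), seg)
        assert first == second


class TestAssignTrack:
    @pytest.mark.parametrize("setting,intent,expected", [
        (ClinicalSetting.EARLY, TreatmentIntent.CURATIVE, Track.CURATIVE),
        (ClinicalSetting.LOCALLY_ADVANCED, TreatmentIntent.PALLIATIVE, Track.PALLIATIVE),
        # intent takes precedence over setting (e.g. curable metastatic seminoma)
        (ClinicalSetting.METASTATIC, TreatmentIntent.CURATIVE, Track.CURATIVE),
        (ClinicalSetting.EARLY, TreatmentIntent.PALLIATIVE, Track.PALLIATIVE),
        # missing intent falls back to the setting
        (ClinicalSetting.METASTATIC, None, Track.PALLIATIVE),
        (ClinicalSetting.LOCALLY_ADVANCED, None, Track.PALLIATIVE),
        (ClinicalSetting.EARLY, None, Track.CURATIVE),
    ])
    def test_intent_precedence(self, setting, intent, expected):
        seg = make_segment([A], setting=setting, intent=intent)
        assert assign_track(seg) is expected


@settings(max_examples=200, deadline=None, derandomize=True)
@given(placebo=st.booleans(), relevant=st.booleans(), n_agents=st.integers(1, 4))
def test_all_supportive_agents_never_qualify(placebo, relevant, n_agents):
    """A segment whose every agent is flagged supportive-only never counts,
    whatever the other flags say."""
    agents = [AgentRecord(f"agent-{i}", "cls", CYTO, supportive_only=True,
                          placebo=placebo and i % 2 == 0,
                          clinically_relevant_exposure=relevant)
              for i in range(n_agents)]
    decision = qualifies_for_lot(make_segment(agents))
    assert not decision.qualifies
    assert not decision.experimental
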