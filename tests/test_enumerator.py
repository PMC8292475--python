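"""Line enumeration over whole histories, labels, and summaries."""

import datetime as dt
from dataclasses import replace

import pytest

from therapylines import (
    AgentRecord,
    ClinicalSetting,
    HistoryValidationError,
    Modality,
    ModalityClass,
    PatientHistory,
    StopReason,
    SubCategory,
    TherapySegment,
    Track,
    TreatmentIntent,
    assign_lines,
    datasets,
    format_label,
    summarize,
)
from therapylines.rules import Action, Guideline

SACT_CYTO = Modality(ModalityClass.SACT, SubCategory.CYTOTOXIC)


class TestFormatLabel:
    @pytest.mark.parametrize("n,clot,plot,expected", [
        (1, 1, 0, "1 (1 + 0)"),
        (5, 2, 3, "5 (2 + 3)"),
        (9, 2, 7, "9 (2 + 7)"),
    ])
    def test_rendering(self, n, clot, plot, expected):
        assert format_label(n, clot, plot) == expected

    def test_sum_contract_enforced(self):
        with pytest.raises(ValueError, match="contract"):
            format_label(3, 1, 1)

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            format_label(0, 0, 0)


class TestReferenceJourney:
    def test_labels_match_published_sequence(self, reference_annotated):
        assert tuple(reference_annotated.labels) == datasets.EXPECTED_LABELS

    def test_substitution_pair_shares_its_line(self, reference_annotated):
        by_serial = {a.serial_no: a for a in reference_annotated.assignments}
        assert by_serial[5].label == by_serial[6].label == "5 (2 + 3)"
        assert by_serial[6].decision.guideline is Guideline.G2

    def test_guideline_trace(self, reference_annotated):
        guidelines = [a.decision.guideline for a in reference_annotated.assignments]
        assert guidelines == [Guideline.FIRST_SEGMENT] + [Guideline.G1] * 4 + \
            [Guideline.G2] + [Guideline.G1] * 4

    def test_every_segment_assigned_or_skipped(self, reference_annotated):
        serials = {a.serial_no for a in reference_annotated.assignments}
        serials |= {sn for sn, _ in reference_annotated.skipped}
        assert serials == {seg.serial_no for seg in reference_annotated.history}
        assert len(reference_annotated.assignments) + \
            len(reference_annotated.skipped) == len(reference_annotated.history)

    def test_experimental_segment_still_counts(self, reference_annotated):
        last = reference_annotated.assignments[-1]
        assert last.qualification.experimental
        assert last.label == "9 (2 + 7)"

    def test_line_number_identity_and_monotone_steps(self, reference_annotated):
        previous = None
        for a in reference_annotated.assignments:
            assert a.line_number == a.clot + a.plot
            if previous is not None:
                assert a.line_number - previous.line_number in (0, 1)
                assert a.clot >= previous.clot and a.plot >= previous.plot
            previous = a


class TestEdgeCases:
    def test_empty_history(self):
        annotated = assign_lines(PatientHistory("empty", ()))
        assert annotated.assignments == []
        assert annotated.skipped == []
        assert annotated.warnings == []

    def test_single_curative_segment(self):
        seg = TherapySegment(
            serial_no=1, clinical_setting=ClinicalSetting.EARLY,
            treatment_intent=TreatmentIntent.CURATIVE,
            modalities=frozenset({SACT_CYTO}),
            agents=(AgentRecord("drug", "cls", SubCategory.CYTOTOXIC),),
            start_date=dt.date(2020, 1, 1))
        annotated = assign_lines(PatientHistory("p", (seg,)))
        assert annotated.labels == ["1 (1 + 0)"]
        assert annotated.assignments[0].track is Track.CURATIVE

    def test_ongoing_segment_is_assigned(self, reference_history):
        segs = list(reference_history.segments)
        segs[-1] = replace(segs[-1], stop_date=None, stop_reason=None)
        annotated = assign_lines(PatientHistory("p", tuple(segs)))
        assert annotated.labels[-1] == "9 (2 + 7)"

    def test_validation_errors_refuse_enumeration(self, reference_history):
        segs = list(reference_history.segments)
        segs[0] = replace(segs[0], stop_date=dt.date(1999, 1, 1))
        with pytest.raises(HistoryValidationError) as excinfo:
            assign_lines(PatientHistory("p", tuple(segs)))
        assert excinfo.value.report.errors

    def test_two_primaries_have_independent_counters(self):
        def seg(serial, pid, start, cpd=None):
            return TherapySegment(
                serial_no=serial, clinical_setting=ClinicalSetting.METASTATIC,
                treatment_intent=TreatmentIntent.PALLIATIVE,
                most_recent_cpd_date=cpd,
                modalities=frozenset({SACT_CYTO}),
                agents=(AgentRecord(f"drug-{serial}", "cls", SubCategory.CYTOTOXIC),),
                start_date=start, primary_id=pid)

        history = PatientHistory("p", (
            seg(1, "breast", dt.date(2020, 1, 1)),
            seg(2, "lung", dt.date(2020, 6, 1)),
            seg(3, "breast", dt.date(2021, 1, 1), cpd=dt.date(2020, 12, 1)),
        ))
        annotated = assign_lines(history)
        by_serial = {a.serial_no: a for a in annotated.assignments}
        assert by_serial[1].label == "1 (0 + 1)"
        assert by_serial[2].label == "1 (0 + 1)"   # fresh counters for the lung primary
        assert by_serial[2].decision.guideline is Guideline.FIRST_SEGMENT
        assert by_serial[3].label == "2 (0 + 2)"

    def test_curative_line_may_follow_palliative_lines(self):
        """No ordering constraint between tracks (e.g. oligometastatic
        disease rendered resectable)."""
        palliative = TherapySegment(
            serial_no=1, clinical_setting=ClinicalSetting.METASTATIC,
            treatment_intent=TreatmentIntent.PALLIATIVE,
            modalities=frozenset({SACT_CYTO}),
            agents=(AgentRecord("a", "x", SubCategory.CYTOTOXIC),),
            start_date=dt.date(2020, 1, 1), stop_date=dt.date(2020, 6, 1),
            stop_reason=StopReason.CPD)
        curative = TherapySegment(
            serial_no=2, clinical_setting=ClinicalSetting.METASTATIC,
            treatment_intent=TreatmentIntent.CURATIVE,
            most_recent_cpd_date=dt.date(2020, 6, 1),
            modalities=frozenset({SACT_CYTO}),
            agents=(AgentRecord("b", "y", SubCategory.CYTOTOXIC),),
            start_date=dt.date(2020, 7, 1))
        annotated = assign_lines(PatientHistory("p", (palliative, curative)))
        assert annotated.labels == ["1 (0 + 1)", "2 (1 + 1)"]


class TestInertness:
    def test_deleting_local_segments_leaves_labels_unchanged(self, reference_history):
        baseline = {a.serial_no: a.label
                    for a in assign_lines(reference_history).assignments}
        surgery = TherapySegment(
            serial_no=11, clinical_setting=ClinicalSetting.METASTATIC,
            treatment_intent=TreatmentIntent.PALLIATIVE,
            modalities=frozenset({Modality(ModalityClass.SURGERY)}),
            start_date=dt.date(2018, 9, 15), stop_date=dt.date(2018, 9, 15),
            stop_reason=StopReason.COMPLETED, comments="palliative debulking")
        segs = sorted(list(reference_history.segments) + [surgery],
                      key=lambda s: (s.start_date, s.serial_no))
        annotated = assign_lines(PatientHistory("p", tuple(segs)))
        assert {a.serial_no: a.label for a in annotated.assignments} == baseline
        assert [sn for sn, _ in annotated.skipped] == [11]

    def test_comments_never_affect_output(self, reference_history):
        baseline = assign_lines(reference_history)
        segs = tuple(replace(s, comments=f"mutated #{s.serial_no}")
                     for s in reference_history.segments)
        mutated = assign_lines(PatientHistory("p", segs))
        assert mutated.labels == baseline.labels
        assert [a.decision.guideline for a in mutated.assignments] == \
            [a.decision.guideline for a in baseline.assignments]


class TestSummarize:
    def test_reference_totals(self, reference_annotated):
        summary = summarize(reference_annotated).primary("1")
        assert (summary.n_lines, summary.clot, summary.plot) == (9, 2, 7)
        assert summary.current_label == "9 (2 + 7)"

    def test_metastatic_line_count_supports_eligibility_query(self, reference_annotated):
        """Lines 4-9 open in the metastatic setting: the 'no more than k
        lines for metastatic disease' query counts six."""
        summary = summarize(reference_annotated).primary("1")
        assert summary.lines_opened_in_metastatic_setting == 6

    def test_disease_free_interval_between_first_lines(self, reference_annotated):
        summary = summarize(reference_annotated).primary("1")
        # line 1 stopped 2005 Aug 14; recurrence documented 2010 Dec 22
        assert summary.disease_free_interval_days[1] == (
            dt.date(2010, 12, 22) - dt.date(2005, 8, 14)).days

    def test_empty_history_summary_is_zero(self):
        annotated = assign_lines(PatientHistory("empty", ()))
        assert summarize(annotated).per_primary == {}
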