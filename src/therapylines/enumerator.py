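"""Fold the transition rules over a history to enumerate lines of therapy.

Every line is reported in the cumulative format ``N (CLoT + PLoT)``: CLoT
counts lines given with curative intent and/or in the early setting, PLoT
counts lines given with palliative intent and/or in the advanced setting,
and N = CLoT + PLoT is the line's serial number over the patient's whole
recorded journey (early and advanced phases alike). Counters run
independently per primary organ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .datamodel import (
    ClinicalSetting,
    PatientHistory,
    TherapySegment,
    ValidationReport,
    validate_history,
)
from .rules import (
    Action,
    EngineConfig,
    Guideline,
    LineState,
    QualificationDecision,
    Track,
    TransitionDecision,
    assign_track,
    classify_transition,
    counted_agents,
    qualifies_for_lot,
)

__all__ = [
    "AnnotatedHistory",
    "HistoryValidationError",
    "LineAssignment",
    "PrimarySummary",
    "Summary",
    "assign_lines",
    "format_label",
    "summarize",
]


class HistoryValidationError(ValueError):
    """Raised when enumeration is refused because validation found ERRORs."""

    def __init__(self, report: ValidationReport):
        self.report = report
        listing = "; ".join(str(issue) for issue in report.errors)
        super().__init__(f"history has validation errors: {listing}")


def format_label(n: int, clot: int, plot: int) -> str:
    """Render the ``N (CLoT + PLoT)`` label, e.g. ``5 (2 + 3)``.

    The identity ``N = CLoT + PLoT`` is a contract, not a convention; a
    violation raises rather than silently printing an inconsistent label.
    """
    if min(n, clot, plot) < 0 or n < 1:
        raise ValueError(f"label components must be non-negative with N >= 1; "
                         f"got N={n}, CLoT={clot}, PLoT={plot}")
    if n != clot + plot:
        raise ValueError(f"label contract violated: N={n} != CLoT+PLoT={clot + plot}")
    return f"{n} ({clot} + {plot})"


@dataclass(frozen=True)
class LineAssignment:
    """The engine's verdict for one qualifying segment."""

    serial_no: int
    primary_id: str
    line_number: int
    track: Track
    clot: int
    plot: int
    label: str
    decision: TransitionDecision
    qualification: QualificationDecision

    def __post_init__(self) -> None:
        if self.line_number != self.clot + self.plot:
            raise ValueError("line number must equal CLoT + PLoT")


@dataclass
class AnnotatedHistory:
    """A history plus one verdict per segment (assigned or skipped)."""

    history: PatientHistory
    assignments: List[LineAssignment] = field(default_factory=list)
    skipped: List[Tuple[int, QualificationDecision]] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)

    def label_for(self, serial_no: int) -> Optional[str]:
        for a in self.assignments:
            if a.serial_no == serial_no:
                return a.label
        return None

    @property
    def labels(self) -> List[str]:
        """Labels of qualifying segments, in segment order."""
        return [a.label for a in self.assignments]


@dataclass
class _PrimaryState:
    clot: int = 0
    plot: int = 0
    line: Optional[LineState] = None


def assign_lines(history: PatientHistory,
                 config: Optional[EngineConfig] = None) -> AnnotatedHistory:
    """Enumerate lines of therapy for one patient.

    Segments are processed in their recorded (chronological) order with
    separate N/CLoT/PLoT counters per ``primary_id``. Non-qualifying segments
    (surgery-only, radiotherapy-only, other local, placebo/supportive-only)
    are recorded as skipped and never influence numbering. A line's track and
    counters are fixed by its opening segment; continuing segments reuse them.

    Raises :class:`HistoryValidationError` when validation reports ERRORs.
    """
    cfg = config if config is not None else EngineConfig()
    report = validate_history(history, cfg, check_line_consistency=False)
    if not report.ok:
        raise HistoryValidationError(report)

    annotated = AnnotatedHistory(history)
    annotated.warnings.extend(str(issue) for issue in report.warnings)
    states: Dict[str, _PrimaryState] = {}

    for seg in history.segments:
        qualification = qualifies_for_lot(seg)
        if not qualification.qualifies:
            annotated.skipped.append((seg.serial_no, qualification))
            continue

        state = states.setdefault(seg.primary_id, _PrimaryState())
        decision = classify_transition(state.line, seg, cfg)
        annotated.warnings.extend(
            f"segment {seg.serial_no}: {w}" for w in decision.warnings)

        if decision.action is Action.NEW_LINE:
            track = assign_track(seg, cfg)
            if seg.treatment_intent is None:
                annotated.warnings.append(
                    f"segment {seg.serial_no}: treatment intent absent; track "
                    f"derived from clinical setting "
                    f"({seg.clinical_setting.value} -> {track.value})")
            if track is Track.CURATIVE:
                state.clot += 1
            else:
                state.plot += 1
            state.line = LineState(
                line_number=state.clot + state.plot,
                track=track,
                opening_segment_start=seg.start_date,
                opening_intent=seg.treatment_intent,
                opening_setting=seg.clinical_setting,
                clot_at_open=state.clot,
                plot_at_open=state.plot,
                current_agents=counted_agents(seg),
                member_serials=[seg.serial_no],
                last_stop_reason=seg.stop_reason,
                last_stop_date=seg.stop_date,
            )
        else:
            line = state.line
            if (seg.treatment_intent is not None
                    and line.opening_intent is not None
                    and seg.treatment_intent is not line.opening_intent):
                annotated.warnings.append(
                    f"segment {seg.serial_no}: intent differs from line opener; "
                    f"line {line.line_number} keeps its {line.track.value} "
                    f"attribution")
            line.current_agents = counted_agents(seg)
            line.member_serials.append(seg.serial_no)
            line.last_stop_reason = seg.stop_reason
            line.last_stop_date = seg.stop_date

        line = state.line
        annotated.assignments.append(LineAssignment(
            serial_no=seg.serial_no,
            primary_id=seg.primary_id,
            line_number=line.line_number,
            track=line.track,
            clot=line.clot_at_open,
            plot=line.plot_at_open,
            label=format_label(line.line_number, line.clot_at_open, line.plot_at_open),
            decision=decision,
            qualification=qualification,
        ))

    return annotated


# --------------------------------------------------------------------------
# Summaries / eligibility queries
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PrimarySummary:
    """Per-primary line counts plus the quantities eligibility queries need.

    ``lines_opened_in_metastatic_setting`` supports queries of the form
    "no more than k separate lines of treatment for metastatic disease".
    ``disease_free_interval_days`` maps a line number to the number of days
    between that line's last stop date and the cPD date that opened the next
    line, supporting disease-free-interval criteria; lines without both dates
    are omitted.
    """

    primary_id: str
    n_lines: int
    clot: int
    plot: int
    current_label: Optional[str]
    lines_opened_in_metastatic_setting: int
    disease_free_interval_days: Dict[int, int]


@dataclass(frozen=True)
class Summary:
    per_primary: Dict[str, PrimarySummary]

    def primary(self, primary_id: str) -> PrimarySummary:
        return self.per_primary[primary_id]


def summarize(annotated: AnnotatedHistory) -> Summary:
    """Aggregate an annotated history into per-primary line counts."""
    history = annotated.history
    per_primary: Dict[str, PrimarySummary] = {}

    for pid in history.primary_ids():
        assignments = [a for a in annotated.assignments if a.primary_id == pid]
        if not assignments:
            per_primary[pid] = PrimarySummary(pid, 0, 0, 0, None, 0, {})
            continue

        openers = [a for a in assignments if a.decision.action is Action.NEW_LINE]
        last = assignments[-1]
        metastatic = sum(
            1 for a in openers
            if history.segment(a.serial_no).clinical_setting is ClinicalSetting.METASTATIC)

        # disease-free interval: last stop of line k -> cPD opening line k+1
        intervals: Dict[int, int] = {}
        for opener, nxt in zip(openers, openers[1:]):
            members = [a for a in assignments if a.line_number == opener.line_number]
            stops = [history.segment(a.serial_no).stop_date for a in members]
            stops = [s for s in stops if s is not None]
            next_cpd = history.segment(nxt.serial_no).most_recent_cpd_date
            if stops and next_cpd is not None:
                intervals[opener.line_number] = (next_cpd - max(stops)).days

        per_primary[pid] = PrimarySummary(
            primary_id=pid,
            n_lines=last.line_number,
            clot=last.clot,
            plot=last.plot,
            current_label=last.label,
            lines_opened_in_metastatic_setting=metastatic,
            disease_free_interval_days=intervals,
        )

    return Summary(per_primary)
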