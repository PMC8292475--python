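"""Typed model of the standardised treatment-history dataset.

The dataset records one row per *therapy segment*: a contiguous period during
which a patient received one therapeutic approach (which may itself be a
pre-planned multimodal sequence, e.g. neoadjuvant chemotherapy → surgery →
radiotherapy → endocrine therapy). Each segment carries the coded vocabulary
of the standard:

* clinical setting  — ``2A`` early / ``2B`` locally advanced / ``2C`` metastatic
* treatment intent  — ``3A`` curative / ``3B`` palliative
* modality          — ``5A`` SACT / ``5B`` experimental SACT / ``5C`` surgery /
  ``5D`` radiotherapy / ``5E`` other local; systemic modalities are
  subcategorised ``i``–``v`` (cytotoxic, endocrine, targeted, immunotherapy,
  other)
* stop reason       — ``8A`` clinical progression (cPD) / ``8B`` completed /
  ``8C`` toxicity / ``8D`` patient or clinician choice / ``8E`` death /
  ``8F`` other

All dates are day-resolution calendar dates (no times, no zones).
Invariant breaches are reported by :func:`validate_history` as ERROR or
WARNING issues rather than raised at construction time, because real-world
records are routinely imperfect and the caller decides what is fatal.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Optional

__all__ = [
    "AgentRecord",
    "ClinicalSetting",
    "DateDialect",
    "DateParseError",
    "Issue",
    "Modality",
    "ModalityClass",
    "PatientHistory",
    "Severity",
    "StopReason",
    "SubCategory",
    "TherapySegment",
    "TreatmentIntent",
    "ValidationReport",
    "format_date",
    "parse_date",
    "validate_history",
]


# --------------------------------------------------------------------------
# Coded vocabularies
# --------------------------------------------------------------------------

class ClinicalSetting(Enum):
    """Maximum extent of cancer spread experienced to date."""

    EARLY = "2A"              # operable, no known distant metastasis
    LOCALLY_ADVANCED = "2B"   # inoperable, no known distant metastasis
    METASTATIC = "2C"         # known distant metastases


class TreatmentIntent(Enum):
    """Intent of therapy in the opinion of the treating clinician."""

    CURATIVE = "3A"
    PALLIATIVE = "3B"


class ModalityClass(Enum):
    SACT = "5A"                # systemic anti-cancer therapy
    EXPERIMENTAL_SACT = "5B"   # SACT without any approved anti-cancer agent
    SURGERY = "5C"
    RADIOTHERAPY = "5D"
    OTHER = "5E"               # other local approaches (HIFU, ablation, ...)


#: Modality classes that constitute systemic therapy and can carry agents.
SYSTEMIC_MODALITIES = frozenset({ModalityClass.SACT, ModalityClass.EXPERIMENTAL_SACT})


class SubCategory(Enum):
    """Subcategorisation of systemic therapy (applies to 5A/5B only)."""

    CYTOTOXIC = "i"
    ENDOCRINE = "ii"
    TARGETED = "iii"
    IMMUNOTHERAPY = "iv"
    OTHER = "v"


class StopReason(Enum):
    CPD = "8A"        # clinical progression of disease
    COMPLETED = "8B"  # completed planned anti-cancer therapy
    TOXICITY = "8C"
    CHOICE = "8D"     # patient/clinician choice
    DEATH = "8E"
    OTHER = "8F"      # e.g. financial


@dataclass(frozen=True)
class Modality:
    """One coded modality entry; systemic entries carry a subcategory."""

    code: ModalityClass
    subcategory: Optional[SubCategory] = None

    def __post_init__(self) -> None:
        systemic = self.code in SYSTEMIC_MODALITIES
        if systemic and self.subcategory is None:
            raise ValueError(f"modality {self.code.value} requires a subcategory i-v")
        if not systemic and self.subcategory is not None:
            raise ValueError(f"modality {self.code.value} cannot carry a subcategory")

    @property
    def is_systemic(self) -> bool:
        return self.code in SYSTEMIC_MODALITIES


# --------------------------------------------------------------------------
# Agents and segments
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AgentRecord:
    """One anti-cancer agent administered during a segment.

    ``experimental`` asserts that the agent lacked FDA/EMA approval for any
    cancer on the start date (a caller-supplied fact, never computed here).
    ``supportive_only`` marks approved drugs given purely as supportive care
    (e.g. dexamethasone as an antiemetic); such exposure never counts toward
    a line of therapy. ``clinically_relevant_exposure`` is the treating
    clinician's judgement that dose and duration could plausibly exert an
    anti-cancer effect.
    """

    name: str
    agent_class: Optional[str] = None   # free text, e.g. "taxane"
    category: Optional[SubCategory] = None
    experimental: bool = False
    supportive_only: bool = False
    placebo: bool = False
    clinically_relevant_exposure: bool = True

    @property
    def key(self) -> str:
        """Case-insensitive identity used for agent-set comparisons."""
        return self.name.strip().casefold()

    @property
    def class_key(self) -> Optional[str]:
        if self.agent_class is None or not self.agent_class.strip():
            return None
        return self.agent_class.strip().casefold()


@dataclass(frozen=True)
class TherapySegment:
    """One row of the standardised dataset.

    ``most_recent_cpd_date`` records the clinical progression that preceded
    (and typically motivated) this segment; it is absent at initial
    diagnosis. ``preplanned_with_previous`` marks the segment as a
    prospectively planned continuation of the previous segment's systemic
    therapy (switch maintenance, planned sequence), which by definition is
    part of the same discrete attempt to treat.
    """

    serial_no: int
    clinical_setting: ClinicalSetting
    start_date: dt.date
    modalities: frozenset = frozenset()
    agents: tuple = ()
    treatment_intent: Optional[TreatmentIntent] = None
    most_recent_cpd_date: Optional[dt.date] = None
    stop_date: Optional[dt.date] = None
    stop_reason: Optional[StopReason] = None
    preplanned_with_previous: bool = False
    primary_id: str = "1"
    comments: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "modalities", frozenset(self.modalities))
        object.__setattr__(self, "agents", tuple(self.agents))

    @property
    def is_systemic(self) -> bool:
        """True if any modality is systemic (5A/5B)."""
        return any(m.is_systemic for m in self.modalities)

    @property
    def ongoing(self) -> bool:
        return self.stop_date is None


@dataclass(frozen=True)
class PatientHistory:
    """Chronologically ordered therapy segments for one patient.

    A patient with primary cancers in more than one organ carries a distinct
    ``primary_id`` per organ; lines of therapy are numbered independently per
    primary.
    """

    patient_id: str
    segments: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))

    def __iter__(self) -> Iterator[TherapySegment]:
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    def primary_ids(self) -> list:
        """Primary identifiers in order of first appearance."""
        seen: list = []
        for seg in self.segments:
            if seg.primary_id not in seen:
                seen.append(seg.primary_id)
        return seen

    def segment(self, serial_no: int) -> TherapySegment:
        for seg in self.segments:
            if seg.serial_no == serial_no:
                return seg
        raise KeyError(f"no segment with serial number {serial_no}")


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------

class Severity(Enum):
    ERROR = "ERROR"      # blocks line enumeration
    WARNING = "WARNING"  # reported, does not block


@dataclass(frozen=True)
class Issue:
    severity: Severity
    serial_no: Optional[int]
    message: str

    def __str__(self) -> str:
        where = f"segment {self.serial_no}" if self.serial_no is not None else "history"
        return f"{self.severity.value} [{where}]: {self.message}"


@dataclass
class ValidationReport:
    issues: list = field(default_factory=list)

    def add(self, severity: Severity, serial_no: Optional[int], message: str) -> None:
        self.issues.append(Issue(severity, serial_no, message))

    def extend(self, other: "ValidationReport") -> None:
        self.issues.extend(other.issues)

    @property
    def errors(self) -> list:
        return [i for i in self.issues if i.severity is Severity.ERROR]

    @property
    def warnings(self) -> list:
        return [i for i in self.issues if i.severity is Severity.WARNING]

    @property
    def ok(self) -> bool:
        return not self.errors

    def __iter__(self) -> Iterator[Issue]:
        return iter(self.issues)


# --------------------------------------------------------------------------
# Dates
# --------------------------------------------------------------------------

class DateDialect(Enum):
    """Accepted date spellings.

    DATASET is the standard's native form ``YYYY MMM DD`` with English
    three-letter month abbreviations (e.g. ``2021 Jan 01``); ISO8601 is
    ``YYYY-MM-DD``. AUTO tries DATASET first, then ISO8601.
    """

    DATASET = "dataset"
    ISO8601 = "iso8601"
    AUTO = "auto"


class DateParseError(ValueError):
    pass


_MONTH_ABBR = ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
               "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]
_MONTH_NUMBER = {name.lower(): i + 1 for i, name in enumerate(_MONTH_ABBR)}


def _parse_dataset(text: str) -> dt.date:
    parts = text.split()
    if len(parts) != 3:
        raise ValueError("expected three tokens 'YYYY MMM DD'")
    year = int(parts[0])
    month = _MONTH_NUMBER.get(parts[1].lower())
    if month is None:
        raise ValueError(f"unknown month abbreviation {parts[1]!r}")
    return dt.date(year, month, int(parts[2]))


def parse_date(text: Optional[str],
               dialect: DateDialect = DateDialect.AUTO) -> Optional[dt.date]:
    """Parse a date cell; ``NA``/empty means absent and returns ``None``.

    Cells beginning with ``NA`` (e.g. ``NA (date of diagnosis: ...)``) are
    treated as absent, matching how the dataset annotates missing cPD dates.
    """
    if text is None:
        return None
    cleaned = text.strip()
    if not cleaned or cleaned.upper().startswith("NA"):
        return None

    attempts = ([DateDialect.DATASET, DateDialect.ISO8601]
                if dialect is DateDialect.AUTO else [dialect])
    for attempt in attempts:
        try:
            if attempt is DateDialect.DATASET:
                return _parse_dataset(cleaned)
            return dt.date.fromisoformat(cleaned)
        except ValueError:
            continue
    names = ", ".join(a.value for a in attempts)
    raise DateParseError(f"cannot parse date {text!r} (tried dialect(s): {names})")


def format_date(date: Optional[dt.date],
                dialect: DateDialect = DateDialect.DATASET) -> str:
    """Serialise a date in the dialect's canonical form; ``None`` -> empty."""
    if date is None:
        return ""
    if dialect is DateDialect.ISO8601:
        return date.isoformat()
    return f"{date.year:04d} {_MONTH_ABBR[date.month - 1]} {date.day:02d}"


# --------------------------------------------------------------------------
# History validation
# --------------------------------------------------------------------------

def validate_history(history: PatientHistory,
                     config=None,
                     check_line_consistency: bool = True) -> ValidationReport:
    """Check a history against the dataset's invariants.

    ERROR issues (which block enumeration): duplicate or non-positive serial
    numbers, segments out of chronological order, stop before start, a cPD
    date after the segment's start, systemic segments without agents, empty
    modality sets, stop date/reason present without the other, or cPD dates
    that go backwards within one primary.

    WARNING issues: missing treatment intent; a segment stopped for
    progression (8A) whose successor carries no later cPD date; a continuing
    segment whose intent differs from its line's opening segment (requires
    ``check_line_consistency``, which replays the transition rules).

    The function is pure: identical inputs yield identical reports.
    """
    report = ValidationReport()
    seen_serials: set = set()

    for seg in history.segments:
        sn = seg.serial_no
        if sn in seen_serials:
            report.add(Severity.ERROR, sn, "duplicate serial number")
        seen_serials.add(sn)
        if sn < 1:
            report.add(Severity.ERROR, sn, "serial number must be a positive integer")
        if not seg.modalities:
            report.add(Severity.ERROR, sn, "no anti-cancer modality recorded")
        if seg.stop_date is not None and seg.stop_date < seg.start_date:
            report.add(Severity.ERROR, sn,
                       f"stop date {seg.stop_date} precedes start date {seg.start_date}")
        if (seg.most_recent_cpd_date is not None
                and seg.most_recent_cpd_date > seg.start_date):
            report.add(Severity.ERROR, sn,
                       "most recent cPD date is after the segment start; the column "
                       "records the progression preceding this therapy")
        if seg.is_systemic and not seg.agents:
            report.add(Severity.ERROR, sn,
                       "systemic modality (5A/5B) recorded without any agents")
        if seg.stop_date is not None and seg.stop_reason is None:
            report.add(Severity.ERROR, sn, "stop date present without a stop reason")
        if seg.stop_reason is not None and seg.stop_date is None:
            report.add(Severity.ERROR, sn, "stop reason present without a stop date")
        if seg.treatment_intent is None:
            report.add(Severity.WARNING, sn,
                       "treatment intent missing; curative/palliative track will be "
                       "derived from the clinical setting")

    order_keys = [(seg.start_date, seg.serial_no) for seg in history.segments]
    if order_keys != sorted(order_keys):
        report.add(Severity.ERROR, None,
                   "segments are not sorted by (start date, serial number)")

    # per-primary temporal consistency
    for pid in history.primary_ids():
        segs = [s for s in history.segments if s.primary_id == pid]
        last_cpd: Optional[dt.date] = None
        for seg in segs:
            if seg.most_recent_cpd_date is not None:
                if last_cpd is not None and seg.most_recent_cpd_date < last_cpd:
                    report.add(Severity.ERROR, seg.serial_no,
                               "most recent cPD date is earlier than a cPD date on a "
                               "preceding segment of the same primary")
                last_cpd = seg.most_recent_cpd_date
        for current, nxt in zip(segs, segs[1:]):
            if current.stop_reason is StopReason.CPD:
                if nxt.most_recent_cpd_date is None or (
                        current.most_recent_cpd_date is not None
                        and nxt.most_recent_cpd_date <= current.most_recent_cpd_date):
                    report.add(Severity.WARNING, nxt.serial_no,
                               "previous segment stopped for progression (8A) but this "
                               "segment carries no later cPD date")

    if check_line_consistency and report.ok:
        _line_consistency_warnings(history, config, report)
    return report


def _line_consistency_warnings(history: PatientHistory, config,
                               report: ValidationReport) -> None:
    """Replay the transition rules to flag intra-line inconsistencies."""
    # local import: the rules module depends on these types
    from . import rules

    cfg = config if config is not None else rules.EngineConfig()
    lines: dict = {}
    for seg in history.segments:
        decision_q = rules.qualifies_for_lot(seg)
        if not decision_q.qualifies:
            continue
        line = lines.get(seg.primary_id)
        decision = rules.classify_transition(line, seg, cfg)
        for w in decision.warnings:
            report.add(Severity.WARNING, seg.serial_no, w)
        if decision.action is rules.Action.NEW_LINE:
            line = rules.LineState(
                line_number=1 if line is None else line.line_number + 1,
                track=rules.assign_track(seg, cfg),
                opening_segment_start=seg.start_date,
                opening_intent=seg.treatment_intent,
                opening_setting=seg.clinical_setting,
                clot_at_open=0, plot_at_open=0,
                current_agents=rules.counted_agents(seg),
                member_serials=[seg.serial_no],
                last_stop_reason=seg.stop_reason,
                last_stop_date=seg.stop_date)
            lines[seg.primary_id] = line
        else:
            if (seg.treatment_intent is not None
                    and line.opening_intent is not None
                    and seg.treatment_intent is not line.opening_intent):
                report.add(Severity.WARNING, seg.serial_no,
                           "intent differs from line opener; the line keeps the "
                           "attribution fixed at its opening segment")
            line.current_agents = rules.counted_agents(seg)
            line.member_serials.append(seg.serial_no)
            line.last_stop_reason = seg.stop_reason
            line.last_stop_date = seg.stop_date
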