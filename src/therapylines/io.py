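"""Read and write the standardised dataset as delimited text (CSV/TSV).

The on-disk layout is the standard's ten columns — serial number, clinical
setting, treatment intent, date of most recent cPD, anti-cancer modality,
start/stop dates, stop reason, comments, and the output label column
``Line of therapy N (CLoT + PLoT)`` — plus machine-readable extension
columns:

* ``Agents`` (required): semicolon-separated entries ``name|class|category|flags``
  with flags drawn from ``experimental``, ``supportive``, ``placebo``,
  ``subclinical``. Agent detail must be structured here because the Comments
  column is prose and is never parsed.
* ``Primary ID`` (optional): distinguishes primaries in multi-primary
  patients; absent means a single primary.
* ``Preplanned continuation`` (optional): ``yes`` marks a segment as a
  prospectively planned continuation of the previous segment's SACT.

Coded cells are parsed leniently ("2A Early", "2A" and "Early" all map to the
early setting; the code prefix wins), and re-serialised canonically. Reading
a written file reproduces the typed history field-for-field.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Tuple, Union

from .datamodel import (
    AgentRecord,
    ClinicalSetting,
    DateDialect,
    DateParseError,
    Modality,
    ModalityClass,
    PatientHistory,
    Severity,
    StopReason,
    SubCategory,
    TherapySegment,
    TreatmentIntent,
    ValidationReport,
    format_date,
    parse_date,
    validate_history,
)
from .enumerator import AnnotatedHistory

__all__ = [
    "CANONICAL_COLUMNS",
    "DatasetDialect",
    "DatasetFormatError",
    "read_history",
    "write_annotated",
    "write_history",
]


class DatasetFormatError(ValueError):
    """Structural problem that prevents reading the file at all."""


@dataclass(frozen=True)
class DatasetDialect:
    """File-level conventions: delimiter and date spelling (UTF-8 always)."""

    delimiter: str = ","
    date_format: DateDialect = DateDialect.DATASET

    def __post_init__(self) -> None:
        if self.delimiter not in (",", "\t"):
            raise ValueError("delimiter must be ',' (CSV) or tab (TSV)")
        if self.date_format is DateDialect.AUTO:
            raise ValueError("a file declares one date format; AUTO is for cells")


DEFAULT_DIALECT = DatasetDialect()

COL_SERIAL = "Serial No."
COL_SETTING = "Clinical setting"
COL_INTENT = "Treatment intent"
COL_CPD = "Date of most recent clinical progression of disease (cPD)"
COL_MODALITY = "Anti-cancer modality"
COL_START = "Start date"
COL_STOP = "Stop date"
COL_STOP_REASON = "Reason for stopping"
COL_COMMENTS = "Comments"
COL_LABEL = "Line of therapy N (CLoT + PLoT)"
COL_AGENTS = "Agents"
COL_PRIMARY = "Primary ID"
COL_PREPLANNED = "Preplanned continuation"

CANONICAL_COLUMNS = (COL_SERIAL, COL_SETTING, COL_INTENT, COL_CPD, COL_MODALITY,
                     COL_START, COL_STOP, COL_STOP_REASON, COL_COMMENTS, COL_LABEL,
                     COL_AGENTS, COL_PRIMARY, COL_PREPLANNED)

_REQUIRED_COLUMNS = (COL_SERIAL, COL_SETTING, COL_INTENT, COL_CPD, COL_MODALITY,
                     COL_START, COL_STOP, COL_STOP_REASON, COL_COMMENTS, COL_AGENTS)


# --------------------------------------------------------------------------
# Lenient coded-cell parsing
# --------------------------------------------------------------------------

_SETTING_TEXT = {
    "early": ClinicalSetting.EARLY,
    "locally advanced": ClinicalSetting.LOCALLY_ADVANCED,
    "metastatic": ClinicalSetting.METASTATIC,
}
_INTENT_TEXT = {
    "curative": TreatmentIntent.CURATIVE,
    "palliative": TreatmentIntent.PALLIATIVE,
}
_STOP_TEXT = {
    "cpd": StopReason.CPD,
    "progression": StopReason.CPD,
    "completed": StopReason.COMPLETED,
    "toxicity": StopReason.TOXICITY,
    "choice": StopReason.CHOICE,
    "death": StopReason.DEATH,
    "other": StopReason.OTHER,
}


def _parse_coded(cell: str, enum_cls, text_map: dict, what: str):
    """Parse a coded cell: code prefix wins, else case-insensitive text."""
    s = cell.strip()
    if not s or s.upper().startswith("NA"):
        return None
    upper = s.upper()
    for member in enum_cls:
        if upper.startswith(member.value):
            return member
    lowered = s.lower()
    for text, member in text_map.items():
        if lowered.startswith(text):
            return member
    raise ValueError(f"unrecognised {what} code {cell!r}")


_MODALITY_CODE_RE = re.compile(r"5\s*([A-Ea-e])")
_ROMAN_RE = re.compile(r"\b(iv|iii|ii|i|v)\b", re.IGNORECASE)
_MODALITY_TEXT = {
    "surgery": ModalityClass.SURGERY,
    "radiotherapy": ModalityClass.RADIOTHERAPY,
}


def _parse_modalities(cell: str) -> frozenset:
    """Parse a modality cell, possibly listing several coded modalities.

    Systemic entries (5A/5B) consume the roman-numeral subcategories that
    follow them up to the next modality code, e.g. ``5A: i, ii; 5C; 5D``.
    """
    s = cell.strip()
    if not s:
        return frozenset()
    matches = list(_MODALITY_CODE_RE.finditer(s))
    modalities: set = set()
    if not matches:
        lowered = s.lower()
        for text, code in _MODALITY_TEXT.items():
            if text in lowered:
                modalities.add(Modality(code))
        if not modalities:
            raise ValueError(f"unrecognised anti-cancer modality cell {cell!r}")
        return frozenset(modalities)

    for i, match in enumerate(matches):
        code = ModalityClass("5" + match.group(1).upper())
        end = matches[i + 1].start() if i + 1 < len(matches) else len(s)
        tail = s[match.end():end]
        if code in (ModalityClass.SACT, ModalityClass.EXPERIMENTAL_SACT):
            subcats = {m.group(1).lower() for m in _ROMAN_RE.finditer(tail)}
            if not subcats:
                raise ValueError(
                    f"systemic modality {code.value} lists no subcategory i-v in {cell!r}")
            for sub in subcats:
                modalities.add(Modality(code, SubCategory(sub)))
        else:
            modalities.add(Modality(code))
    return frozenset(modalities)


def _format_modalities(modalities: frozenset) -> str:
    sub_order = [s.value for s in SubCategory]
    parts: List[str] = []
    for code in ModalityClass:
        entries = [m for m in modalities if m.code is code]
        if not entries:
            continue
        if code in (ModalityClass.SACT, ModalityClass.EXPERIMENTAL_SACT):
            subs = sorted((m.subcategory.value for m in entries), key=sub_order.index)
            parts.append(f"{code.value}: {', '.join(subs)}")
        else:
            parts.append(code.value)
    return "; ".join(parts)


_AGENT_FLAGS = {
    "experimental": "experimental",
    "supportive": "supportive_only",
    "placebo": "placebo",
    "subclinical": "clinically_relevant_exposure",  # presence means False
}


def _parse_agents(cell: str) -> Tuple[AgentRecord, ...]:
    """Parse the Agents extension cell: ``name|class|category|flags; ...``."""
    s = cell.strip()
    if not s:
        return ()
    agents: List[AgentRecord] = []
    for entry in s.split(";"):
        entry = entry.strip()
        if not entry:
            continue
        fields = [f.strip() for f in entry.split("|")]
        if len(fields) > 4:
            raise ValueError(f"agent entry {entry!r} has more than four '|' fields")
        fields += [""] * (4 - len(fields))
        name, agent_class, category_code, flags_field = fields
        if not name:
            raise ValueError(f"agent entry {entry!r} has no name")
        category = None
        if category_code:
            try:
                category = SubCategory(category_code.lower())
            except ValueError:
                raise ValueError(
                    f"agent entry {entry!r}: unknown subcategory {category_code!r}")
        kwargs = {"experimental": False, "supportive_only": False, "placebo": False,
                  "clinically_relevant_exposure": True}
        for flag in re.split(r"[,\s]+", flags_field):
            flag = flag.strip().lower()
            if not flag:
                continue
            if flag not in _AGENT_FLAGS:
                raise ValueError(f"agent entry {entry!r}: unknown flag {flag!r}")
            attr = _AGENT_FLAGS[flag]
            if attr == "clinically_relevant_exposure":
                kwargs[attr] = False
            else:
                kwargs[attr] = True
        agents.append(AgentRecord(name=name, agent_class=agent_class or None,
                                  category=category, **kwargs))
    return tuple(agents)


def _format_agents(agents: Tuple[AgentRecord, ...]) -> str:
    entries = []
    for a in agents:
        flags = []
        if a.experimental:
            flags.append("experimental")
        if a.supportive_only:
            flags.append("supportive")
        if a.placebo:
            flags.append("placebo")
        if not a.clinically_relevant_exposure:
            flags.append("subclinical")
        entries.append("|".join([
            a.name,
            a.agent_class or "",
            a.category.value if a.category is not None else "",
            ",".join(flags),
        ]))
    return "; ".join(entries)


_SETTING_LABELS = {
    ClinicalSetting.EARLY: "2A Early",
    ClinicalSetting.LOCALLY_ADVANCED: "2B Locally advanced",
    ClinicalSetting.METASTATIC: "2C Metastatic",
}
_INTENT_LABELS = {
    TreatmentIntent.CURATIVE: "3A Curative",
    TreatmentIntent.PALLIATIVE: "3B Palliative",
}
_STOP_LABELS = {
    StopReason.CPD: "8A cPD",
    StopReason.COMPLETED: "8B Completed",
    StopReason.TOXICITY: "8C Toxicity",
    StopReason.CHOICE: "8D Choice",
    StopReason.DEATH: "8E Death",
    StopReason.OTHER: "8F Other",
}


# --------------------------------------------------------------------------
# Reading
# --------------------------------------------------------------------------

def _open_source(source):
    if hasattr(source, "read"):
        return source, False
    return open(source, "r", encoding="utf-8", newline=""), True


def read_history(source: Union[str, Path, "TextIO"],
                 dialect: DatasetDialect = DEFAULT_DIALECT,
                 patient_id: str = "patient-1") -> Tuple[PatientHistory, ValidationReport]:
    """Read a standardised dataset file into a typed history.

    Returns the history plus a validation report. Per-row problems
    (unrecognised codes, malformed dates) are reported as ERROR issues with
    the row's serial number (or row position when the serial itself is
    unreadable) and the offending row is left out of the history. A missing
    required column is a hard :class:`DatasetFormatError`.
    """
    stream, should_close = _open_source(source)
    try:
        reader = csv.reader(stream, delimiter=dialect.delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise DatasetFormatError("empty file: no header row")
        columns = {name.strip(): idx for idx, name in enumerate(header)}
        missing = [c for c in _REQUIRED_COLUMNS if c not in columns]
        if missing:
            raise DatasetFormatError(
                f"missing required column(s): {', '.join(repr(c) for c in missing)}")

        report = ValidationReport()
        segments: List[TherapySegment] = []

        def cell(row: List[str], col: str) -> str:
            idx = columns.get(col)
            if idx is None or idx >= len(row):
                return ""
            return row[idx]

        for row_no, row in enumerate(reader, start=2):
            if not any(f.strip() for f in row):
                continue
            serial_text = cell(row, COL_SERIAL).strip()
            try:
                serial = int(serial_text)
            except ValueError:
                report.add(Severity.ERROR, None,
                           f"row {row_no}: serial number {serial_text!r} is not an integer")
                continue
            try:
                segment = TherapySegment(
                    serial_no=serial,
                    clinical_setting=_require(
                        _parse_coded(cell(row, COL_SETTING), ClinicalSetting,
                                     _SETTING_TEXT, "clinical setting"),
                        "clinical setting"),
                    treatment_intent=_parse_coded(
                        cell(row, COL_INTENT), TreatmentIntent, _INTENT_TEXT,
                        "treatment intent"),
                    most_recent_cpd_date=parse_date(cell(row, COL_CPD),
                                                    dialect.date_format),
                    modalities=_parse_modalities(cell(row, COL_MODALITY)),
                    start_date=_require(parse_date(cell(row, COL_START),
                                                   dialect.date_format), "start date"),
                    stop_date=parse_date(cell(row, COL_STOP), dialect.date_format),
                    stop_reason=_parse_coded(cell(row, COL_STOP_REASON), StopReason,
                                             _STOP_TEXT, "stop reason"),
                    comments=cell(row, COL_COMMENTS),
                    agents=_parse_agents(cell(row, COL_AGENTS)),
                    primary_id=cell(row, COL_PRIMARY).strip() or "1",
                    preplanned_with_previous=cell(row, COL_PREPLANNED).strip().lower()
                    in {"yes", "true", "1", "y"},
                )
            except (ValueError, DateParseError) as exc:
                report.add(Severity.ERROR, serial, f"row {row_no}: {exc}")
                continue
            segments.append(segment)

        history = PatientHistory(patient_id=patient_id, segments=tuple(segments))
        report.extend(validate_history(history))
        return history, report
    finally:
        if should_close:
            stream.close()


def _require(value, what: str):
    if value is None:
        raise ValueError(f"{what} is required but missing")
    return value


# --------------------------------------------------------------------------
# Writing
# --------------------------------------------------------------------------

def _open_dest(dest):
    if hasattr(dest, "write"):
        return dest, False
    return open(dest, "w", encoding="utf-8", newline=""), True


def _write_rows(history: PatientHistory,
                labels: Dict[int, str],
                dest,
                dialect: DatasetDialect) -> None:
    stream, should_close = _open_dest(dest)
    try:
        writer = csv.writer(stream, delimiter=dialect.delimiter,
                            lineterminator="\n")
        writer.writerow(CANONICAL_COLUMNS)
        for seg in history.segments:
            writer.writerow([
                str(seg.serial_no),
                _SETTING_LABELS[seg.clinical_setting],
                _INTENT_LABELS[seg.treatment_intent] if seg.treatment_intent else "",
                format_date(seg.most_recent_cpd_date, dialect.date_format),
                _format_modalities(seg.modalities),
                format_date(seg.start_date, dialect.date_format),
                format_date(seg.stop_date, dialect.date_format),
                _STOP_LABELS[seg.stop_reason] if seg.stop_reason else "",
                seg.comments,
                labels.get(seg.serial_no, ""),
                _format_agents(seg.agents),
                seg.primary_id,
                "yes" if seg.preplanned_with_previous else "",
            ])
    finally:
        if should_close:
            stream.close()


def write_history(history: PatientHistory,
                  dest: Union[str, Path, "TextIO"],
                  dialect: DatasetDialect = DEFAULT_DIALECT) -> None:
    """Write a history without line labels (the engine's input form)."""
    _write_rows(history, {}, dest, dialect)


def write_annotated(annotated: AnnotatedHistory,
                    dest: Union[str, Path, "TextIO"],
                    dialect: DatasetDialect = DEFAULT_DIALECT) -> None:
    """Write an annotated history with the label column filled in.

    Qualifying segments carry their ``N (CLoT + PLoT)`` label; skipped
    segments leave the column empty. Row order and serial numbers are
    preserved exactly as recorded (the writer never re-sorts).
    """
    labels = {a.serial_no: a.label for a in annotated.assignments}
    _write_rows(annotated.history, labels, dest, dialect)
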