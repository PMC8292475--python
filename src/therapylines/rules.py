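"""Qualification and transition rules for line-of-therapy enumeration.

Two questions are decided here, as pure traceable functions:

1. Does a therapy segment count toward a line of therapy at all?
   (:func:`qualifies_for_lot`) — only systemic anti-cancer therapy (SACT,
   including experimental SACT) with at least one genuinely anti-cancer agent
   at clinically relevant exposure qualifies. Surgery, radiotherapy and other
   local modalities are never assigned a line; neither are placebo-only or
   supportive-only exposures.

2. Does a qualifying segment open a new line or continue the open one?
   (:func:`classify_transition`) — a first-match decision cascade over the
   five draft guidelines:

   * G1 — once a new clinical progression (cPD) is documented, the next SACT
     opens a new line;
   * G2 — absent progression, an agent discontinued for toxicity and
     substituted by another agent of the same class retains the line;
   * G3 — absent progression, adding a new agent to the ongoing SACT opens a
     new line (unless the addition was prospectively planned);
   * G4 — dropping agents from the ongoing SACT retains the line for the
     remaining agents;
   * G5 — dose/schedule/route modifications with an unchanged agent set
     retain the line.

   Pre-planned continuations (switch maintenance, planned sequences) always
   continue the line, and a documented new progression dominates every
   continuation rule.

Unplanned regimen changes without progression that match none of the above
(e.g. wholesale switch to a disjoint regimen, or substitution for financial
reasons) are an open scenario in the framework; they default to a new line
with a warning, and the trigger set for G2 is configurable.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Tuple

from .datamodel import (
    AgentRecord,
    ClinicalSetting,
    StopReason,
    TherapySegment,
    TreatmentIntent,
)

__all__ = [
    "Action",
    "EngineConfig",
    "Guideline",
    "LineState",
    "QualificationDecision",
    "SameClassSource",
    "Track",
    "TransitionDecision",
    "assign_track",
    "classify_transition",
    "counted_agents",
    "is_new_progression",
    "qualifies_for_lot",
]


class Track(Enum):
    """Curative-track (CLoT) versus palliative-track (PLoT) attribution."""

    CURATIVE = "curative"
    PALLIATIVE = "palliative"


class Action(Enum):
    NEW_LINE = "new_line"
    CONTINUE_LINE = "continue_line"


class Guideline(Enum):
    """Which clause of the decision cascade fired."""

    FIRST_SEGMENT = "first_segment"
    PREPLANNED = "preplanned"
    G1 = "G1"  # new progression -> new line
    G2 = "G2"  # same-class substitution after toxicity -> continue
    G3 = "G3"  # agent added without progression -> new line
    G4 = "G4"  # agent dropped -> continue
    G5 = "G5"  # dose/schedule/route change -> continue


@dataclass(frozen=True)
class QualificationDecision:
    """Whether a segment counts toward a line, and why."""

    qualifies: bool
    experimental: bool  # True iff every counted agent is experimental
    clause: str

    def __post_init__(self) -> None:
        if not self.qualifies and self.experimental:
            raise ValueError("a non-qualifying segment cannot be experimental SACT")


@dataclass(frozen=True)
class TransitionDecision:
    action: Action
    guideline: Guideline
    rationale: str
    warnings: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.guideline is Guideline.FIRST_SEGMENT and self.action is not Action.NEW_LINE:
            raise ValueError("the first qualifying segment always opens a line")
        continue_only = {Guideline.G2, Guideline.G4, Guideline.G5, Guideline.PREPLANNED}
        if self.guideline in continue_only and self.action is not Action.CONTINUE_LINE:
            raise ValueError(f"{self.guideline.value} implies continuation")


@dataclass
class LineState:
    """Running state of the currently open line for one primary."""

    line_number: int
    track: Track
    opening_segment_start: dt.date
    opening_intent: Optional[TreatmentIntent]
    opening_setting: ClinicalSetting
    clot_at_open: int
    plot_at_open: int
    current_agents: Tuple[AgentRecord, ...]
    member_serials: list
    last_stop_reason: Optional[StopReason] = None
    last_stop_date: Optional[dt.date] = None


class SameClassSource(Enum):
    """How "same class" is judged for G2 substitutions.

    AGENT_CLASS_FIELD compares the caller-supplied free-text class (e.g.
    "taxane"), falling back to the coarse i-v subcategory with a warning when
    a class is absent. SUBCATEGORY_FALLBACK compares subcategories only.
    """

    AGENT_CLASS_FIELD = "agent_class_field"
    SUBCATEGORY_FALLBACK = "subcategory_fallback"


@dataclass(frozen=True)
class EngineConfig:
    """Documented defaults for every judgement the framework leaves open.

    ``substitution_reasons_for_g2`` — stop reasons of the preceding segment
    that allow a same-class substitution to retain the line; the guideline
    names toxicity (8C), so that is the whole default set. Substitutions for
    choice/financial reasons (8D/8F) then fall through to a new line with a
    warning, reflecting that the framework poses them as unresolved.

    ``treat_gap_resumption_as_continuation`` — whether resuming the identical
    agent set after an unplanned break (drug holiday) without intervening
    progression continues the line (default) or opens a new one.

    ``unknown_intent_track_policy`` — with intent missing, the track is read
    off the clinical setting: early (2A) counts as curative-track, locally
    advanced/metastatic (2B/2C) as palliative-track.
    """

    same_class_source: SameClassSource = SameClassSource.AGENT_CLASS_FIELD
    substitution_reasons_for_g2: frozenset = frozenset({StopReason.TOXICITY})
    treat_gap_resumption_as_continuation: bool = True
    unknown_intent_track_policy: str = "BY_SETTING"

    def to_dict(self) -> dict:
        return {
            "same_class_source": self.same_class_source.value,
            "substitution_reasons_for_g2": ",".join(
                sorted(r.value for r in self.substitution_reasons_for_g2)),
            "treat_gap_resumption_as_continuation":
                str(self.treat_gap_resumption_as_continuation).lower(),
            "unknown_intent_track_policy": self.unknown_intent_track_policy,
        }

    def to_text(self) -> str:
        """Flat ``key = value`` serialisation, echoed on every run."""
        return "\n".join(f"{k} = {v}" for k, v in self.to_dict().items())

    @classmethod
    def from_dict(cls, data: dict) -> "EngineConfig":
        kwargs: dict = {}
        if "same_class_source" in data:
            kwargs["same_class_source"] = SameClassSource(data["same_class_source"])
        if "substitution_reasons_for_g2" in data:
            raw = data["substitution_reasons_for_g2"]
            codes = [c.strip() for c in raw.split(",") if c.strip()] if isinstance(raw, str) else list(raw)
            kwargs["substitution_reasons_for_g2"] = frozenset(StopReason(c) for c in codes)
        if "treat_gap_resumption_as_continuation" in data:
            raw = data["treat_gap_resumption_as_continuation"]
            kwargs["treat_gap_resumption_as_continuation"] = (
                raw if isinstance(raw, bool) else str(raw).strip().lower() in {"true", "1", "yes"})
        if "unknown_intent_track_policy" in data:
            kwargs["unknown_intent_track_policy"] = data["unknown_intent_track_policy"]
        return cls(**kwargs)

    @classmethod
    def from_text(cls, text: str) -> "EngineConfig":
        data: dict = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            data[key.strip()] = value.strip()
        return cls.from_dict(data)


DEFAULT_CONFIG = EngineConfig()


# --------------------------------------------------------------------------
# Qualification
# --------------------------------------------------------------------------

def counted_agents(segment: TherapySegment) -> Tuple[AgentRecord, ...]:
    """Agents that count as anti-cancer exposure for this segment.

    Excludes supportive-only use, blinded placebo, and exposures below a
    clinically relevant dose/duration.
    """
    return tuple(a for a in segment.agents
                 if not a.supportive_only
                 and not a.placebo
                 and a.clinically_relevant_exposure)


def qualifies_for_lot(segment: TherapySegment) -> QualificationDecision:
    """Decide whether a segment is assigned a line of therapy at all."""
    if not segment.is_systemic:
        return QualificationDecision(
            False, False,
            "local modality only (surgery/radiotherapy/other local energy); "
            "local treatments are not assigned a line of therapy")
    counted = counted_agents(segment)
    if not counted:
        agents = segment.agents
        if agents and all(a.placebo for a in agents):
            clause = ("placebo-only exposure is not a SACT "
                      "(absent unblinded information)")
        elif agents and all(a.supportive_only or a.placebo for a in agents):
            clause = ("agents given for supportive/symptomatic care only are "
                      "not anti-cancer agents")
        elif agents:
            clause = ("no agent reached a clinically relevant dose/duration "
                      "in the clinician's judgement")
        else:
            clause = "systemic modality recorded without agents"
        return QualificationDecision(False, False, clause)
    experimental = all(a.experimental for a in counted)
    clause = ("experimental SACT (no counted agent approved for any cancer "
              "at start of therapy)" if experimental
              else "SACT with at least one counted anti-cancer agent")
    return QualificationDecision(True, experimental, clause)


# --------------------------------------------------------------------------
# Transitions
# --------------------------------------------------------------------------

def is_new_progression(line: LineState, segment: TherapySegment) -> bool:
    """True iff the segment's cPD date documents a progression on this line.

    A cPD date that precedes the line's opening is the progression that
    motivated the line, not a new event.
    """
    cpd = segment.most_recent_cpd_date
    return cpd is not None and cpd > line.opening_segment_start


def _class_keys(agents, config: EngineConfig):
    """Comparison keys for same-class matching, plus any fallback warnings."""
    keys = []
    warnings = []
    for agent in agents:
        if (config.same_class_source is SameClassSource.AGENT_CLASS_FIELD
                and agent.class_key is not None):
            keys.append(("class", agent.class_key))
        else:
            if (config.same_class_source is SameClassSource.AGENT_CLASS_FIELD
                    and agent.class_key is None):
                warnings.append(
                    f"agent class missing for {agent.name!r}; judging same-class "
                    f"substitution by the coarse i-v subcategory")
            category = agent.category.value if agent.category is not None else "unspecified"
            keys.append(("subcategory", category))
    return sorted(keys), warnings


def _is_same_class_swap(dropped, added, config: EngineConfig):
    """One-for-one replacement of discontinued agents by same-class agents."""
    if not dropped or not added or len(dropped) != len(added):
        return False, []
    dropped_keys, w1 = _class_keys(dropped, config)
    added_keys, w2 = _class_keys(added, config)
    return dropped_keys == added_keys, w1 + w2


def classify_transition(line: Optional[LineState],
                        segment: TherapySegment,
                        config: EngineConfig = DEFAULT_CONFIG) -> TransitionDecision:
    """Decide NEW_LINE vs CONTINUE_LINE for one qualifying segment.

    First-match cascade: first qualifying segment for the primary; pre-planned
    continuation (absent new progression); G1; G2; G3; G4; G5. A regimen
    change matching no clause defaults to a new line with a warning.
    The decision is a pure function of ``(line, segment, config)``.
    """
    if line is None:
        return TransitionDecision(
            Action.NEW_LINE, Guideline.FIRST_SEGMENT,
            "first qualifying systemic therapy recorded for this primary")

    new_progression = is_new_progression(line, segment)

    if segment.preplanned_with_previous and not new_progression:
        return TransitionDecision(
            Action.CONTINUE_LINE, Guideline.PREPLANNED,
            "prospectively planned continuation of the ongoing SACT "
            "(part of the same discrete attempt to treat)")

    if new_progression:
        return TransitionDecision(
            Action.NEW_LINE, Guideline.G1,
            f"clinical progression documented {segment.most_recent_cpd_date} "
            f"after the line opened {line.opening_segment_start}; the next SACT "
            f"receives a new line")

    current = {a.key: a for a in line.current_agents}
    incoming = {a.key: a for a in counted_agents(segment)}
    added = [incoming[k] for k in incoming.keys() - current.keys()]
    dropped = [current[k] for k in current.keys() - incoming.keys()]

    if added and dropped and line.last_stop_reason in config.substitution_reasons_for_g2:
        matched, warnings = _is_same_class_swap(dropped, added, config)
        if matched:
            reason = line.last_stop_reason.value
            return TransitionDecision(
                Action.CONTINUE_LINE, Guideline.G2,
                f"agent(s) discontinued ({reason}) and substituted by same-class "
                f"agent(s) without progression; the line is retained",
                tuple(warnings))

    if added and not dropped:
        names = ", ".join(sorted(a.name for a in added))
        return TransitionDecision(
            Action.NEW_LINE, Guideline.G3,
            f"new agent(s) added to the ongoing SACT without progression "
            f"({names}); this is a new SACT and a new line")

    if dropped and not added and incoming:
        return TransitionDecision(
            Action.CONTINUE_LINE, Guideline.G4,
            "agent(s) discontinued from the ongoing SACT; the line is retained "
            "for the remaining agents")

    if not added and not dropped:
        if (not config.treat_gap_resumption_as_continuation
                and line.last_stop_date is not None):
            return TransitionDecision(
                Action.NEW_LINE, Guideline.G3,
                "identical agent set resumed after an unplanned break; configured "
                "policy counts the resumption as a new line",
                ("unplanned resumption after a treatment gap treated as a new "
                 "line per configuration",))
        return TransitionDecision(
            Action.CONTINUE_LINE, Guideline.G5,
            "agent set unchanged; dose/schedule/route modifications retain the line")

    # unresolved scenario: simultaneous add+drop outside G2, or wholesale switch
    return TransitionDecision(
        Action.NEW_LINE, Guideline.G3,
        "unplanned regimen change without documented progression matches no "
        "continuation rule; counted as a new line",
        ("unplanned regimen change without cPD (e.g. non-toxicity substitution "
         "or wholesale switch); defaulting to a new line",))


# --------------------------------------------------------------------------
# Track attribution
# --------------------------------------------------------------------------

def assign_track(segment: TherapySegment,
                 config: EngineConfig = DEFAULT_CONFIG) -> Track:
    """Dichotomise a line-opening segment into curative vs palliative track.

    The clinician's stated intent takes precedence over the clinical setting
    (curative therapy of metastatic disease exists, e.g. chemosensitive germ
    cell tumours). With intent missing, the configured policy reads the track
    off the setting: early -> curative, otherwise palliative.
    """
    if segment.treatment_intent is TreatmentIntent.CURATIVE:
        return Track.CURATIVE
    if segment.treatment_intent is TreatmentIntent.PALLIATIVE:
        return Track.PALLIATIVE
    # BY_SETTING is the only policy currently defined
    if segment.clinical_setting is ClinicalSetting.EARLY:
        return Track.CURATIVE
    return Track.PALLIATIVE
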