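"""Seeded generator of synthetic treatment histories with known answers.

The generator builds chronologically consistent patient journeys —
curative-track lines first (early setting), then palliative-track lines
(locally advanced, then metastatic), each opened by a documented progression
— and, with configurable probabilities, exercises every continuation rule:
same-class substitution after toxicity, agent drops, dose changes, and
interleaved non-qualifying surgery/radiotherapy segments. Because the
generator decides which segments open lines, it can emit the expected
line assignments alongside the history; this by-construction ground truth
is an oracle that is entirely independent of the rule engine.

It is a rule-coverage generator, not a disease model: dates sit on a
synthetic monthly grid (only event order matters to the rules), and there is
no epidemiological realism in regimen choice or durations.
"""

from __future__ import annotations

import datetime as dt
import random
from dataclasses import dataclass
from typing import List, Optional, Tuple

from .datamodel import (
    AgentRecord,
    ClinicalSetting,
    Modality,
    ModalityClass,
    PatientHistory,
    StopReason,
    SubCategory,
    TherapySegment,
    TreatmentIntent,
)
from .enumerator import LineAssignment, format_label
from .rules import (
    Action,
    Guideline,
    QualificationDecision,
    Track,
    TransitionDecision,
)

__all__ = ["ScenarioConfig", "generate_history"]


@dataclass(frozen=True)
class ScenarioConfig:
    """Shape of one synthetic journey.

    Defaults mirror the reference worked example: two curative-track lines
    followed by seven palliative-track lines. Event probabilities are per
    line and chosen as realistic rule-coverage rates: toxicity-driven
    same-class substitution 0.2, agent drop 0.1, dose/schedule change 0.2,
    and a 0.15 chance of a non-qualifying local-therapy segment (surgery or
    radiotherapy) between lines.
    """

    n_curative_lines: int = 2
    n_palliative_lines: int = 7
    p_toxicity_substitution: float = 0.2
    p_agent_drop: float = 0.1
    p_dose_change: float = 0.2
    p_nonqualifying_interleave: float = 0.15
    multi_primary: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_toxicity_substitution", "p_agent_drop", "p_dose_change",
                     "p_nonqualifying_interleave"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]; got {p}")
        if self.n_curative_lines < 0 or self.n_palliative_lines < 0:
            raise ValueError("line counts must be non-negative")
        if self.n_curative_lines + self.n_palliative_lines < 1:
            raise ValueError("at least one line is required")


# Small formulary: (class, subcategory, members). Classes with two members
# support same-class substitution.
_FORMULARY: Tuple[Tuple[str, SubCategory, Tuple[str, ...]], ...] = (
    ("taxane", SubCategory.CYTOTOXIC, ("paclitaxel", "docetaxel")),
    ("anthracycline", SubCategory.CYTOTOXIC, ("doxorubicin", "epirubicin")),
    ("platinum", SubCategory.CYTOTOXIC, ("carboplatin", "cisplatin")),
    ("fluoropyrimidine", SubCategory.CYTOTOXIC, ("capecitabine", "5-fluorouracil")),
    ("aromatase inhibitor", SubCategory.ENDOCRINE, ("letrozole", "anastrozole")),
    ("selective oestrogen receptor degrader", SubCategory.ENDOCRINE, ("fulvestrant",)),
    ("CDK4/6 inhibitor", SubCategory.TARGETED, ("palbociclib", "ribociclib")),
    ("mTOR inhibitor", SubCategory.TARGETED, ("everolimus",)),
    ("PD-1 inhibitor", SubCategory.IMMUNOTHERAPY, ("pembrolizumab", "nivolumab")),
)


def _grid(month_index: int, day: int = 1) -> dt.date:
    """Synthetic monthly date grid starting 2000 Jan 01."""
    year, month = divmod(month_index, 12)
    return dt.date(2000 + year, month + 1, day)


@dataclass
class _PlannedSegment:
    """A segment before serial numbers are known, plus its expected verdict."""

    kwargs: dict
    qualifies: bool
    # for qualifying segments:
    line_number: int = 0
    track: Optional[Track] = None
    clot: int = 0
    plot: int = 0
    action: Optional[Action] = None
    guideline: Optional[Guideline] = None


class _PrimaryBuilder:
    """Builds one primary's segments on a shared month counter."""

    def __init__(self, rng: random.Random, config: ScenarioConfig,
                 primary_id: str, start_month: int):
        self.rng = rng
        self.config = config
        self.primary_id = primary_id
        self.month = start_month
        self.planned: List[_PlannedSegment] = []
        self.clot = 0
        self.plot = 0
        self.pending_cpd: Optional[dt.date] = None  # opens the next line

    def _pick_regimen(self, n_agents: int, need_swappable: bool) -> List[AgentRecord]:
        pool = list(_FORMULARY)
        self.rng.shuffle(pool)
        if need_swappable:
            pool.sort(key=lambda entry: len(entry[2]) < 2)  # swappable classes first
        agents = []
        for cls, cat, members in pool[:n_agents]:
            agents.append(AgentRecord(self.rng.choice(members), cls, cat))
        return agents

    def _substitute(self, agent: AgentRecord) -> AgentRecord:
        for cls, cat, members in _FORMULARY:
            if cls == agent.agent_class:
                others = [m for m in members if m != agent.name]
                if others:
                    return AgentRecord(self.rng.choice(others), cls, cat)
        raise AssertionError("swappable class required for substitution event")

    def _maybe_interleave(self, setting: ClinicalSetting,
                          intent: TreatmentIntent) -> None:
        if self.rng.random() >= self.config.p_nonqualifying_interleave:
            return
        code = self.rng.choice((ModalityClass.SURGERY, ModalityClass.RADIOTHERAPY))
        start = _grid(self.month)
        stop = _grid(self.month, day=14)
        self.month += 1
        self.planned.append(_PlannedSegment(
            kwargs=dict(
                clinical_setting=setting, treatment_intent=intent,
                most_recent_cpd_date=None,
                modalities=frozenset({Modality(code)}), agents=(),
                start_date=start, stop_date=stop,
                stop_reason=StopReason.COMPLETED,
                primary_id=self.primary_id,
                comments="local therapy (not assigned a line)"),
            qualifies=False))

    def add_line(self, track: Track, setting: ClinicalSetting,
                 intent: TreatmentIntent, is_last: bool) -> None:
        cfg = self.config
        rng = self.rng

        events: List[str] = []
        if rng.random() < cfg.p_toxicity_substitution:
            events.append("G2")
        if rng.random() < cfg.p_agent_drop:
            events.append("G4")
        if rng.random() < cfg.p_dose_change:
            events.append("G5")

        need_swappable = "G2" in events
        n_agents = 2 if "G4" in events else rng.choice((1, 2))
        agents = self._pick_regimen(n_agents, need_swappable)

        if track is Track.CURATIVE:
            self.clot += 1
        else:
            self.plot += 1
        line_number = self.clot + self.plot

        opener_cpd = self.pending_cpd
        start = _grid(self.month)
        self.month += rng.randint(2, 5)  # therapy duration in months

        chain: List[_PlannedSegment] = []

        def push(seg_agents, guideline, action, comments):
            chain.append(_PlannedSegment(
                kwargs=dict(
                    clinical_setting=setting, treatment_intent=intent,
                    most_recent_cpd_date=opener_cpd,
                    modalities=frozenset(
                        Modality(ModalityClass.SACT, a.category) for a in seg_agents),
                    agents=tuple(seg_agents),
                    start_date=start, stop_date=None, stop_reason=None,
                    primary_id=self.primary_id, comments=comments),
                qualifies=True, line_number=line_number, track=track,
                clot=self.clot, plot=self.plot, action=action, guideline=guideline))

        push(agents, Guideline.FIRST_SEGMENT if line_number == 1 else Guideline.G1,
             Action.NEW_LINE, "line opener")

        current = list(agents)
        for event in events:
            if event == "G2":
                victim = next(a for a in current
                              if len(next(m for c, _, m in _FORMULARY
                                          if c == a.agent_class)) >= 2)
                chain[-1].kwargs["stop_date"] = _grid(self.month, day=14)
                chain[-1].kwargs["stop_reason"] = StopReason.TOXICITY
                self.month += 1
                start = _grid(self.month)
                self.month += rng.randint(2, 4)
                current = [self._substitute(a) if a is victim else a for a in current]
                push(current, Guideline.G2, Action.CONTINUE_LINE,
                     "same-class substitute after toxicity")
            elif event == "G4":
                chain[-1].kwargs["stop_date"] = _grid(self.month, day=14)
                chain[-1].kwargs["stop_reason"] = StopReason.CHOICE
                self.month += 1
                start = _grid(self.month)
                self.month += rng.randint(2, 4)
                current = current[:-1]  # drop one agent, keep the rest
                push(current, Guideline.G4, Action.CONTINUE_LINE,
                     "agent dropped, remaining agents continue")
            else:  # G5
                chain[-1].kwargs["stop_date"] = _grid(self.month, day=14)
                chain[-1].kwargs["stop_reason"] = StopReason.OTHER
                self.month += 1
                start = _grid(self.month)
                self.month += rng.randint(2, 4)
                push(list(current), Guideline.G5, Action.CONTINUE_LINE,
                     "dose reduced, same agents")

        # close the line and schedule the progression that opens the next one
        if is_last and track is Track.PALLIATIVE:
            pass  # final palliative line stays ongoing (no stop date)
        elif track is Track.CURATIVE:
            stop = _grid(self.month, day=14)
            chain[-1].kwargs["stop_date"] = stop
            chain[-1].kwargs["stop_reason"] = StopReason.COMPLETED
            self.month += rng.randint(1, 3)  # disease-free interval
            self.pending_cpd = _grid(self.month)
            self.month += 1
        else:
            stop = _grid(self.month, day=14)
            chain[-1].kwargs["stop_date"] = stop
            chain[-1].kwargs["stop_reason"] = StopReason.CPD
            self.pending_cpd = stop  # progression documented at stop
            self.month += 1

        self.planned.extend(chain)
        if not is_last:
            self._maybe_interleave(setting, intent)

    def build(self) -> None:
        cfg = self.config
        total = cfg.n_curative_lines + cfg.n_palliative_lines
        index = 0
        for _ in range(cfg.n_curative_lines):
            index += 1
            self.add_line(Track.CURATIVE, ClinicalSetting.EARLY,
                          TreatmentIntent.CURATIVE, is_last=index == total)
        for j in range(cfg.n_palliative_lines):
            index += 1
            setting = (ClinicalSetting.LOCALLY_ADVANCED if j == 0
                       else ClinicalSetting.METASTATIC)
            self.add_line(Track.PALLIATIVE, setting,
                          TreatmentIntent.PALLIATIVE, is_last=index == total)


def generate_history(config: ScenarioConfig) -> Tuple[PatientHistory, List[LineAssignment]]:
    """Generate one history plus its by-construction expected assignments.

    Identical configs (including seed) produce identical output. The expected
    assignments carry the generator's own transition verdicts (action and
    guideline) and labels; the final line of the first primary is numbered
    ``n_curative_lines + n_palliative_lines`` with CLoT/PLoT equal to the
    configured line counts.
    """
    rng = random.Random(config.seed)
    builders = [_PrimaryBuilder(rng, config, "1", start_month=0)]
    builders[0].build()
    if config.multi_primary:
        # an independent second primary diagnosed after the first journey,
        # presenting de novo metastatic (no prior progression on record)
        second = _PrimaryBuilder(rng, config, "2",
                                 start_month=builders[0].month + 1)
        second.add_line(Track.PALLIATIVE, ClinicalSetting.METASTATIC,
                        TreatmentIntent.PALLIATIVE, is_last=True)
        builders.append(second)

    planned = [p for b in builders for p in b.planned]
    planned.sort(key=lambda p: p.kwargs["start_date"])

    segments: List[TherapySegment] = []
    expected: List[LineAssignment] = []
    for serial, plan in enumerate(planned, start=1):
        segments.append(TherapySegment(serial_no=serial, **plan.kwargs))
        if plan.qualifies:
            decision = TransitionDecision(
                plan.action, plan.guideline, "synthetic ground truth")
            qualification = QualificationDecision(
                True, False, "synthetic ground truth")
            expected.append(LineAssignment(
                serial_no=serial, primary_id=plan.kwargs["primary_id"],
                line_number=plan.line_number, track=plan.track,
                clot=plan.clot, plot=plan.plot,
                label=format_label(plan.line_number, plan.clot, plan.plot),
                decision=decision, qualification=qualification))

    return PatientHistory(patient_id=f"synthetic-{config.seed}",
                          segments=tuple(segments)), expected
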