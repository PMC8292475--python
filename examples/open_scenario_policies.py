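"""How configurable policies change verdicts in genuinely open scenarios.

The framework resolves the common cases but leaves some situations open —
substitution for financial (not toxicity) reasons, drug holidays,
rechallenge. The engine makes its defaults explicit in ``EngineConfig`` so
an audit can state exactly which convention produced each count.

Here: a patient stops oxaliplatin for financial reasons (8F Other) and
switches to cisplatin (same class, platinum) with no progression. Under the
default policy only toxicity (8C) triggers the same-class substitution rule,
so the switch opens line 2; a site that decides financial substitutions
should retain the line adds 8F to the trigger set.
"""

import datetime as dt

from therapylines import (
    AgentRecord, ClinicalSetting, EngineConfig, Modality, ModalityClass,
    PatientHistory, StopReason, SubCategory, TherapySegment, TreatmentIntent,
    assign_lines,
)

CYTO = SubCategory.CYTOTOXIC
SACT = frozenset({Modality(ModalityClass.SACT, CYTO)})

history = PatientHistory("financial-substitution", (
    TherapySegment(
        serial_no=1, clinical_setting=ClinicalSetting.METASTATIC,
        treatment_intent=TreatmentIntent.PALLIATIVE, modalities=SACT,
        agents=(AgentRecord("oxaliplatin", "platinum", CYTO),),
        start_date=dt.date(2022, 1, 10), stop_date=dt.date(2022, 4, 2),
        stop_reason=StopReason.OTHER, comments="stopped for financial reasons"),
    TherapySegment(
        serial_no=2, clinical_setting=ClinicalSetting.METASTATIC,
        treatment_intent=TreatmentIntent.PALLIATIVE, modalities=SACT,
        agents=(AgentRecord("cisplatin", "platinum", CYTO),),
        start_date=dt.date(2022, 4, 20), comments="no progression documented"),
))

for name, config in [
    ("default (G2 requires toxicity)", EngineConfig()),
    ("site policy (8F also triggers G2)",
     EngineConfig(substitution_reasons_for_g2=frozenset(
         {StopReason.TOXICITY, StopReason.OTHER}))),
]:
    annotated = assign_lines(history, config)
    verdict = annotated.assignments[-1]
    print(f"{name}:")
    print(f"  segment 2 -> {verdict.decision.guideline.value}, "
          f"label {verdict.label}")
    for warning in annotated.warnings:
        print(f"  warning: {warning}")
    print()

print("Same records, different documented conventions: 2 (0 + 2) under the "
      "default, 1 (0 + 1) when financial substitution retains the line. The "
      "effective config is serialised with every run so counts are auditable.")
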