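"""Packaged example history: a hypothetical breast-cancer journey.

The ten-segment history below is the framework's reference worked example:
a patient first treated with curative intent in the early setting (a
pre-planned neoadjuvant chemotherapy → surgery → radiotherapy → endocrine
sequence counted as a single SACT, then endocrine therapy plus mastectomy
for an isolated local recurrence), followed by seven palliative-track lines
through locally advanced and metastatic disease — including a
paclitaxel → docetaxel same-class substitution after toxicity that retains
its line, and a final experimental targeted agent.

The expected labels run ``1 (1 + 0)`` through ``9 (2 + 7)``, with the
toxicity-substitution pair sharing the repeated label ``5 (2 + 3)``.
"""

from __future__ import annotations

import datetime as dt

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

__all__ = ["EXPECTED_LABELS", "breast_cancer_history"]

#: Expected ``N (CLoT + PLoT)`` labels for the ten segments, in serial order.
EXPECTED_LABELS = (
    "1 (1 + 0)", "2 (2 + 0)", "3 (2 + 1)", "4 (2 + 2)", "5 (2 + 3)",
    "5 (2 + 3)", "6 (2 + 4)", "7 (2 + 5)", "8 (2 + 6)", "9 (2 + 7)",
)

_SACT = ModalityClass.SACT
_EXP = ModalityClass.EXPERIMENTAL_SACT
_CYTO = SubCategory.CYTOTOXIC
_ENDO = SubCategory.ENDOCRINE
_TARG = SubCategory.TARGETED


def _d(year: int, month: int, day: int) -> dt.date:
    return dt.date(year, month, day)


def breast_cancer_history(patient_id: str = "example-breast") -> PatientHistory:
    """Build the ten-segment reference history (single primary)."""
    segments = (
        TherapySegment(
            serial_no=1,
            clinical_setting=ClinicalSetting.EARLY,
            treatment_intent=TreatmentIntent.CURATIVE,
            most_recent_cpd_date=None,  # initial diagnosis 1999 Dec 20
            modalities=frozenset({
                Modality(_SACT, _CYTO), Modality(_SACT, _ENDO),
                Modality(ModalityClass.SURGERY), Modality(ModalityClass.RADIOTHERAPY),
            }),
            agents=(
                AgentRecord("5-fluorouracil", "fluoropyrimidine", _CYTO),
                AgentRecord("epirubicin", "anthracycline", _CYTO),
                AgentRecord("cyclophosphamide", "alkylating agent", _CYTO),
                AgentRecord("tamoxifen", "selective oestrogen receptor modulator", _ENDO),
                AgentRecord("letrozole", "aromatase inhibitor", _ENDO),
            ),
            start_date=_d(2000, 1, 1),
            stop_date=_d(2005, 8, 14),
            stop_reason=StopReason.COMPLETED,
            comments="Pre-planned sequence: chemotherapy x6, breast-conserving "
                     "surgery, external-beam radiotherapy, then endocrine therapy "
                     "(tamoxifen 2 y, letrozole 3 y); one SACT",
        ),
        TherapySegment(
            serial_no=2,
            clinical_setting=ClinicalSetting.EARLY,
            treatment_intent=TreatmentIntent.CURATIVE,
            most_recent_cpd_date=_d(2010, 12, 22),
            modalities=frozenset({Modality(_SACT, _ENDO),
                                  Modality(ModalityClass.SURGERY)}),
            agents=(AgentRecord("letrozole", "aromatase inhibitor", _ENDO),),
            start_date=_d(2011, 1, 1),
            stop_date=_d(2013, 1, 1),
            stop_reason=StopReason.COMPLETED,
            comments="Isolated local recurrence; mastectomy then letrozole 2 y",
        ),
        TherapySegment(
            serial_no=3,
            clinical_setting=ClinicalSetting.LOCALLY_ADVANCED,
            treatment_intent=TreatmentIntent.PALLIATIVE,
            most_recent_cpd_date=_d(2015, 2, 1),
            modalities=frozenset({Modality(_SACT, _ENDO)}),
            agents=(AgentRecord("anastrozole", "aromatase inhibitor", _ENDO),),
            start_date=_d(2015, 2, 7),
            stop_date=_d(2016, 9, 19),
            stop_reason=StopReason.CPD,
            comments="Anastrozole",
        ),
        TherapySegment(
            serial_no=4,
            clinical_setting=ClinicalSetting.METASTATIC,
            treatment_intent=TreatmentIntent.PALLIATIVE,
            most_recent_cpd_date=_d(2016, 9, 15),
            modalities=frozenset({Modality(_SACT, _ENDO), Modality(_SACT, _TARG)}),
            agents=(
                AgentRecord("everolimus", "mTOR inhibitor", _TARG),
                AgentRecord("exemestane", "aromatase inhibitor", _ENDO),
            ),
            start_date=_d(2016, 10, 2),
            stop_date=_d(2017, 1, 7),
            stop_reason=StopReason.CPD,
            comments="Everolimus + exemestane",
        ),
        TherapySegment(
            serial_no=5,
            clinical_setting=ClinicalSetting.METASTATIC,
            treatment_intent=TreatmentIntent.PALLIATIVE,
            most_recent_cpd_date=_d(2017, 1, 7),
            modalities=frozenset({Modality(_SACT, _CYTO)}),
            agents=(AgentRecord("paclitaxel", "taxane", _CYTO),),
            start_date=_d(2017, 2, 1),
            stop_date=_d(2017, 7, 17),
            stop_reason=StopReason.TOXICITY,
            comments="Paclitaxel, stopped for neuropathy",
        ),
        TherapySegment(
            serial_no=6,
            clinical_setting=ClinicalSetting.METASTATIC,
            treatment_intent=TreatmentIntent.PALLIATIVE,
            most_recent_cpd_date=_d(2017, 1, 7),
            modalities=frozenset({Modality(_SACT, _CYTO)}),
            agents=(AgentRecord("docetaxel", "taxane", _CYTO),),
            start_date=_d(2017, 8, 9),
            stop_date=_d(2017, 12, 23),
            stop_reason=StopReason.CPD,
            comments="Docetaxel substituted for paclitaxel (same class), "
                     "no new progression",
        ),
        TherapySegment(
            serial_no=7,
            clinical_setting=ClinicalSetting.METASTATIC,
            treatment_intent=TreatmentIntent.PALLIATIVE,
            most_recent_cpd_date=_d(2017, 12, 17),
            modalities=frozenset({Modality(_SACT, _CYTO)}),
            agents=(AgentRecord("capecitabine", "fluoropyrimidine", _CYTO),),
            start_date=_d(2018, 1, 8),
            stop_date=_d(2018, 8, 15),
            stop_reason=StopReason.CPD,
            comments="Capecitabine",
        ),
        TherapySegment(
            serial_no=8,
            clinical_setting=ClinicalSetting.METASTATIC,
            treatment_intent=TreatmentIntent.PALLIATIVE,
            most_recent_cpd_date=_d(2018, 8, 15),
            modalities=frozenset({Modality(_SACT, _CYTO)}),
            agents=(AgentRecord("eribulin", "halichondrin", _CYTO),),
            start_date=_d(2018, 9, 1),
            stop_date=_d(2018, 12, 30),
            stop_reason=StopReason.CPD,
            comments="Eribulin",
        ),
        TherapySegment(
            serial_no=9,
            clinical_setting=ClinicalSetting.METASTATIC,
            treatment_intent=TreatmentIntent.PALLIATIVE,
            most_recent_cpd_date=_d(2019, 1, 3),
            modalities=frozenset({Modality(_SACT, _ENDO)}),
            agents=(AgentRecord("fulvestrant",
                                "selective oestrogen receptor degrader", _ENDO),),
            start_date=_d(2019, 1, 27),
            stop_date=_d(2019, 6, 15),
            stop_reason=StopReason.CPD,
            comments="Fulvestrant",
        ),
        TherapySegment(
            serial_no=10,
            clinical_setting=ClinicalSetting.METASTATIC,
            treatment_intent=TreatmentIntent.PALLIATIVE,
            most_recent_cpd_date=_d(2019, 6, 4),
            modalities=frozenset({Modality(_EXP, _TARG)}),
            agents=(AgentRecord("experimental small molecule", None, _TARG,
                                experimental=True),),
            start_date=_d(2019, 6, 22),
            stop_date=_d(2020, 4, 30),
            stop_reason=StopReason.CPD,
            comments="Experimental targeted small molecule (trial)",
        ),
    )
    return PatientHistory(patient_id=patient_id, segments=segments)
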