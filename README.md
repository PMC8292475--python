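# therapylines

Deterministic, auditable enumeration of **lines of therapy (LoT)** from
standardised treatment histories in solid cancers.

Counting how many lines of systemic therapy a patient has received sounds
trivial and is anything but: trial protocols, audits and reimbursement rules
all need the number, yet clinicians and databases count differently —
should (neo)adjuvant therapy count? a taxane swapped for another taxane
after neuropathy? a drug dropped from a doublet? `therapylines` implements a
systematic framework that answers these questions with explicit, replayable
rules, for clinical-data curators, trial feasibility screeners and
real-world-evidence analysts.

## The model

A patient history is a chronological table of **therapy segments**, each
coded with the clinical setting (2A early / 2B locally advanced / 2C
metastatic), treatment intent (3A curative / 3B palliative), the date of the
most recent **clinical progression of disease (cPD)**, modality codes (5A
SACT, 5B experimental SACT, 5C surgery, 5D radiotherapy, 5E other local),
start/stop dates, a stop-reason code (8A cPD … 8F other) and a structured
agent list.

Only **systemic anti-cancer therapy** (SACT, including experimental SACT) is
assigned a line; local modalities, supportive-only drugs, blinded placebo
and sub-clinical exposures are skipped. Each qualifying segment is then
classified by a first-match cascade:

1. **G1** — once a new cPD is documented, the next SACT opens a new line;
2. **G2** — without progression, an agent stopped for toxicity and replaced
   by a same-class agent retains the line;
3. **G3** — without progression, adding a new agent to the ongoing SACT
   opens a new line (unless prospectively planned);
4. **G4** — dropping agents retains the line for the remainder;
5. **G5** — dose/schedule/route changes with the same agents retain the line.

Every line is dichotomised into the **curative track** (curative intent
and/or early setting) or the **palliative track**, and reported cumulatively
as **`N (CLoT + PLoT)`** with `N = CLoT + PLoT`: a patient on
`5 (2 + 3)` is on their fifth-ever line — two curative-track, three
palliative-track. Intent takes precedence over setting (curative therapy of
metastatic disease exists). Multiple primaries get independent counters.

Scenarios the framework leaves open (financial substitutions, drug holidays,
rechallenge) are explicit `EngineConfig` policies with documented defaults,
serialised with every run.

## Worked example

```sh
python examples/worked_example.py
```

```
segment  rule            label       agents
      1  first_segment   1 (1 + 0)   5-fluorouracil, epirubicin, cyclophosphamide, tamoxifen, letrozole
      2  G1              2 (2 + 0)   letrozole
      3  G1              3 (2 + 1)   anastrozole
      4  G1              4 (2 + 2)   everolimus, exemestane
      5  G1              5 (2 + 3)   paclitaxel
      6  G2              5 (2 + 3)   docetaxel
      7  G1              6 (2 + 4)   capecitabine
      8  G1              7 (2 + 5)   eribulin
      9  G1              8 (2 + 6)   fulvestrant
     10  G1              9 (2 + 7)   experimental small molecule

Final status: line 9 of therapy (2 curative-track + 7 palliative-track).
```

Segment 1 is a pre-planned neoadjuvant-chemo → surgery → radiotherapy →
endocrine sequence counted as a *single* SACT (one line). Segments 5–6 show
G2: docetaxel substituted for paclitaxel after neuropathy, same class, no
progression — the repeated label `5 (2 + 3)` marks one discrete attempt to
treat. The experimental agent (segment 10) still earns a line. Other
examples cover eligibility queries (`examples/eligibility_queries.py`),
engine-vs-generator auditing (`examples/synthetic_cohort.py`) and
configurable open-scenario policies (`examples/open_scenario_policies.py`).

The same pipeline is available from a shell:

```sh
therapylines assign -i history.csv -o annotated.csv     # fills column 10
therapylines validate -i history.csv
therapylines simulate --curative 2 --palliative 7 --seed 1 -o synthetic.csv
```

## Library surface

- `datamodel` — typed segments/histories, coded vocabularies, date parsing
  (`2021 Jan 01` and ISO forms), `validate_history` (ERRORs block, WARNINGs
  don't);
- `rules` — `qualifies_for_lot`, `classify_transition`, `assign_track`,
  `EngineConfig`;
- `enumerator` — `assign_lines`, `format_label`, `summarize` (per-primary
  totals, metastatic-line counts, disease-free intervals);
- `io` — CSV/TSV reader/writer for the standardised columns plus a
  structured `Agents` column; lossless round trips;
- `synthgen` — seeded scenario generator emitting histories *with*
  by-construction expected assignments (an engine-independent oracle);
- `datasets` — the packaged ten-segment reference journey.

See `docs/methods.md` for the full decision semantics, defaults and
limitations.

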