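# Methods

## Problem and scope

`therapylines` mechanises the enumeration of lines of therapy (LoT) in
solid cancers from a standardised, coded treatment history. It is a rule
engine, not a statistical model: given the same records and configuration it
always produces the same labels, and every verdict carries the clause that
produced it. Haematological malignancies are out of scope (the framework's
vocabulary — operable/inoperable, early/advanced — is solid-tumour
specific), as is any inference from free text, drug dictionaries, imaging
response criteria or EHR integration: settings, intents, cPD dates and
agent flags are inputs asserted by the data curator.

## Qualification

A segment is assigned a line iff it has a systemic modality (5A SACT or 5B
experimental SACT) **and** at least one *counted* agent: not
supportive-only, not blinded placebo, and at a clinically relevant
dose/duration in the clinician's judgement. Surgery-, radiotherapy- and
other-local-only segments never receive a line: their impact on subsequent
systemic options is unclear and counting them would conflate modalities.
A segment whose counted agents are all unapproved (for any cancer, at start
date) is an *experimental* SACT — it still earns a line. Unblinding is
modelled by the caller clearing the `placebo` flag.

## Transition cascade

For a qualifying segment against the currently open line of its primary,
the first matching clause wins:

| order | clause | verdict |
|---|---|---|
| a | no open line | NEW (first segment) |
| b | pre-planned continuation, no new progression | CONTINUE |
| c | new progression documented (G1) | NEW |
| d | same-class swap after a configured stop reason (G2) | CONTINUE |
| e | agents added, none removed (G3) | NEW |
| f | agents removed, none added (G4) | CONTINUE |
| g | identical agent set (G5: dose/schedule/route change) | CONTINUE |
| — | anything else (disjoint switch, non-G2 substitution) | NEW + warning |

Definitions used by the clauses:

- **New progression** means the segment's most-recent-cPD date is strictly
  later than the *opening* segment's start date of the current line. A cPD
  date earlier than the opening is the progression that motivated the line
  (the reference journey's docetaxel row repeats its paclitaxel line's cPD
  date) and never closes it.
- **Agent identity** is the case-folded, trimmed agent name; only counted
  agents participate, so adding an antiemetic never triggers G3.
- **Same class** (G2) is equality of the caller-supplied free-text class
  (case-insensitive), requiring a one-for-one match between dropped and
  added agents. When a class string is absent the comparison falls back to
  the coarse i–v subcategory and emits a warning — the free text is
  preferred because the subcategory alone would equate, say, capecitabine
  with eribulin. A config switch (`same_class_source`) forces
  subcategory-only matching for datasets without class annotations.

Two deliberate tie-breaks, since the guidelines can be read as
conflicting:

- Progression dominates every continuation rule (the cascade fires G1
  before G2/G4/G5, and before the pre-planned clause). The guidelines say
  drops and modifications retain the line "irrespective of cPD", but also
  that once cPD is documented the *next SACT* gets a new line; we resolve in
  favour of progression, which is the reading consistent with the reference
  journey and with auditing practice (a post-progression regimen is a new
  attempt to treat even if its agent set overlaps the old one).
- A line has exactly one curative/palliative attribution, fixed by its
  opening segment. A continuing segment whose own intent differs draws a
  warning but never re-tracks the line (the reference substitution pair
  shares one label).

## Track attribution and the label

On NEW, the line's track is the opening segment's intent (3A → curative,
3B → palliative) — intent takes precedence over setting, so curative-intent
therapy of metastatic disease is curative-track. With intent missing, the
default policy reads the setting (2A → curative; 2B/2C → palliative) and
warns. CLoT/PLoT/N are cumulative over the whole journey, early and
advanced phases alike, per primary organ; `format_label` enforces
`N = CLoT + PLoT` as a hard contract. Whether a second tumour in a paired
organ continues the numbering or starts fresh is exactly the caller's
`primary_id` coding. No ordering constraint is imposed between tracks: a
curative-track line may follow palliative-track lines (oligometastatic
disease rendered resectable).

## Configurable open scenarios

The framework explicitly leaves some situations to future consensus; the
engine makes them named `EngineConfig` policies rather than hidden
hard-codes, and serialises the effective config with every run:

- `substitution_reasons_for_g2` (default `{8C}`): G2 names toxicity only.
  Financial/choice substitutions therefore default to a new line with a
  warning.
- `treat_gap_resumption_as_continuation` (default true): resuming the
  identical regimen after an unplanned break without intervening cPD keeps
  the line ("discrete attempt to treat" spirit); sites may count it as a
  new line instead. Rechallenge after progression is always G1.
- `unknown_intent_track_policy` (`BY_SETTING`): the only policy currently
  defined for missing intent.

These defaults are the package's own documented conventions, not claims
about any consensus.

## Validation

`validate_history` separates ERRORs (block enumeration: duplicate/negative
serials, unordered segments, stop before start, cPD after start, systemic
segments without agents, stop date/reason present without the other, cPD
dates regressing within a primary) from WARNINGs (missing intent, a
progression-coded stop without a later cPD on the successor, intent
differing from the line opener). The "later cPD" check compares against the
previous segment's cPD date, not its stop date — a progression is routinely
documented days before the therapy formally stops. Dates are day-resolution
Gregorian dates; the native spelling is `YYYY MMM DD` with English
three-letter months, ISO `YYYY-MM-DD` is accepted, and `NA`-prefixed cells
mean absent.

## File format

CSV (RFC-4180 quoting) or TSV, UTF-8, header mandatory. The ten standard
columns are written canonically and read leniently (code prefix wins over
descriptive text; modality cells may combine entries, `5A: i, ii; 5C; 5D`).
Three machine-readable extensions make the file deterministic where the
standard keeps prose: a required `Agents` column
(`name|class|category|flags`, `;`-separated; flags `experimental`,
`supportive`, `placebo`, `subclinical`), an optional `Primary ID`, and an
optional `Preplanned continuation` marker. Comments are carried verbatim
and never parsed. The writer preserves row order and serial numbers;
write → read is lossless for every typed field, and the emitted label
column matches `^[0-9]+ \([0-9]+ \+ [0-9]+\)$`.

## Synthetic generator

`synthgen` exists to audit the engine without patient data. It composes
journeys line by line — curative lines first (2A/3A), then palliative (the
first 2B, the rest 2C), each subsequent line opened by a cPD date strictly
after the previous line's opening — and, per line, samples continuation
events: a toxicity-driven same-class substitution (must continue via G2),
an agent drop (G4), a dose change (G5), plus optional non-qualifying
surgery/radiotherapy interleaves. Because the generator decides the
structure, it emits the expected assignment for every segment as it builds;
this ground truth never calls the engine, making the agreement test a true
dual-route check.

Defaults (2 curative + 7 palliative lines; substitution 0.2, drop 0.1, dose
change 0.2, interleave 0.15 per line) mirror the reference journey's shape
with event rates chosen once as plausible for a heavily pre-treated solid
tumour course. Dates sit on a synthetic monthly grid from 2000 Jan 01 —
only event *order* matters to the rules — and all randomness flows from a
single `random.Random(seed)` stream, so identical configs are byte-identical.
The generator is a rule-coverage tool, not a disease model: it does not
emulate survival, regimen popularity, missing data, or coding errors, so
passing the agreement suite demonstrates correctness of the rule fold, not
robustness to dirty real-world records (that is what validation and the
warning channel are for).

## Test-suite problem sizes

The cascade truth table enumerates 120 cells (3 cPD positions × 4 stop
reasons × 5 agent-set relations × pre-planned flag); the engine/generator
agreement suite replays 1000 seeded scenarios spanning line counts from
(1, 0) to (3, 4) shapes and event probabilities from 0 to 1, with the
inertness/round-trip properties checked on the reference history plus 60
synthetic ones. The whole suite runs in a few seconds on one CPU.

## Known limitations

- Same-class judgement is only as good as the supplied class strings; there
  is no drug ontology.
- `preplanned_with_previous` is an input assertion; the engine never infers
  planned sequences from timing.
- Disease-free intervals are computed from recorded stop and cPD dates and
  can be negative (progression documented before the formal stop); they are
  reported as-is for the caller's eligibility logic.
- Histories are processed per patient; cohort-level analytics beyond
  `summarize` are out of scope.
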