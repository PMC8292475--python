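"""Trial-eligibility style queries over an annotated history.

Two screening questions the cumulative label format answers directly:

* "no more than k separate lines of treatment for metastatic disease" —
  count lines whose opening segment is coded metastatic (2C);
* "prior early-setting therapy counts as advanced if the disease-free
  interval was shorter than d days" — the gap between one line's stop date
  and the progression date that opened the next.
"""

from therapylines import assign_lines, datasets, summarize

annotated = assign_lines(datasets.breast_cancer_history())
summary = summarize(annotated).primary("1")

print(f"Total lines: {summary.n_lines}  "
      f"(CLoT {summary.clot} + PLoT {summary.plot})")
print(f"Current label: {summary.current_label}")
print(f"Lines opened in the metastatic setting: "
      f"{summary.lines_opened_in_metastatic_setting}")

print("\nDisease-free / progression-free gaps between consecutive lines:")
for line_number, days in sorted(summary.disease_free_interval_days.items()):
    print(f"  line {line_number} -> line {line_number + 1}: {days:>5} days")

print("\nA negative gap means the progression was documented a few days "
      "before the previous therapy formally stopped.")
print(f"Eligible for a trial requiring <= 2 prior metastatic lines? "
      f"{'yes' if summary.lines_opened_in_metastatic_setting <= 2 else 'no'}")
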