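"""Enumerate lines of therapy for the packaged breast-cancer journey.

Builds the ten-segment reference history (two curative-track episodes in the
early setting, then seven palliative-track lines through locally advanced
and metastatic disease), runs the rule engine with default configuration and
prints one trace row per segment: which guideline fired and the cumulative
``N (CLoT + PLoT)`` label. The paclitaxel -> docetaxel toxicity substitution
(segments 5 and 6) shares the repeated label ``5 (2 + 3)`` — one discrete
attempt to treat, two drugs of the same class.
"""

from therapylines import assign_lines, datasets

history = datasets.breast_cancer_history()
annotated = assign_lines(history)

print(f"{'segment':>7}  {'rule':<14}  {'label':<10}  agents")
for assignment in annotated.assignments:
    segment = history.segment(assignment.serial_no)
    agents = ", ".join(a.name for a in segment.agents) or "-"
    print(f"{assignment.serial_no:>7}  {assignment.decision.guideline.value:<14}  "
          f"{assignment.label:<10}  {agents}")

final = annotated.assignments[-1]
print(f"\nFinal status: line {final.line_number} of therapy "
      f"({final.clot} curative-track + {final.plot} palliative-track).")
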