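"""Full paired active / ATP-depleted cohort analysis on synthetic cells.

Generates 12 paired cells (trajectory sets + LLPS images per condition)
with the programmed effect structure — active cells gain mechanical work
that raises K_alpha, alpha and entropy and homogenizes their content —
runs the complete measurement chain, and prints the assembled report:
paired t-tests, per-arm regressions, the refitted elastic law, and the
qualitative direction expectations.
"""

from diffent import pipeline, synth

spec = synth.CohortSpec(seed=7)
data = synth.generate_cohort(spec)
report = pipeline.analyze_cohort(data)

print(report.to_markdown())
print("\nEvery 'yes' marks a programmed effect recovered end to end from "
      "rendered trajectories and images, not from the ground truth table.")
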