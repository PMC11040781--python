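"""Full treatment-comparison study: does a treatment widen fibril spacing?

Simulates triplicate reference and treated samples where the treatment
increases the true interfibrillar spacing by 22% (the Kratky peak shifts to
lower q) without touching the crystal structure, runs the whole pipeline,
and prints per-condition summaries and the treated-vs-reference comparison.
"""

from cellscatter import RunConfig, run_study

report = run_study(RunConfig(seed=7, spacing_increase=0.22, n_replicates=3))

summaries = report.summaries.set_index(["measure", "condition"])
for cond in ("reference", "treated"):
    row = summaries.loc[("d_cc_A", cond)]
    print(f"{cond:<10} d_cc = {row['mean']:.2f} +/- {row['sd']:.2f} A (n = {row['n']})")

comp = report.comparisons.set_index("measure")
dcc = comp.loc["d_cc_A"]
star = "*" if dcc.significant else ""
print(f"\nspacing change: {dcc.percent_change:+.1f}% (p = {dcc.p_value:.2g}, "
      f"two-tailed t-test){star}")
ci = comp.loc["crystallinity_index"]
print(f"crystallinity index change: {ci.percent_change:+.1f}% (p = {ci.p_value:.2g})")
print(
    "\nThe spacing increase is significant while crystallinity is not - the\n"
    "signature of a treatment that loosens fibril packing without degrading\n"
    "the crystals themselves."
)
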