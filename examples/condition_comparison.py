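"""Full study comparison: intact vs regenerating, per temporal bin.

Simulates the default two-condition study (four roots per condition,
seven days at 15-minute cadence), where the regenerating condition departs
from the intact one only 24 hours after perturbation, and runs the
Kolmogorov-Smirnov comparison harness across temporal bins and metrics.
"""

from rootmitosis import run_comparisons
from rootmitosis.synthetic import intact_defaults, regenerating_defaults, simulate_table

table = simulate_table(intact_defaults(1), regenerating_defaults(1), 4)
print(f"{len(table)} events, roots: {', '.join(table.root_ids)}\n")

report = run_comparisons(table)
print(report.to_text())
print("\nburst thresholds (mean + 1 SD, pooled per condition):",
      {k: round(v, 2) for k, v in report.conventions["burst_thresholds"].items()})
print("-> events per frame: indistinguishable in the 0-6 h and 6-24 h bins,")
print("   diverging from 24 h on — the late-onset signature of regeneration.")
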