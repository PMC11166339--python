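"""Crude odds ratios from a published exposure-by-status table.

A 3x2 table of printed counts is all the crude analysis needs; Woolf
confidence limits use the sum of reciprocal cells.
"""

from nestedcc import CrudeTable, crude_or

# 215 cases / 1,516 controls by rebamipide prescription status
table = CrudeTable(
    counts={
        "non_user": (93, 724),
        "continuous_user": (52, 597),
        "irregular_user": (70, 195),
    }
)

pct = table.column_percentages()
for cat, (a, b) in table.counts.items():
    print(f"{cat:<16} cases {a:>3} ({pct[cat][0]:.1f}%)  controls {b:>4} ({pct[cat][1]:.1f}%)")

for cat, (orr, (lo, hi)) in crude_or(table).items():
    print(f"crude OR {cat}: {orr:.2f} (95% CI {lo:.2f}-{hi:.2f})")

# Expected output: 0.68 (0.47-0.97) for continuous vs non-users and
# 2.79 (1.97-3.96) for irregular vs non-users -- continuous co-prescription
# is associated with fewer bleeds even before matching adjusts for dose.
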