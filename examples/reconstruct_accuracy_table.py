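"""Recover integer contingency tables from printed accuracy percentages.

Published diagnostic tables often give SE/SP/PPV/NPV at one decimal without
the underlying counts.  With the positive-class size known (37 gap segments)
and one shared negative-class size, exhaustive integer enumeration recovers
the only consistent tables — and feeding them back through the metrics
reproduces every printed cell.
"""

from pfmap import contingency_metrics, reconstruct_counts, round_report

ROWS = [
    ("bipolar voltage ", (16.2, 96.1, 50.0, 82.8)),
    ("omnipolar voltage", (10.8, 97.4, 50.0, 82.1)),
    ("bipolar PF       ", (51.4, 96.8, 79.2, 89.3)),
    ("omnipolar PF     ", (54.1, 95.5, 74.1, 89.7)),
]

solutions = reconstruct_counts([r for _, r in ROWS], n_gap=37)
sol = solutions[0]
print(f"unique minimal negative-class size: n_block = {sol.n_block}")
for (name, printed), table in zip(ROWS, sol.tables):
    m = contingency_metrics(table)
    cells = tuple(round_report(m[k]) for k in ("se", "sp", "ppv", "npv"))
    ok = "reproduces printed row" if cells == printed else "MISMATCH"
    print(f"{name} tp={table.tp:2d} fp={table.fp:2d} fn={table.fn:2d} tn={table.tn:3d}  "
          f"SE/SP/PPV/NPV = {cells}  <- {ok}")
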