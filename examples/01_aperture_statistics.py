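"""Gap-width and leaf-trailing statistics of a dual-layer VMAT plan.

Generates a synthetic three-arc plan of the "small target" class, writes
it to disk, reads it back, and reports the per-strip effective gap
percentiles and the trailing-class breakdown: how often each layer's tip
defines the field edge, and how far the other layer trails behind it.
"""

import io

from duomlc import (
    generate_vmat_plan,
    plan_gap_trailing_stats,
    read_plan,
    write_plan,
)

plan = generate_vmat_plan("small", seed=42)

# round-trip through the serialized form, as an exported plan would travel
buf = io.StringIO()
write_plan(plan, buf)
buf.seek(0)
plan = read_plan(buf)

stats = plan_gap_trailing_stats(plan)
print("Effective 5 mm strip gaps over all control points:")
print(f"  median {stats.gap_median:5.1f} mm   "
      f"IQR [{stats.gap_p25:.1f}, {stats.gap_p75:.1f}] mm   "
      f"({stats.n_gap_samples} open samples)")
print("Trailing classes over the open bank edges:")
for cls, pct in stats.class_pct.items():
    print(f"  {cls.value:28s} {pct:5.1f} %")
print(f"  (sum {sum(stats.class_pct.values()):.1f} % — the classes partition "
      "the edges)")
print()
print("Reading: a large short-trailing / overlap share means many edges")
print("behave like a mono-block collimator tip rather than a single-layer")
print("rounded tip, which lowers the effective leaf-tip transmission.")
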