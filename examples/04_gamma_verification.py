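"""Dose-difference and global gamma verification of a mismatched plan.

Simulates a biplanar-array measurement of a VMAT plan with the study tip
model (true per-layer DLGs 0.97 / 0.87 mm), recalculates the plan the way
a planning system with a 0.1 mm DLG would, and verifies calculated
against measured with global 2%/2 mm gamma and a 10% low-dose threshold.
"""

import numpy as np

from duomlc import (
    DetectorGeometry,
    compute_fluence_field,
    delta4_detector_points,
    generate_vmat_plan,
    pooled_histogram,
    verify_against_field,
)
from duomlc.synthetic import study_tip_model

model = study_tip_model()
plan = generate_vmat_plan("small", seed=5)
pts = delta4_detector_points(DetectorGeometry())

# "measurement": the trailing-aware engine plus 0.5 % array noise
meas_field = compute_fluence_field(plan, model, "measured")
rng = np.random.default_rng(5)
measured = meas_field.dose_at(pts)
measured = np.maximum(
    measured + rng.normal(0.0, 0.005 * measured.max(), len(measured)), 0.0
)

# "calculation": constant 0.1 mm DLG, no trailing dependence
calc_field = compute_fluence_field(plan, model, "tps", dlg_calc=0.1)

result = verify_against_field(pts, measured, calc_field)
print(f"points evaluated (>= 10% of max dose): {result.n_evaluated}")
print(f"mean dose difference: {result.dd_mean:+.2f} %  (SD {result.dd_sd:.2f} %)")
print(f"mean gamma (2%/2mm):  {result.gamma_mean:.2f}   (SD {result.gamma_sd:.2f})")
print(f"gamma pass rate:      {result.pass_rate:.2f} %")

hist = pooled_histogram([result.per_point_dd], bin_width=1.0)
print("\nPooled DD histogram (1 % bins):")
for _, row in hist.iterrows():
    bar = "#" * int(60 * row["count"] / hist["count"].max())
    print(f"  [{row['bin_low']:+5.1f}, {row['bin_high']:+5.1f}) "
          f"{int(row['count']):5d} {bar}")

print("\nReading: the negative mean DD says the 0.1 mm-DLG calculation")
print("underestimates the delivered dose; the gamma pass rate sits below")
print("the usual 95 % action level, motivating DLG tuning.")
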