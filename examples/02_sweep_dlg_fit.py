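"""Measure the dosimetric leaf gap from sweeping-gap readings.

Simulates the sweeping-gap test (gaps 2-20 mm, 120 mm sweep) for a single
layer and for trailing distances between 0 and 20 mm, corrects each
reading for transmission, fits the dose-ratio line, and prints the DLG
versus trailing distance — the x-intercept drops toward the mono-block
value as the two layers' tips close on each other.
"""

from duomlc import (
    Layer,
    default_tip_model,
    fit_readings,
    simulate_sweep_reading,
    trailing_curve,
)

model = default_tip_model()
gaps = range(2, 21, 2)

print("Single-layer sweeps (no trailing layer):")
for layer in (Layer.PROXIMAL, Layer.DISTAL):
    readings = [simulate_sweep_reading(g, None, model, layer) for g in gaps]
    fit = fit_readings(
        readings,
        t_layer=model.transmission[layer],
        t_dual=model.dual_transmission,
    )
    print(f"  {layer.value:8s}: DLG = {fit.dlg:+.3f} mm  "
          f"(slope {fit.slope:.5f}/mm, R^2 = {fit.r_squared:.6f})")

fits = {}
for t in (0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 10.0, 20.0):
    readings = [simulate_sweep_reading(g, t, model, Layer.PROXIMAL) for g in gaps]
    fits[t] = fit_readings(
        readings,
        t_layer=model.transmission[Layer.PROXIMAL],
        t_dual=model.dual_transmission,
    )

print("\nTrailing sweeping-gap test (proximal leading, distal trailing):")
table = trailing_curve(fits)
print(table[["trailing_mm", "dlg_mm", "r_squared"]].to_string(index=False))
print("\nReading: beyond ~5 mm of trailing the DLG saturates at the")
print("single-layer value; at zero trailing the coincident tips behave as")
print("one mono-block edge and the fitted DLG turns negative.")
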