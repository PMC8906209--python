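"""The full empirical DLG-tuning loop on a synthetic plan cohort.

Runs the end-to-end study: generate dual-layer plans of both target
classes, simulate measurements, verify the 0.1 mm-DLG baseline, tune the
DLG per layer and class on single-layer sequences (openings of 0 / 0.2 /
0.4 / 0.6 mm per bank emulate DLGs of 0.1 / 0.5 / 0.9 / 1.3 mm), assign
the nearest 0.2 mm-grid value and re-verify the dual-layer plans.

Scaled down for a desk run (about a minute); pass a StudyConfig for
larger cohorts.
"""

from duomlc import DetectorGeometry, StudyConfig, run_study

config = StudyConfig(
    n_small=2,
    n_large=1,
    n_cp_per_arc=40,
    detector=DetectorGeometry(
        spacing_central=3.0, spacing_outer=6.0, central_extent=80.0, extent=160.0
    ),
)
report = run_study(config, seed=17)

print("True per-layer DLGs of the generating tip model:",
      report.true_dlg)
print("\nTuning results (mean DD is % of max measured dose):")
for (scope, layer), t in sorted(report.tuning.items()):
    grid = ", ".join(f"{d:.1f}: {dd:+.2f}%" for d, dd in zip(t.dlg_grid, t.mean_dd))
    print(f"  {scope:8s} {layer:8s}  DLG_emp = {t.dlg_emp:.3f} mm "
          f"(slope {t.slope:.2f} %/mm, R^2 {t.r_squared:.5f})")
    print(f"           grid {{{grid}}} -> assigned {t.assigned_dlg:.1f} mm, "
          f"opening {t.per_bank_opening:.1f} mm/bank")

print(f"\nAssigned DLG used for the final pass: {report.assigned_dlg}")
print(f"baseline dual-layer: mean DD {report.pooled_mean_dd('baseline'):+.2f} %, "
      f"gamma pass {report.pooled_pass_rate('baseline'):.2f} %")
print(f"after tuning:        mean DD {report.pooled_mean_dd('final'):+.2f} %, "
      f"gamma pass {report.pooled_pass_rate('final'):.2f} %")

print("\nReading: the mean DD responds linearly to the assigned DLG, its")
print("zero crossing recovers the generating tip model to a few")
print("hundredths of a millimetre, and re-verifying with the assigned")
print("value moves the systematic dose difference to about zero while the")
print("gamma pass rate climbs above its baseline.")
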