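"""Empirical DLG tuning: sweep a DLG grid, find the zero crossing, assign.

The planning system's built-in DLG cannot be edited directly, so a larger
effective DLG is *emulated* by opening every leaf pair of a layer by
``(DLG - base)/2`` per bank and recalculating with unchanged monitor
units.  The pooled mean dose difference responds linearly to the DLG, so
the empirically adjusted value ``DLG_emp`` is the zero crossing of a
least-squares line through the (DLG, mean DD) grid.  Because serialized
positions carry one decimal, only DLGs on the ``base + 0.2k`` mm grid are
assignable; ``assign_dlg`` rounds to that grid (ties upward).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import math

import numpy as np

from .editing import apply_leaf_opening, opening_for_dlg
from .plan import DualLayerPlan, Layer
from .verification import DoseDistribution, mean_dose_difference

__all__ = [
    "TuningResult",
    "evaluate_dlg_grid",
    "find_dlg_emp",
    "assign_dlg",
    "tune_dlg",
]


@dataclass(frozen=True)
class TuningResult:
    """Outcome of one DLG-tuning pass (one layer, one plan pool)."""

    dlg_grid: tuple[float, ...]
    mean_dd: tuple[float, ...]  # pooled mean DD per grid value, %
    slope: float  # %/mm
    intercept: float
    r_squared: float
    dlg_emp: float  # zero crossing, mm
    extrapolated: bool
    assigned_dlg: float  # nearest value on the base + 0.2k grid, mm
    per_bank_opening: float  # (assigned_dlg - base)/2, mm


def evaluate_dlg_grid(
    plans: Sequence[DualLayerPlan],
    measurements: Sequence[DoseDistribution],
    dlg_values: Sequence[float],
    dose_engine: Callable[[DualLayerPlan], DoseDistribution],
    layers: set[Layer] | None = None,
    base_dlg: float = 0.1,
    threshold_pct: float = 10.0,
) -> dict[float, float]:
    """Pooled mean dose difference at each DLG of a grid.

    For each DLG value, every plan is opened by ``opening_for_dlg`` on the
    given layers, recalculated through ``dose_engine`` with unchanged MU,
    and compared to its measurement; the per-plan mean DDs are pooled by
    an unweighted mean.  Engine failures on individual plans are reported
    as warnings and the remaining plans carry the pool.
    """
    if len(plans) != len(measurements):
        raise ValueError("need one measurement per plan")
    out: dict[float, float] = {}
    for dlg in dlg_values:
        delta = opening_for_dlg(dlg, base_dlg)
        per_plan = []
        for pi, (plan, meas) in enumerate(zip(plans, measurements)):
            try:
                edited = (
                    plan if delta == 0.0
                    else apply_leaf_opening(plan, delta, layers=layers)
                )
                calc = dose_engine(edited)
                dd = mean_dose_difference(meas, calc, threshold_pct=threshold_pct)
                per_plan.append(dd.mean)
            except Exception as exc:  # pragma: no cover - defensive path
                warnings.warn(
                    f"plan {pi} failed at DLG {dlg} mm: {exc}", stacklevel=2
                )
        if not per_plan:
            raise RuntimeError(f"all plans failed at DLG {dlg} mm")
        out[dlg] = float(np.mean(per_plan))
    return out


def find_dlg_emp(
    grid: dict[float, float] | Sequence[tuple[float, float]],
    slope_tol: float = 1e-6,
) -> tuple[float, float, dict]:
    """Zero crossing of the mean-DD-versus-DLG line.

    Fits an ordinary least-squares line ``DD = slope * dlg + c`` through
    all grid points (the response is linear, so no piecewise scheme) and
    returns ``(dlg_emp, slope, diagnostics)`` with ``dlg_emp = -c /
    slope``.  The diagnostics carry the intercept, R² and an
    ``extrapolated`` flag raised when the crossing lies outside the grid
    range.  Exact on collinear input and invariant to point order.
    """
    pairs = sorted(grid.items()) if isinstance(grid, dict) else sorted(grid)
    if len(pairs) < 2:
        raise ValueError("need mean DD at >= 2 DLG values")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    slope, intercept = np.polyfit(x, y, 1)
    if abs(slope) < slope_tol:
        raise ValueError("DD insensitive to DLG: slope below tolerance")
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - float((resid**2).sum()) / ss_tot
    dlg_emp = float(-intercept / slope)
    diags = {
        "intercept": float(intercept),
        "r_squared": r2,
        "extrapolated": bool(dlg_emp < x.min() or dlg_emp > x.max()),
    }
    return dlg_emp, float(slope), diags


def assign_dlg(
    dlg_emp: float, base: float = 0.1, step: float = 0.2
) -> tuple[float, float]:
    """Round an empirical DLG to the assignable ``base + k*step`` grid.

    Positions serialize at 0.1 mm, so per-bank openings — and hence DLG
    increments — come in 0.2 mm steps.  Ties round up.  Returns
    ``(assigned_dlg, per_bank_opening)``.
    """
    if step <= 0.0:
        raise ValueError("step must be > 0")
    k = max(0, math.floor((dlg_emp - base) / step + 0.5))
    assigned = base + k * step
    return round(assigned, 10), round((assigned - base) / 2.0, 10)


def tune_dlg(
    plans: Sequence[DualLayerPlan],
    measurements: Sequence[DoseDistribution],
    dlg_values: Sequence[float],
    dose_engine: Callable[[DualLayerPlan], DoseDistribution],
    layers: set[Layer] | None = None,
    base_dlg: float = 0.1,
) -> TuningResult:
    """Full tuning pass: grid evaluation, zero crossing, assignment."""
    grid = evaluate_dlg_grid(
        plans, measurements, dlg_values, dose_engine, layers=layers,
        base_dlg=base_dlg,
    )
    dlg_emp, slope, diags = find_dlg_emp(grid)
    assigned, opening = assign_dlg(dlg_emp, base=base_dlg)
    dlgs = tuple(sorted(grid))
    return TuningResult(
        dlg_grid=dlgs,
        mean_dd=tuple(grid[d] for d in dlgs),
        slope=slope,
        intercept=diags["intercept"],
        r_squared=diags["r_squared"],
        dlg_emp=dlg_emp,
        extrapolated=diags["extrapolated"],
        assigned_dlg=assigned,
        per_bank_opening=opening,
    )
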