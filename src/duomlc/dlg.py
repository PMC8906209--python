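"""Sweeping-gap analysis: transmission correction and DLG extraction.

In a sweeping-gap test a constant gap ``g`` travels a distance ``L`` at
constant speed across an on-axis chamber.  The chamber signal relative to
an open reference field grows linearly with ``g``; with rounded leaf tips
the line does not pass through the origin, and the (negative) x-intercept
of the least-squares fit is the dosimetric leaf gap:

    y(g) = slope * (g + DLG)        =>  DLG = intercept / slope

Before fitting, the raw dose ratio ``D_g / D_ref`` is corrected for leaf
transmission accumulated while the point is blocked.  The correction used
here is a dwell-fraction model: the beam-on fraction for which the chamber
sits behind leaves is split into a dual-shielded part (both layers, dwell
``(L - g - 2t)/L``, transmission ``T_dual``) and a single-shielded part
(dwell ``2t/L`` between the leading and trailing tips in the trailing
test, or ``(L - g)/L`` in the plain single-layer test, charged at the
swept layer's transmission).  Any other correction can be substituted via
the ``correction`` hook of :func:`fit_readings`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .plan import Layer

__all__ = [
    "SweepReading",
    "DlgFitResult",
    "corrected_ratio",
    "fit_dlg",
    "fit_readings",
    "readings_from_csv",
    "trailing_curve",
]


@dataclass(frozen=True)
class SweepReading:
    """One chamber reading of a sweeping-gap field.

    ``trailing`` is the trailing distance in mm, or ``None`` for a plain
    single-layer sweep (other layer fully retracted) — the distinction
    matters for the transmission correction, because at ``t = 0`` the
    blocked region is dual-shielded while with no trailing layer it is
    single-shielded.
    """

    gap: float
    d_g: float
    d_ref: float
    trailing: float | None = None
    layer: Layer | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.d_ref <= 0.0:
            raise ValueError("d_ref must be > 0")
        if self.d_g < 0.0:
            raise ValueError("d_g must be >= 0")

    @property
    def ratio(self) -> float:
        return self.d_g / self.d_ref


@dataclass(frozen=True)
class DlgFitResult:
    """Least-squares line through (gap, corrected ratio) and its DLG."""

    slope: float  # per mm
    intercept: float
    dlg: float  # mm; positive DLG <=> positive y-intercept
    r_squared: float
    n_points: int


def corrected_ratio(
    reading: SweepReading,
    t_layer: float,
    t_dual: float = 0.0,
    sweep_distance: float = 120.0,
) -> float:
    """Dose ratio with the transmission dwell contribution removed.

    Parameters
    ----------
    t_layer
        Transmission of the swept layer (fraction).
    t_dual
        Transmission through both layers; defaults to 0 since it is below
        1e-4 for the stacked design.
    sweep_distance
        Sweep travel ``L`` in mm.
    """
    if not 0.0 <= t_dual <= t_layer < 1.0:
        raise ValueError("require 0 <= t_dual <= t_layer < 1")
    g, L = reading.gap, sweep_distance
    if g > L:
        raise ValueError(f"gap {g} mm exceeds sweep distance {L} mm")
    if reading.trailing is None:
        f_single = (L - g) / L
        f_dual = 0.0
    else:
        t = reading.trailing
        f_single = min(2.0 * t, L - g) / L
        f_dual = max(L - g - 2.0 * t, 0.0) / L
    return reading.ratio - t_layer * f_single - t_dual * f_dual


def fit_dlg(points: Sequence[tuple[float, float]]) -> DlgFitResult:
    """Ordinary least squares of corrected ratio on gap width.

    Exact (machine precision) on collinear input.  Raises on fewer than
    two distinct gaps or on a non-positive slope, which cannot arise from
    physical sweep data (more gap, more dose).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(np.unique(pts[:, 0])) < 2:
        raise ValueError("need readings at >= 2 distinct gap widths")
    g, y = pts[:, 0], pts[:, 1]
    slope, intercept = np.polyfit(g, y, 1)
    if slope <= 0.0:
        raise ValueError(f"non-physical fit: slope {slope:.3g} per mm is not > 0")
    resid = y - (slope * g + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - float((resid**2).sum()) / ss_tot
    return DlgFitResult(
        slope=float(slope),
        intercept=float(intercept),
        dlg=float(intercept / slope),
        r_squared=r2,
        n_points=len(g),
    )


def fit_readings(
    readings: Iterable[SweepReading],
    t_layer: float,
    t_dual: float = 0.0,
    sweep_distance: float = 120.0,
    correction: Callable[..., float] = corrected_ratio,
) -> DlgFitResult:
    """Correct a set of readings and fit their DLG in one step."""
    pts = [
        (r.gap, correction(r, t_layer, t_dual, sweep_distance)) for r in readings
    ]
    return fit_dlg(pts)


def readings_from_csv(path) -> list[SweepReading]:
    """Read sweep readings from a ``gap,trailing,d_g,d_ref[,layer]`` table.

    An empty ``trailing`` cell means a plain single-layer sweep (no
    trailing layer), which is distinct from ``trailing = 0``.
    """
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        t = row.get("trailing")
        trailing = None if pd.isna(t) else float(t)
        layer = None
        if "layer" in df.columns and not pd.isna(row["layer"]):
            layer = Layer(row["layer"])
        out.append(
            SweepReading(
                gap=float(row["gap"]),
                d_g=float(row["d_g"]),
                d_ref=float(row["d_ref"]),
                trailing=trailing,
                layer=layer,
            )
        )
    return out


def trailing_curve(
    fits: Mapping[float, DlgFitResult], tol: float = 1e-9
) -> pd.DataFrame:
    """Tabulate DLG versus trailing distance, flagging non-monotone drops.

    Physically the DLG is nondecreasing in the trailing distance (the tip
    pair approaches a single-layer edge as ``t`` grows), so a decrease
    between consecutive trailing distances is flagged for inspection.
    """
    if len(fits) < 2:
        raise ValueError("need fits at >= 2 trailing distances")
    ts = sorted(fits)
    dlgs = [fits[t].dlg for t in ts]
    flags = [False] + [dlgs[i] < dlgs[i - 1] - tol for i in range(1, len(ts))]
    return pd.DataFrame(
        {
            "trailing_mm": ts,
            "dlg_mm": dlgs,
            "slope_per_mm": [fits[t].slope for t in ts],
            "r_squared": [fits[t].r_squared for t in ts],
            "nonmonotonic": flags,
        }
    )
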