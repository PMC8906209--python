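"""Strip decomposition of the staggered dual layer and aperture statistics.

The two leaf layers interleave at half a leaf width, so the plan geometry
is analysed on 5 mm strips: each strip is covered by exactly one proximal
pair and (except for the two outermost strips) one distal pair.  Per strip
the *effective* gap is the intersection of the two layers' pair gaps, and
per bank the *trailing distance* ``t`` is the offset between the two
layers' same-side tips; the layer whose tip is innermost defines the field
edge while the other trails behind it.  Small trailing distances make the
tip pair behave like a mono-block edge, which is why these statistics
matter for leaf-tip dose modelling.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .plan import ControlPoint, DualLayerPlan, Layer, MlcLayerSpec

__all__ = [
    "Strip",
    "StripAperture",
    "TrailingClass",
    "GapTrailingStats",
    "build_strips",
    "strip_apertures",
    "plan_gap_trailing_stats",
]

#: saturation boundary between "short" and "long" trailing, mm
TRAILING_SPLIT_MM = 5.0
#: positions are snapped to this grid before class comparisons, mm
CLASS_ROUND_MM = 0.01


@dataclass(frozen=True)
class Strip:
    """A 5 mm analysis strip: its extent and the leaf pairs covering it."""

    strip_index: int
    y_low: float
    y_high: float
    prox_pair: int
    dist_pair: int | None  # None for the two outermost, proximal-only strips


class TrailingClass(str, Enum):
    """Exhaustive classification of one bank edge of an open strip."""

    PROX_DEFINING_SHORT = "proximal_defining_t_lt_5"
    PROX_DEFINING_LONG = "proximal_defining_t_ge_5"
    DIST_DEFINING_SHORT = "distal_defining_t_lt_5"
    DIST_DEFINING_LONG = "distal_defining_t_ge_5"
    OVERLAP = "complete_overlap_t_eq_0"


@dataclass(frozen=True)
class StripAperture:
    """Per-strip aperture of one control point.

    ``defining`` / ``trailing`` are per-bank ``(bank_a, bank_b)`` tuples;
    ``defining`` entries are a :class:`Layer` or ``None`` for a tie
    (``t == 0``).  Proximal-only strips have ``has_distal=False`` and no
    trailing classification.
    """

    strip_index: int
    effective_gap: float
    prox_tips: tuple[float, float]
    dist_tips: tuple[float, float] | None
    trailing: tuple[float, float] | None
    defining: tuple[Layer | None, Layer | None] | None

    @property
    def has_distal(self) -> bool:
        return self.dist_tips is not None

    @property
    def is_open(self) -> bool:
        return self.effective_gap > 0.0


def build_strips(
    prox_spec: MlcLayerSpec, dist_spec: MlcLayerSpec
) -> list[Strip]:
    """Tile the proximal extent into half-leaf-width strips.

    For the stock geometry (29 pairs over 290 mm, 28 pairs over 280 mm,
    half-pitch stagger) this yields 58 strips of 5 mm, 56 of which carry
    both layers.

    Raises
    ------
    ValueError
        If the declared stagger is not half a leaf width, or the centred
        placement of the two banks does not realize that stagger.
    """
    w = prox_spec.leaf_width_iso
    if dist_spec.leaf_width_iso != w:
        raise ValueError("layers must share a leaf width")
    if abs(dist_spec.lateral_offset - prox_spec.lateral_offset - w / 2.0) > 1e-9:
        raise ValueError(
            f"distal layer must be staggered by half a leaf width "
            f"({w / 2.0} mm), declared offset is {dist_spec.lateral_offset} mm"
        )
    prox_edges = prox_spec.pair_edges()
    dist_edges = dist_spec.pair_edges()
    realized = (prox_edges[0] - dist_edges[0]) % w
    if abs(realized - w / 2.0) > 1e-9:
        raise ValueError(
            f"realized boundary stagger {realized} mm is not half-pitch"
        )
    h = w / 2.0
    n_strips = 2 * prox_spec.n_pairs
    strips: list[Strip] = []
    dist_lo, dist_hi = dist_edges[0], dist_edges[-1]
    for k in range(n_strips):
        y_low = prox_edges[0] + k * h
        y_mid = y_low + h / 2.0
        prox_pair = k // 2
        if dist_lo - 1e-9 < y_mid < dist_hi + 1e-9:
            dist_pair = int((y_mid - dist_lo) // w)
        else:
            dist_pair = None
        strips.append(Strip(k, y_low, y_low + h, prox_pair, dist_pair))
    return strips


def _snap100(x: float) -> int:
    """Position in integer hundredths of a millimetre."""
    return round(x / CLASS_ROUND_MM)


def strip_apertures(cp: ControlPoint, strips: list[Strip]) -> list[StripAperture]:
    """Effective gap, trailing distances and defining layers per strip.

    Positions are snapped to a 0.01 mm grid and differenced in integer
    hundredths, so serialization round-trips and float rounding cannot
    flip a tie into a one-ulp trailing distance or move a distance across
    the 5 mm class boundary.
    """
    pa, pb = cp.positions[Layer.PROXIMAL]
    da, db = cp.positions[Layer.DISTAL]
    out: list[StripAperture] = []
    for s in strips:
        iap, ibp = _snap100(pa[s.prox_pair]), _snap100(pb[s.prox_pair])
        if s.dist_pair is None:
            gap = max(0, ibp - iap) / 100.0
            out.append(
                StripAperture(
                    s.strip_index, gap, (iap / 100.0, ibp / 100.0), None, None, None
                )
            )
            continue
        iad, ibd = _snap100(da[s.dist_pair]), _snap100(db[s.dist_pair])
        gap = max(0, min(ibp, ibd) - max(iap, iad)) / 100.0
        t_a, t_b = abs(iap - iad) / 100.0, abs(ibp - ibd) / 100.0

        def _defining(tip_p: int, tip_d: int, innermost_is_larger: bool):
            if tip_p == tip_d:
                return None
            if (tip_p > tip_d) == innermost_is_larger:
                return Layer.PROXIMAL
            return Layer.DISTAL

        out.append(
            StripAperture(
                s.strip_index,
                gap,
                (iap / 100.0, ibp / 100.0),
                (iad / 100.0, ibd / 100.0),
                (t_a, t_b),
                (_defining(iap, iad, True), _defining(ibp, ibd, False)),
            )
        )
    return out


def classify_edge(defining: Layer | None, t: float) -> TrailingClass:
    """Assign one bank edge to its trailing class (exhaustive partition)."""
    if defining is None or t == 0.0:
        return TrailingClass.OVERLAP
    short = t < TRAILING_SPLIT_MM
    if defining is Layer.PROXIMAL:
        return (
            TrailingClass.PROX_DEFINING_SHORT if short
            else TrailingClass.PROX_DEFINING_LONG
        )
    return (
        TrailingClass.DIST_DEFINING_SHORT if short
        else TrailingClass.DIST_DEFINING_LONG
    )


@dataclass(frozen=True)
class GapTrailingStats:
    """Gap-width percentiles and trailing-class percentages of a plan."""

    gap_median: float
    gap_p25: float
    gap_p75: float
    class_pct: dict[TrailingClass, float]
    n_gap_samples: int
    n_edge_samples: int

    def to_row(self) -> pd.Series:
        row = {
            "gap_median_mm": self.gap_median,
            "gap_p25_mm": self.gap_p25,
            "gap_p75_mm": self.gap_p75,
        }
        for cls in TrailingClass:
            row[f"pct_{cls.value}"] = self.class_pct[cls]
        row["n_gap_samples"] = self.n_gap_samples
        row["n_edge_samples"] = self.n_edge_samples
        return pd.Series(row)


def _weighted_percentiles(
    values: np.ndarray, weights: np.ndarray, qs: list[float]
) -> list[float]:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    # midpoint-of-mass positions; linear interpolation between them
    p = (cw - 0.5 * w) / cw[-1]
    return [float(np.interp(q / 100.0, p, v)) for q in qs]


def plan_gap_trailing_stats(
    plan: DualLayerPlan, weighting: str = "unweighted"
) -> GapTrailingStats:
    """Pool gap and trailing statistics over all control points of a plan.

    Sampling units: a (control point, strip) pair with a positive effective
    gap contributes one gap sample; each bank edge of an open dual-covered
    strip contributes one trailing-class sample.  Closed strips carry no
    aperture information and are excluded.  ``weighting="mu_weighted"``
    weights each control point by its meterset increment times the beam MU;
    the default weights every control point equally.
    """
    if weighting not in ("unweighted", "mu_weighted"):
        raise ValueError(f"unknown weighting '{weighting}'")
    gaps: list[float] = []
    gap_w: list[float] = []
    class_w: dict[TrailingClass, float] = {c: 0.0 for c in TrailingClass}
    n_edges = 0
    for beam in plan.beams:
        strips = build_strips(
            beam.layer_specs[Layer.PROXIMAL], beam.layer_specs[Layer.DISTAL]
        )
        incr = beam.meterset_increments()
        for ci, cp in enumerate(beam.control_points):
            w_cp = 1.0 if weighting == "unweighted" else incr[ci] * beam.beam_mu
            if w_cp <= 0.0:
                continue
            for ap in strip_apertures(cp, strips):
                if not ap.is_open:
                    continue
                gaps.append(ap.effective_gap)
                gap_w.append(w_cp)
                if ap.has_distal:
                    for bank in (0, 1):
                        cls = classify_edge(ap.defining[bank], ap.trailing[bank])
                        class_w[cls] += w_cp
                        n_edges += 1
    if not gaps:
        raise ValueError("empty aperture: plan has no open strips")
    gaps_arr = np.asarray(gaps)
    w_arr = np.asarray(gap_w)
    if weighting == "unweighted":
        p25, p50, p75 = np.percentile(gaps_arr, [25, 50, 75])
    else:
        p25, p50, p75 = _weighted_percentiles(gaps_arr, w_arr, [25, 50, 75])
    total_w = sum(class_w.values())
    if total_w > 0:
        pct = {c: 100.0 * v / total_w for c, v in class_w.items()}
    else:
        pct = {c: 0.0 for c in class_w}
    return GapTrailingStats(
        gap_median=float(p50),
        gap_p25=float(p25),
        gap_p75=float(p75),
        class_pct=pct,
        n_gap_samples=len(gaps),
        n_edge_samples=n_edges,
    )
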