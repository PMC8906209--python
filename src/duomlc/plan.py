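"""Domain model for stacked-and-staggered dual-layer MLC treatment plans.

The dual-layer collimator carries 29 upper ("proximal") leaf pairs and 28
lower ("distal") pairs, each projecting to 10 mm width at the isocenter
plane, with the distal bank offset by half a leaf width so that the two
layers interleave to an effective 5 mm resolution.  Leaf positions are
expressed in signed millimetres along the leaf-travel axis at isocenter:
bank A tips approach from the negative side, bank B from the positive side,
and the geometric pair gap is ``x_B - x_A``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import numpy as np

__all__ = [
    "Layer",
    "MlcLayerSpec",
    "ControlPoint",
    "Beam",
    "DualLayerPlan",
    "PlanIssue",
    "validate_plan",
    "round_position",
    "PROXIMAL_SPEC",
    "DISTAL_SPEC",
    "default_layer_specs",
]


class Layer(str, Enum):
    """Identifier of an MLC layer in the dual-layer stack."""

    PROXIMAL = "proximal"
    DISTAL = "distal"

    def other(self) -> "Layer":
        return Layer.DISTAL if self is Layer.PROXIMAL else Layer.PROXIMAL


@dataclass(frozen=True)
class MlcLayerSpec:
    """Static geometry of one MLC layer.

    Parameters
    ----------
    layer_id
        Which layer of the stack this describes.
    n_pairs
        Number of opposed leaf pairs (29 proximal, 28 distal).
    leaf_width_iso
        Leaf width projected to the isocenter plane, mm.
    lateral_offset
        Shift of the leaf bank along the leaf-width axis relative to the
        proximal bank, mm.  The distal layer sits at half a leaf width.
    travel_min, travel_max
        Mechanical travel limits of a leaf tip, mm at isocenter.
    transmission
        Average inter/intra-leaf transmission of the layer (fraction).
    max_speed
        Maximum leaf speed, mm/s.
    """

    layer_id: Layer
    n_pairs: int
    leaf_width_iso: float = 10.0
    lateral_offset: float = 0.0
    travel_min: float = -140.0
    travel_max: float = 140.0
    transmission: float = 0.004
    max_speed: float = 50.0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if not self.travel_min < self.travel_max:
            raise ValueError("travel_min must be < travel_max")
        if not 0.0 <= self.transmission < 1.0:
            raise ValueError("transmission must be in [0, 1)")
        if self.leaf_width_iso <= 0:
            raise ValueError("leaf_width_iso must be > 0")

    @property
    def extent(self) -> float:
        """Total span of the leaf bank along the leaf-width axis, mm."""
        return self.n_pairs * self.leaf_width_iso

    def pair_edges(self) -> np.ndarray:
        """Leaf-pair boundary coordinates along the width axis.

        Both layers are centred on the axis; with 29 vs 28 pairs of equal
        width this places the distal boundaries half a pitch off the
        proximal ones.  ``lateral_offset`` declares that stagger and is
        validated by the strip-decomposition routines.
        """
        half = self.extent / 2.0
        return -half + self.leaf_width_iso * np.arange(self.n_pairs + 1)


PROXIMAL_SPEC = MlcLayerSpec(layer_id=Layer.PROXIMAL, n_pairs=29, lateral_offset=0.0)
DISTAL_SPEC = MlcLayerSpec(layer_id=Layer.DISTAL, n_pairs=28, lateral_offset=5.0)


def default_layer_specs() -> dict[Layer, MlcLayerSpec]:
    """Layer specifications of the stock dual-layer collimator."""
    return {Layer.PROXIMAL: PROXIMAL_SPEC, Layer.DISTAL: DISTAL_SPEC}


@dataclass
class ControlPoint:
    """One plan sample: gantry angle, meterset fraction and leaf positions.

    ``positions`` maps each layer to a pair of float arrays ``(x_a, x_b)``
    holding the bank-A and bank-B tip coordinates (mm at isocenter) of every
    leaf pair of that layer.  A closed pair is represented by ``x_a == x_b``.
    """

    index: int
    cumulative_meterset_weight: float
    gantry_angle: float
    positions: dict[Layer, tuple[np.ndarray, np.ndarray]]

    def copy(self) -> "ControlPoint":
        return ControlPoint(
            index=self.index,
            cumulative_meterset_weight=self.cumulative_meterset_weight,
            gantry_angle=self.gantry_angle,
            positions={
                layer: (xa.copy(), xb.copy())
                for layer, (xa, xb) in self.positions.items()
            },
        )


@dataclass
class Beam:
    """A single arc/beam: monitor units plus its control-point sequence."""

    beam_mu: float
    control_points: list[ControlPoint]
    layer_specs: dict[Layer, MlcLayerSpec] = field(default_factory=default_layer_specs)
    name: str = ""

    def meterset_increments(self) -> np.ndarray:
        """Per-control-point meterset weight, midpoint rule at the ends.

        Control point ``i`` is weighted by half the meterset delivered over
        its two adjacent segments, so the increments sum to 1 for a valid
        beam (cumulative weights running 0 → 1).
        """
        w = np.array([cp.cumulative_meterset_weight for cp in self.control_points])
        padded = np.concatenate([[w[0]], w, [w[-1]]])
        return (padded[2:] - padded[:-2]) / 2.0


@dataclass
class DualLayerPlan:
    """A treatment plan delivered through both MLC layers."""

    beams: list[Beam]
    metadata: dict = field(default_factory=dict)

    def copy(self) -> "DualLayerPlan":
        return DualLayerPlan(
            beams=[
                Beam(
                    beam_mu=b.beam_mu,
                    control_points=[cp.copy() for cp in b.control_points],
                    layer_specs=dict(b.layer_specs),
                    name=b.name,
                )
                for b in self.beams
            ],
            metadata=dict(self.metadata),
        )


@dataclass(frozen=True)
class PlanIssue:
    """A single validation finding, locating beam / control point / pair."""

    beam: int
    control_point: int | None
    layer: Layer | None
    pair: int | None
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        loc = f"beam {self.beam}"
        if self.control_point is not None:
            loc += f", cp {self.control_point}"
        if self.layer is not None:
            loc += f", {self.layer.value}"
        if self.pair is not None:
            loc += f", pair {self.pair}"
        return f"{loc}: {self.message}"


_POSITION_TOL = 1e-9


def validate_plan(plan: DualLayerPlan) -> list[PlanIssue]:
    """Check every structural invariant of a plan; empty list means valid.

    Checks, per beam: both layer specs present with matching pair counts,
    at least two control points, cumulative meterset weights nondecreasing
    and spanning [0, 1], tips ordered (``x_a <= x_b``) and within travel.
    """
    issues: list[PlanIssue] = []
    for bi, beam in enumerate(plan.beams):
        for layer in (Layer.PROXIMAL, Layer.DISTAL):
            if layer not in beam.layer_specs:
                issues.append(PlanIssue(bi, None, layer, None, "missing layer spec"))
        if len(beam.control_points) < 2:
            issues.append(PlanIssue(bi, None, None, None, "fewer than 2 control points"))
            continue
        w = [cp.cumulative_meterset_weight for cp in beam.control_points]
        if abs(w[0]) > _POSITION_TOL:
            issues.append(PlanIssue(bi, 0, None, None, "first meterset weight not 0"))
        if abs(w[-1] - 1.0) > _POSITION_TOL:
            issues.append(
                PlanIssue(bi, len(w) - 1, None, None, "last meterset weight not 1")
            )
        for ci in range(1, len(w)):
            if w[ci] < w[ci - 1] - _POSITION_TOL:
                issues.append(
                    PlanIssue(bi, ci, None, None, "cumulative meterset weight decreases")
                )
        for ci, cp in enumerate(beam.control_points):
            for layer, spec in beam.layer_specs.items():
                if layer not in cp.positions:
                    issues.append(PlanIssue(bi, ci, layer, None, "missing positions"))
                    continue
                xa, xb = cp.positions[layer]
                if len(xa) != spec.n_pairs or len(xb) != spec.n_pairs:
                    issues.append(
                        PlanIssue(
                            bi, ci, layer, None,
                            f"expected {spec.n_pairs} pairs, got {len(xa)}/{len(xb)}",
                        )
                    )
                    continue
                bad_order = np.nonzero(xa > xb + _POSITION_TOL)[0]
                for pi in bad_order:
                    issues.append(
                        PlanIssue(bi, ci, layer, int(pi), "bank A tip beyond bank B tip")
                    )
                out = np.nonzero(
                    (xa < spec.travel_min - _POSITION_TOL)
                    | (xb > spec.travel_max + _POSITION_TOL)
                )[0]
                for pi in out:
                    issues.append(
                        PlanIssue(bi, ci, layer, int(pi), "tip outside travel range")
                    )
    return issues


def round_position(x: float) -> float:
    """Round a leaf position to the nearest 0.1 mm, half-up (toward +inf).

    This is the serialization resolution of the planning system: stored
    positions carry one decimal, so in-memory edits stay exact and rounding
    happens once, on write.
    """
    return math.floor(x * 10.0 + 0.5) / 10.0


def round_positions(x: Iterable[float]) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) * 10.0 + 0.5) / 10.0
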