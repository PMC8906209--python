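"""Leaf-sequence editing operations.

Three editing families, all of which a planning system will not do for the
user and therefore have to happen on the exported plan:

* ``to_single_layer`` — collapse a dual-layer sequence so that one layer
  alone defines the aperture while the other tracks it a fixed distance
  behind the tips (jaw-tracking style), removing the leaf-trailing effect.
* ``apply_leaf_opening`` / ``opening_for_dlg`` — open every pair of a layer
  symmetrically by a per-bank delta, which emulates entering a larger
  dosimetric leaf gap (DLG) in the dose calculation: opening each bank by
  ``(target_dlg - base_dlg)/2`` realizes ``target_dlg``.
* ``make_sweep_plan`` — constant-speed sweeping-gap sequences, optionally
  with the second layer trailing at a fixed distance ``t``, used to measure
  the DLG and its trailing dependence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .plan import (
    Beam,
    ControlPoint,
    DualLayerPlan,
    Layer,
    MlcLayerSpec,
    default_layer_specs,
)

__all__ = [
    "to_single_layer",
    "apply_leaf_opening",
    "opening_for_dlg",
    "SweepSpec",
    "make_sweep_plan",
]

#: resolution of the serialized leaf positions; openings must sit on it, mm
SERIALIZATION_GRID_MM = 0.1


def _overlap_map(
    track_spec: MlcLayerSpec, def_spec: MlcLayerSpec
) -> list[list[int]]:
    """For each tracking pair, the defining pairs it overlaps laterally."""
    te = track_spec.pair_edges()
    de = def_spec.pair_edges()
    out: list[list[int]] = []
    for i in range(track_spec.n_pairs):
        lo, hi = te[i], te[i + 1]
        js = [
            j
            for j in range(def_spec.n_pairs)
            if min(hi, de[j + 1]) - max(lo, de[j]) > 1e-9
        ]
        out.append(js)
    return out


def to_single_layer(
    plan: DualLayerPlan, defining_layer: Layer, retraction: float = 5.0
) -> DualLayerPlan:
    """Convert a dual-layer sequence into a single-layer one.

    The defining layer is left untouched; every pair of the other layer is
    retracted ``retraction`` mm beyond the outermost tips of the defining
    pairs it overlaps, so the tracking layer never encroaches on the
    defining aperture (clamped to travel limits where necessary).  The
    per-strip effective aperture then equals the defining layer's aperture
    wherever clamping did not bind, and every open edge trails by at least
    ``retraction``.

    The operation is idempotent for a fixed defining layer.
    """
    if retraction <= 0.0:
        raise ValueError("retraction must be > 0 mm")
    out = plan.copy()
    for beam in out.beams:
        if defining_layer not in beam.layer_specs:
            raise ValueError(f"plan has no {defining_layer.value} layer")
        track = defining_layer.other()
        omap = _overlap_map(beam.layer_specs[track], beam.layer_specs[defining_layer])
        tspec = beam.layer_specs[track]
        for cp in beam.control_points:
            da, db = cp.positions[defining_layer]
            ta, tb = cp.positions[track]
            for i, js in enumerate(omap):
                ta[i] = max(tspec.travel_min, min(da[j] for j in js) - retraction)
                tb[i] = min(tspec.travel_max, max(db[j] for j in js) + retraction)
    out.metadata = dict(out.metadata)
    out.metadata["sequence"] = f"{defining_layer.value}_single_layer"
    return out


def apply_leaf_opening(
    plan: DualLayerPlan,
    delta: float,
    layers: set[Layer] | None = None,
    mode: str = "all_pairs",
) -> DualLayerPlan:
    """Open leaf pairs symmetrically by ``delta`` mm per bank.

    Each affected pair moves ``x_A -> x_A - delta`` and ``x_B -> x_B +
    delta`` (gap grows by ``2*delta``), clamped to the travel limits with a
    warning when clamping binds.  Meterset weights and MU are unchanged —
    the edit simulates a dose recalculation with a larger DLG, not a
    different delivery.

    ``mode="all_pairs"`` (default) opens every pair, including closed ones,
    which is what the tuning procedure does; ``mode="open_only"`` skips
    pairs whose gap is at most 0.1 mm, avoiding leakage slits through
    parked pairs.
    """
    if delta < 0.0:
        raise ValueError("delta must be >= 0")
    if mode not in ("all_pairs", "open_only"):
        raise ValueError(f"unknown mode '{mode}'")
    if layers is None:
        layers = {Layer.PROXIMAL, Layer.DISTAL}
    out = plan.copy()
    if delta == 0.0:
        return out
    clamped = 0
    for beam in out.beams:
        for cp in beam.control_points:
            for layer in layers:
                spec = beam.layer_specs[layer]
                xa, xb = cp.positions[layer]
                if mode == "open_only":
                    sel = (xb - xa) > SERIALIZATION_GRID_MM
                else:
                    sel = np.ones_like(xa, dtype=bool)
                na = xa[sel] - delta
                nb = xb[sel] + delta
                clamped += int((na < spec.travel_min).sum())
                clamped += int((nb > spec.travel_max).sum())
                xa[sel] = np.maximum(na, spec.travel_min)
                xb[sel] = np.minimum(nb, spec.travel_max)
    if clamped:
        warnings.warn(
            f"leaf opening clamped at travel limits for {clamped} bank position(s)",
            stacklevel=2,
        )
    return out


def opening_for_dlg(target_dlg: float, base_dlg: float = 0.1) -> float:
    """Per-bank opening that realizes ``target_dlg`` on top of ``base_dlg``.

    The opening is ``(target_dlg - base_dlg) / 2``; because serialized
    positions carry one decimal, the opening must sit on the 0.1 mm grid,
    i.e. only targets on the ``base + 0.2k`` grid are assignable.
    """
    if target_dlg < base_dlg:
        raise ValueError("target_dlg must be >= base_dlg")
    delta = (target_dlg - base_dlg) / 2.0
    steps = delta / SERIALIZATION_GRID_MM
    if abs(steps - round(steps)) > 1e-6:
        raise ValueError(
            f"target DLG {target_dlg} mm is not assignable: openings must lie "
            f"on the 0.1 mm position grid, so targets are limited to the "
            f"{base_dlg} + 0.2k mm grid"
        )
    return round(steps) * SERIALIZATION_GRID_MM


@dataclass(frozen=True)
class SweepSpec:
    """Parameters of a sweeping-gap sequence.

    A gap of width ``gap`` travels ``sweep_distance`` mm at constant speed
    symmetrically about the axis inside a square field; optionally the
    other layer trails the leading one at a fixed distance
    ``trailing_distance`` on both banks (its pair gap is ``gap + 2t``).
    """

    gap: float
    sweep_distance: float = 120.0
    leaf_speed: float = 5.0
    leading_layer: Layer = Layer.PROXIMAL
    trailing_layer: Layer | None = None
    trailing_distance: float = 0.0
    field_size: float = 100.0
    n_control_points: int | None = None

    def __post_init__(self) -> None:
        if self.gap <= 0.0:
            raise ValueError("gap must be > 0")
        if self.sweep_distance <= 0.0:
            raise ValueError("sweep_distance must be > 0")
        if self.trailing_distance < 0.0:
            raise ValueError("trailing_distance must be >= 0")
        if (
            self.trailing_layer is not None
            and self.trailing_layer is self.leading_layer
        ):
            raise ValueError("trailing layer must differ from leading layer")

    @property
    def cp_count(self) -> int:
        """Default: one control point per 5 mm of travel, plus the start."""
        if self.n_control_points is not None:
            return self.n_control_points
        return int(round(self.sweep_distance / 5.0)) + 1


def make_sweep_plan(
    spec: SweepSpec, layer_specs: dict[Layer, MlcLayerSpec] | None = None
) -> DualLayerPlan:
    """Build the sweeping-gap (optionally trailing) leaf sequence.

    The gap centre runs from ``-L/2`` to ``+L/2`` with cumulative meterset
    weight linear in tip displacement (constant leaf speed).  Only pairs
    inside the square field participate; other pairs are parked closed.
    With no trailing layer the second layer is fully retracted.
    """
    specs = layer_specs if layer_specs is not None else default_layer_specs()
    lead_spec = specs[spec.leading_layer]
    g, L, t = spec.gap, spec.sweep_distance, spec.trailing_distance
    outer = L / 2.0 + g / 2.0 + (t if spec.trailing_layer is not None else 0.0)
    for s in specs.values():
        if outer > s.travel_max + 1e-9 or -outer < s.travel_min - 1e-9:
            raise ValueError(
                f"sweep of gap {g} mm with trailing {t} mm exceeds the "
                f"leaf travel range"
            )
    n = spec.cp_count
    centers = np.linspace(-L / 2.0, L / 2.0, n)
    weights = np.linspace(0.0, 1.0, n)
    half_field = spec.field_size / 2.0
    in_field: dict[Layer, np.ndarray] = {}
    for layer, s in specs.items():
        edges = s.pair_edges()
        mids = (edges[:-1] + edges[1:]) / 2.0
        in_field[layer] = np.abs(mids) < half_field

    cps = []
    for i in range(n):
        positions = {}
        for layer, s in specs.items():
            park = -100.0  # closed pairs sit well off-axis
            xa = np.full(s.n_pairs, park)
            xb = np.full(s.n_pairs, park)
            sel = in_field[layer]
            if layer is spec.leading_layer:
                xa[sel] = centers[i] - g / 2.0
                xb[sel] = centers[i] + g / 2.0
            elif layer is spec.trailing_layer:
                xa[sel] = centers[i] - g / 2.0 - t
                xb[sel] = centers[i] + g / 2.0 + t
            else:  # fully retracted
                xa[:] = s.travel_min
                xb[:] = s.travel_max
            positions[layer] = (xa, xb)
        cps.append(
            ControlPoint(
                index=i,
                cumulative_meterset_weight=float(weights[i]),
                gantry_angle=0.0,
                positions=positions,
            )
        )
    mu = 100.0 * (L / spec.leaf_speed) / 60.0  # nominal MU at constant speed
    beam = Beam(beam_mu=mu, control_points=cps, layer_specs=dict(specs), name="sweep")
    meta = {
        "sequence": "sweep",
        "gap_mm": g,
        "trailing_mm": t if spec.trailing_layer is not None else None,
        "leading_layer": spec.leading_layer.value,
    }
    return DualLayerPlan(beams=[beam], metadata=meta)
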