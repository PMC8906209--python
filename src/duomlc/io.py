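"""Plan serialization.

Plans are stored as JSON documents that mirror the RT-plan hierarchy
(beams → control points → per-layer beam-limiting-device positions).  On
write every leaf position is rounded to the nearest 0.1 mm (half-up), the
resolution at which the planning system stores positional information; all
other fields are preserved exactly.  Layers are identified on read by pair
count (29 → proximal, 28 → distal), falling back to the stored layer label;
files where neither disambiguates are rejected.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import IO

import numpy as np

from .plan import (
    Beam,
    ControlPoint,
    DualLayerPlan,
    Layer,
    MlcLayerSpec,
    round_positions,
    validate_plan,
)

__all__ = ["read_plan", "write_plan", "PlanFormatError", "PlanGeometryError"]

_FORMAT = "duomlc-rtplan"
_VERSION = 1


class PlanFormatError(ValueError):
    """The document is not a well-formed plan file."""


class PlanGeometryError(ValueError):
    """The stored geometry is inconsistent with a dual-layer MLC."""


def _spec_to_json(spec: MlcLayerSpec) -> dict:
    return {
        "layer_id": spec.layer_id.value,
        "n_pairs": spec.n_pairs,
        "leaf_width_iso": spec.leaf_width_iso,
        "lateral_offset": spec.lateral_offset,
        "travel_min": spec.travel_min,
        "travel_max": spec.travel_max,
        "transmission": spec.transmission,
        "max_speed": spec.max_speed,
    }


def _spec_from_json(d: dict) -> MlcLayerSpec:
    return MlcLayerSpec(
        layer_id=Layer(d["layer_id"]),
        n_pairs=int(d["n_pairs"]),
        leaf_width_iso=float(d["leaf_width_iso"]),
        lateral_offset=float(d["lateral_offset"]),
        travel_min=float(d["travel_min"]),
        travel_max=float(d["travel_max"]),
        transmission=float(d["transmission"]),
        max_speed=float(d["max_speed"]),
    )


def write_plan(plan: DualLayerPlan, dest: str | Path | IO[str]) -> None:
    """Serialize a plan, rounding leaf positions to the 0.1 mm grid.

    Raises
    ------
    PlanGeometryError
        If any rounded position falls outside its layer's travel range
        (rounding is applied first; a position that rounds onto the limit
        is accepted).
    """
    doc: dict = {"format": _FORMAT, "version": _VERSION, "metadata": plan.metadata}
    beams = []
    for bi, beam in enumerate(plan.beams):
        cps = []
        for cp in beam.control_points:
            positions = {}
            for layer, (xa, xb) in cp.positions.items():
                spec = beam.layer_specs[layer]
                ra, rb = round_positions(xa), round_positions(xb)
                if (ra < spec.travel_min - 1e-9).any() or (
                    rb > spec.travel_max + 1e-9
                ).any():
                    raise PlanGeometryError(
                        f"beam {bi}, cp {cp.index}, layer {layer.value}: "
                        "rounded position exceeds travel range"
                    )
                positions[layer.value] = {
                    "bank_a": [float(v) for v in ra],
                    "bank_b": [float(v) for v in rb],
                }
            cps.append(
                {
                    "index": cp.index,
                    "cumulative_meterset_weight": cp.cumulative_meterset_weight,
                    "gantry_angle": cp.gantry_angle,
                    "positions": positions,
                }
            )
        beams.append(
            {
                "name": beam.name,
                "beam_mu": beam.beam_mu,
                "layer_specs": [_spec_to_json(s) for s in beam.layer_specs.values()],
                "control_points": cps,
            }
        )
    doc["beams"] = beams
    if hasattr(dest, "write"):
        json.dump(doc, dest, indent=1)
    else:
        Path(dest).write_text(json.dumps(doc, indent=1))


def _identify_layers(spec_docs: list[dict]) -> dict[Layer, MlcLayerSpec]:
    """Map stored layer specs to proximal/distal by pair count, then label."""
    if len(spec_docs) < 2:
        raise PlanGeometryError(
            "single-layer plan: a second MLC layer is required"
        )
    if len(spec_docs) > 2:
        raise PlanGeometryError(f"expected 2 MLC layers, found {len(spec_docs)}")
    counts = [int(d["n_pairs"]) for d in spec_docs]
    if counts[0] == counts[1]:
        raise PlanGeometryError(
            f"ambiguous layer identification: both layers carry {counts[0]} "
            "pairs; the stacked design has one more proximal pair"
        )
    if sorted(counts) == [28, 29]:
        assignment = {
            Layer.PROXIMAL: spec_docs[counts.index(29)],
            Layer.DISTAL: spec_docs[counts.index(28)],
        }
    else:
        # nonstandard geometry: the staggered stack always has one more
        # proximal pair; reject if the stored labels say otherwise
        prox_doc = spec_docs[counts.index(max(counts))]
        dist_doc = spec_docs[counts.index(min(counts))]
        labels = (prox_doc.get("layer_id"), dist_doc.get("layer_id"))
        if labels not in ((None, None), ("proximal", "distal")):
            raise PlanGeometryError(
                f"layer labels {labels} contradict pair counts {counts}"
            )
        assignment = {Layer.PROXIMAL: prox_doc, Layer.DISTAL: dist_doc}
    specs = {}
    for layer, doc in assignment.items():
        doc = dict(doc)
        doc["layer_id"] = layer.value
        specs[layer] = _spec_from_json(doc)
    return specs


def read_plan(source: str | Path | IO[str]) -> DualLayerPlan:
    """Read a plan file, validating geometry and meterset monotonicity."""
    if hasattr(source, "read"):
        doc = json.load(source)
    else:
        doc = json.loads(Path(source).read_text())
    if doc.get("format") != _FORMAT:
        raise PlanFormatError("not a dual-layer MLC plan document")
    beams = []
    for bdoc in doc["beams"]:
        specs = _identify_layers(bdoc["layer_specs"])
        cps = []
        for cdoc in bdoc["control_points"]:
            positions: dict[Layer, tuple[np.ndarray, np.ndarray]] = {}
            stored = cdoc["positions"]
            for layer, spec in specs.items():
                key = layer.value
                if key not in stored:
                    # positions keyed by stored label order; re-key by count
                    raise PlanFormatError(f"control point missing layer '{key}'")
                xa = np.asarray(stored[key]["bank_a"], dtype=float)
                xb = np.asarray(stored[key]["bank_b"], dtype=float)
                if len(xa) != spec.n_pairs or len(xb) != spec.n_pairs:
                    raise PlanGeometryError(
                        f"layer '{key}': expected {spec.n_pairs} pairs, "
                        f"got {len(xa)}/{len(xb)}"
                    )
                positions[layer] = (xa, xb)
            cps.append(
                ControlPoint(
                    index=int(cdoc["index"]),
                    cumulative_meterset_weight=float(
                        cdoc["cumulative_meterset_weight"]
                    ),
                    gantry_angle=float(cdoc["gantry_angle"]),
                    positions=positions,
                )
            )
        beams.append(
            Beam(
                beam_mu=float(bdoc["beam_mu"]),
                control_points=cps,
                layer_specs=specs,
                name=bdoc.get("name", ""),
            )
        )
    plan = DualLayerPlan(beams=beams, metadata=dict(doc.get("metadata", {})))
    issues = validate_plan(plan)
    monotonicity = [i for i in issues if "meterset" in i.message]
    if monotonicity:
        raise PlanFormatError(f"invalid meterset weights: {monotonicity[0]}")
    order = [i for i in issues if "bank A tip" in i.message]
    if order:
        raise PlanGeometryError(str(order[0]))
    return plan
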