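"""End-to-end synthetic QA study.

Reproduces the full workflow on generated data: analyse dual-layer
apertures, convert to single-layer sequences, verify baseline dose
calculations against simulated measurements, tune the DLG per layer and
target class on the single-layer sequences, and re-verify the dual-layer
plans with the assigned DLG.  Everything is driven by a
:class:`StudyConfig` and a single seed, and the report is reproducible
bit-for-bit from the pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .aperture import GapTrailingStats, plan_gap_trailing_stats
from .editing import apply_leaf_opening, to_single_layer
from .plan import DualLayerPlan, Layer
from .synthetic import (
    DetectorGeometry,
    DoseField,
    TipModel,
    compute_fluence_field,
    delta4_detector_points,
    study_tip_model,
)
from .tuning import TuningResult, tune_dlg
from .verification import DoseDistribution, VerificationResult, gamma_global
from . import verification as _verification

__all__ = ["StudyConfig", "StudyReport", "run_study", "verify_against_field"]


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of the synthetic study.

    Defaults are a desk-scale version of a clinical tuning campaign:
    4 small-target and 2 large-target three-arc plans at 60 control points
    per arc, a biplanar detector sampled at 2 mm in the central region,
    measurement noise of 0.5 % of the maximum dose (typical array
    repeatability), and the 0.1 / 0.5 / 0.9 / 1.3 mm DLG grid that per-bank
    openings of 0 / 0.2 / 0.4 / 0.6 mm realize on a 0.1 mm base.
    """

    n_small: int = 4
    n_large: int = 2
    n_arcs: int = 3
    n_cp_per_arc: int = 60
    tip_model: TipModel = field(default_factory=study_tip_model)
    base_dlg: float = 0.1
    dlg_grid: tuple[float, ...] = (0.1, 0.5, 0.9, 1.3)
    noise_sd_pct: float = 0.5
    detector: DetectorGeometry = field(
        default_factory=lambda: DetectorGeometry(
            spacing_central=2.0,
            spacing_outer=6.0,
            central_extent=80.0,
            extent=168.0,
        )
    )
    dose_pct: float = 2.0
    dta_mm: float = 2.0
    threshold_pct: float = 10.0
    apply_class: str = "small"  # which class's tuned DLG the final pass uses

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "tip_model" in doc:
            tm = doc["tip_model"]
            if "dlg_single" in tm:
                tm["dlg_single"] = {Layer(k): v for k, v in tm["dlg_single"].items()}
            if "transmission" in tm:
                tm["transmission"] = {
                    Layer(k): v for k, v in tm["transmission"].items()
                }
            doc["tip_model"] = TipModel(**tm)
        if "detector" in doc:
            doc["detector"] = DetectorGeometry(**doc["detector"])
        if "dlg_grid" in doc:
            doc["dlg_grid"] = tuple(doc["dlg_grid"])
        return cls(**doc)


def _split_planes(points: np.ndarray, dose: np.ndarray):
    """Split a biplanar 3D cloud into per-plane 2D distributions."""
    coronal = np.abs(points[:, 2]) < 1e-9
    sagittal = ~coronal
    return (
        ("coronal", DoseDistribution.from_points(points[coronal][:, [0, 1]], dose[coronal])),
        ("sagittal", DoseDistribution.from_points(points[sagittal][:, [0, 2]], dose[sagittal])),
    )


def verify_against_field(
    measured_points: np.ndarray,
    measured_dose: np.ndarray,
    calc_field: DoseField,
    dose_pct: float = 2.0,
    dta_mm: float = 2.0,
    threshold_pct: float = 10.0,
    grid_step: float = 1.0,
) -> VerificationResult:
    """Verify a calculated dose field against a biplanar measured cloud.

    Each detector plane is compared in its own in-plane coordinates
    against a regular grid sampled from the field (with enough margin to
    cover every gamma search sphere); the per-point dose differences and
    gamma values of the two planes are pooled into one result.  Dose
    normalization (maximum measured dose and low-dose threshold) is global
    over the full cloud, as array-QA software does.
    """
    d_max = float(measured_dose.max())
    margin = 3.0 * dta_mm + grid_step
    half = float(np.abs(measured_points[:, :3]).max()) + margin
    axis = np.arange(-half, half + grid_step / 2, grid_step)
    parts = []
    for plane, ref in _split_planes(measured_points, measured_dose):
        evaluated = calc_field.plane_grid(plane, axis, axis)
        parts.append(
            gamma_global(
                ref,
                evaluated,
                dose_pct=dose_pct,
                dta_mm=dta_mm,
                threshold_pct=threshold_pct,
                norm_dose=d_max,
            )
        )
    dd = np.concatenate([p.per_point_dd for p in parts])
    gam = np.concatenate([p.per_point_gamma for p in parts])
    return VerificationResult(
        dd_mean=float(dd.mean()),
        dd_sd=_verification._sd(dd),
        gamma_mean=float(gam.mean()),
        gamma_sd=_verification._sd(gam),
        pass_rate=100.0 * float((gam <= 1.0).mean()),
        n_evaluated=len(gam),
        criteria=parts[0].criteria,
        per_point_dd=dd,
        per_point_gamma=gam,
    )


@dataclass
class StudyReport:
    """Everything the study computed, keyed by plan id / sequence / class."""

    seed: int
    config: StudyConfig
    plan_classes: dict[str, str]
    aperture_stats: dict[str, GapTrailingStats]
    baseline: dict[tuple[str, str], VerificationResult]  # (plan_id, sequence)
    tuning: dict[tuple[str, str], TuningResult]  # (class or "overall", layer)
    final: dict[str, VerificationResult]  # plan_id -> tuned dual verification
    assigned_dlg: dict[str, float]  # layer -> assigned DLG used in final pass
    true_dlg: dict[str, float]  # layer -> generating single-layer DLG

    def pooled_mean_dd(self, stage: str, sequence: str = "dual") -> float:
        """Unweighted mean over plans of the per-plan mean DD (%)."""
        if stage == "baseline":
            vals = [
                r.dd_mean for (pid, seq), r in self.baseline.items()
                if seq == sequence
            ]
        elif stage == "final":
            vals = [r.dd_mean for r in self.final.values()]
        else:
            raise ValueError(f"unknown stage '{stage}'")
        return float(np.mean(vals))

    def pooled_pass_rate(self, stage: str, sequence: str = "dual") -> float:
        if stage == "baseline":
            res = [r for (pid, seq), r in self.baseline.items() if seq == sequence]
        else:
            res = list(self.final.values())
        gam = np.concatenate([r.per_point_gamma for r in res])
        return 100.0 * float((gam <= 1.0).mean())

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for (pid, seq), r in self.baseline.items():
            rows.append(
                {
                    "plan": pid, "class": self.plan_classes[pid], "stage": "baseline",
                    "sequence": seq, "dd_mean": r.dd_mean, "dd_sd": r.dd_sd,
                    "gamma_mean": r.gamma_mean, "pass_rate": r.pass_rate,
                }
            )
        for pid, r in self.final.items():
            rows.append(
                {
                    "plan": pid, "class": self.plan_classes[pid], "stage": "tuned",
                    "sequence": "dual", "dd_mean": r.dd_mean, "dd_sd": r.dd_sd,
                    "gamma_mean": r.gamma_mean, "pass_rate": r.pass_rate,
                }
            )
        return pd.DataFrame(rows)


def run_study(config: StudyConfig | None = None, seed: int = 0) -> StudyReport:
    """Run the full analyse → convert → verify → tune → re-verify loop."""
    from .synthetic import generate_vmat_plan  # local import to avoid cycle

    cfg = config or StudyConfig()
    model = cfg.tip_model
    rng = np.random.default_rng(seed)
    pts = delta4_detector_points(cfg.detector)

    plans: list[tuple[str, str, DualLayerPlan]] = []
    for cls, count in (("small", cfg.n_small), ("large", cfg.n_large)):
        for i in range(count):
            pid = f"{cls}-{i + 1}"
            plan = generate_vmat_plan(
                cls,
                n_arcs=cfg.n_arcs,
                n_cp_per_arc=cfg.n_cp_per_arc,
                seed=int(rng.integers(2**31)),
            )
            plans.append((cls, pid, plan))

    sequences: dict[str, dict[str, DualLayerPlan]] = {}
    measured: dict[tuple[str, str], np.ndarray] = {}
    aperture_stats = {}
    baseline: dict[tuple[str, str], VerificationResult] = {}
    plan_classes = {}
    seq_layers = {"proximal": Layer.PROXIMAL, "distal": Layer.DISTAL}

    def measure(plan: DualLayerPlan) -> np.ndarray:
        fld = compute_fluence_field(plan, model, "measured")
        dose = fld.dose_at(pts)
        noise_seed = int(rng.integers(2**31))
        noise = np.random.default_rng(noise_seed).normal(
            0.0, cfg.noise_sd_pct / 100.0 * dose.max(), len(dose)
        )
        return np.maximum(dose + noise, 0.0)

    for cls, pid, plan in plans:
        plan_classes[pid] = cls
        aperture_stats[pid] = plan_gap_trailing_stats(plan)
        seqs = {
            "dual": plan,
            "proximal": to_single_layer(plan, Layer.PROXIMAL),
            "distal": to_single_layer(plan, Layer.DISTAL),
        }
        sequences[pid] = seqs
        for seq_name, seq_plan in seqs.items():
            measured[(pid, seq_name)] = measure(seq_plan)
            calc = compute_fluence_field(
                seq_plan, model, "tps", dlg_calc=cfg.base_dlg
            )
            baseline[(pid, seq_name)] = verify_against_field(
                pts, measured[(pid, seq_name)], calc,
                dose_pct=cfg.dose_pct, dta_mm=cfg.dta_mm,
                threshold_pct=cfg.threshold_pct,
            )

    def tps_engine(plan: DualLayerPlan) -> DoseDistribution:
        fld = compute_fluence_field(plan, model, "tps", dlg_calc=cfg.base_dlg)
        return DoseDistribution.from_points(pts, fld.dose_at(pts))

    tuning: dict[tuple[str, str], TuningResult] = {}
    for seq_name, layer in seq_layers.items():
        for scope in ("small", "large", "overall"):
            sel = [
                (pid, cls) for cls, pid, _ in plans
                if scope == "overall" or cls == scope
            ]
            if not sel:
                continue
            pool_plans = [sequences[pid][seq_name] for pid, _ in sel]
            pool_meas = [
                DoseDistribution.from_points(pts, measured[(pid, seq_name)])
                for pid, _ in sel
            ]
            tuning[(scope, seq_name)] = tune_dlg(
                pool_plans, pool_meas, cfg.dlg_grid, tps_engine,
                layers={layer}, base_dlg=cfg.base_dlg,
            )

    assigned = {
        "proximal": tuning[(cfg.apply_class, "proximal")].assigned_dlg,
        "distal": tuning[(cfg.apply_class, "distal")].assigned_dlg,
    }
    final: dict[str, VerificationResult] = {}
    for cls, pid, plan in plans:
        tuned = apply_leaf_opening(
            plan,
            tuning[(cfg.apply_class, "proximal")].per_bank_opening,
            layers={Layer.PROXIMAL},
        )
        tuned = apply_leaf_opening(
            tuned,
            tuning[(cfg.apply_class, "distal")].per_bank_opening,
            layers={Layer.DISTAL},
        )
        calc = compute_fluence_field(tuned, model, "tps", dlg_calc=cfg.base_dlg)
        final[pid] = verify_against_field(
            pts, measured[(pid, "dual")], calc,
            dose_pct=cfg.dose_pct, dta_mm=cfg.dta_mm,
            threshold_pct=cfg.threshold_pct,
        )

    return StudyReport(
        seed=seed,
        config=cfg,
        plan_classes=plan_classes,
        aperture_stats=aperture_stats,
        baseline=baseline,
        tuning=tuning,
        final=final,
        assigned_dlg=assigned,
        true_dlg={
            "proximal": model.dlg_single[Layer.PROXIMAL],
            "distal": model.dlg_single[Layer.DISTAL],
        },
    )
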