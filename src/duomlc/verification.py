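"""Measured-vs-calculated dose comparison: dose difference and global gamma.

Conventions (the ones used for array-based patient-specific QA):

* the *measured* distribution is the reference, the *calculated* one is
  evaluated against it;
* per-point dose difference ``DD_i = 100 * (D_calc,i - D_meas,i) /
  max(D_meas)`` — global normalization, so a negative mean means the
  calculation underestimates;
* the gamma index uses a global dose criterion (percent of the maximum
  measured dose) and a distance-to-agreement criterion, with points below
  a low-dose threshold (fraction of the measured maximum) excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "DoseDistribution",
    "DoseDifference",
    "VerificationResult",
    "mean_dose_difference",
    "gamma_global",
    "pooled_histogram",
]


class DoseDistribution:
    """Dose values on a regular grid or at scattered points.

    Grid distributions (1-3 spatial dimensions) support interpolation and
    can serve as the evaluated distribution of a gamma comparison; point
    clouds (detector arrays) are typically the reference.
    """

    def __init__(
        self,
        points: np.ndarray,
        dose: np.ndarray,
        axes: tuple[np.ndarray, ...] | None = None,
        values: np.ndarray | None = None,
    ):
        self.points = np.atleast_2d(np.asarray(points, dtype=float))
        self.dose = np.asarray(dose, dtype=float)
        if (self.dose < 0).any():
            raise ValueError("dose must be nonnegative")
        if len(self.dose) != len(self.points):
            raise ValueError("points and dose lengths differ")
        self.axes = axes
        self.values = values
        self.d_max = float(self.dose.max())

    @property
    def kind(self) -> str:
        return "grid" if self.axes is not None else "cloud"

    @property
    def ndim_space(self) -> int:
        return self.points.shape[1]

    @classmethod
    def from_points(cls, points: np.ndarray, dose: np.ndarray) -> "DoseDistribution":
        return cls(points, dose)

    @classmethod
    def from_grid(
        cls, axes: tuple[np.ndarray, ...], values: np.ndarray
    ) -> "DoseDistribution":
        axes = tuple(np.asarray(a, dtype=float) for a in axes)
        values = np.asarray(values, dtype=float)
        if values.shape != tuple(len(a) for a in axes):
            raise ValueError("values shape does not match axes")
        for a in axes:
            if len(a) > 1 and not (np.diff(a) > 0).all():
                raise ValueError("grid axes must be strictly increasing")
        mesh = np.meshgrid(*axes, indexing="ij")
        points = np.stack([m.ravel() for m in mesh], axis=1)
        return cls(points, values.ravel(), axes=axes, values=values)

    @classmethod
    def from_csv(cls, path) -> "DoseDistribution":
        """Read an ``x[,y[,z]],dose`` table (plain text, header row)."""
        df = pd.read_csv(path)
        cols = [c for c in ("x", "y", "z") if c in df.columns]
        return cls.from_points(df[cols].to_numpy(), df["dose"].to_numpy())

    def to_csv(self, path) -> None:
        cols = ["x", "y", "z"][: self.ndim_space]
        df = pd.DataFrame(self.points, columns=cols)
        df["dose"] = self.dose
        df.to_csv(path, index=False)

    def interpolator(self) -> RegularGridInterpolator:
        if self.axes is None:
            raise ValueError("interpolation requires a grid distribution")
        return RegularGridInterpolator(
            self.axes, self.values, method="linear", bounds_error=True
        )

    def evaluate_at(self, points: np.ndarray) -> np.ndarray:
        """Dose at arbitrary points: multilinear interpolation on grids,
        exact matching on clouds."""
        points = np.atleast_2d(points)
        if self.axes is not None:
            return self.interpolator()(points)
        if points.shape == self.points.shape and np.allclose(
            points, self.points, atol=1e-6
        ):
            return self.dose.copy()
        raise ValueError(
            "cloud distribution can only be evaluated at its own points"
        )


@dataclass(frozen=True)
class DoseDifference:
    """Per-point dose differences with their summary statistics."""

    mean: float  # % of max measured dose
    sd: float
    per_point: np.ndarray  # DD at the points entering the statistics, %
    n_points: int


@dataclass(frozen=True)
class VerificationResult:
    """Joint dose-difference / gamma summary of one comparison."""

    dd_mean: float
    dd_sd: float
    gamma_mean: float
    gamma_sd: float
    pass_rate: float  # % of evaluated points with gamma <= 1
    n_evaluated: int
    criteria: dict = field(default_factory=dict)
    per_point_dd: np.ndarray | None = None
    per_point_gamma: np.ndarray | None = None


def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0


def mean_dose_difference(
    measured: DoseDistribution,
    calculated: DoseDistribution,
    threshold_pct: float = 10.0,
    restrict_to_threshold: bool = True,
    norm_dose: float | None = None,
) -> DoseDifference:
    """Global-normalized dose difference of calculated against measured.

    Statistics are taken over points whose *measured* dose reaches
    ``threshold_pct`` % of the measured maximum; pass
    ``restrict_to_threshold=False`` to average over all points instead
    (some array-QA packages do not threshold the dose difference).
    ``norm_dose`` overrides the normalization maximum, e.g. when one plane
    of a larger measured set is compared on its own.
    """
    norm = measured.d_max if norm_dose is None else float(norm_dose)
    d_calc = calculated.evaluate_at(measured.points)
    dd = 100.0 * (d_calc - measured.dose) / norm
    if restrict_to_threshold:
        mask = measured.dose >= threshold_pct / 100.0 * norm
        if not mask.any():
            raise ValueError(
                f"no measured point reaches the {threshold_pct}% dose threshold"
            )
        dd = dd[mask]
    return DoseDifference(
        mean=float(dd.mean()), sd=_sd(dd), per_point=dd, n_points=len(dd)
    )


def _offset_grid(radius: float, step: float, ndim: int) -> np.ndarray:
    """Spatial offsets covering the search ball with spacing <= step,
    including the origin and the surface radius."""
    n = max(1, int(np.ceil(radius / step)))
    axis = np.arange(-n, n + 1) * (radius / n)
    mesh = np.meshgrid(*([axis] * ndim), indexing="ij")
    offs = np.stack([m.ravel() for m in mesh], axis=1)
    keep = (offs**2).sum(axis=1) <= radius**2 + 1e-12
    return offs[keep]


def gamma_global(
    measured: DoseDistribution,
    calculated: DoseDistribution,
    dose_pct: float = 2.0,
    dta_mm: float = 2.0,
    threshold_pct: float = 10.0,
    search_radius_factor: float = 3.0,
    interp_step_mm: float = 0.2,
    local: bool = False,
    chunk_size: int = 4_000_000,
    norm_dose: float | None = None,
) -> VerificationResult:
    """Global gamma index of ``calculated`` against ``measured``.

    For each reference (measured) point above the low-dose threshold the
    gamma value is the minimum, over evaluated positions within
    ``search_radius_factor * dta_mm`` of the point, of::

        sqrt(|r - r_i|^2 / dta^2 + (D_eval(r) - D_meas,i)^2 / (dose_crit)^2)

    with ``dose_crit = dose_pct% * max(D_meas)`` (or of the local measured
    dose with ``local=True``).  The evaluated distribution is sampled by
    multilinear interpolation on a sub-grid of spacing at most
    ``interp_step_mm``; the search is exhaustive over that sub-grid, so on
    small problems it reproduces a brute-force computation exactly.

    Reference points whose whole search sphere is not covered by the
    evaluated grid are excluded with a warning.
    """
    if calculated.axes is None:
        raise ValueError("evaluated distribution must be a regular grid")
    radius = search_radius_factor * dta_mm
    norm = measured.d_max if norm_dose is None else float(norm_dose)
    thr = threshold_pct / 100.0 * norm
    above = measured.dose >= thr
    lo = np.array([a[0] for a in calculated.axes])
    hi = np.array([a[-1] for a in calculated.axes])
    covered = ((measured.points - radius) >= lo - 1e-9).all(axis=1) & (
        (measured.points + radius) <= hi + 1e-9
    ).all(axis=1)
    if (above & ~covered).any():
        warnings.warn(
            f"{int((above & ~covered).sum())} reference point(s) excluded: "
            "search sphere not covered by the evaluated grid",
            stacklevel=2,
        )
    sel = above & covered
    if not sel.any():
        raise ValueError("no evaluable reference point above the dose threshold")
    ref_pts = measured.points[sel]
    ref_dose = measured.dose[sel]
    if local:
        crit_col = (dose_pct / 100.0 * ref_dose)[:, None]
    else:
        crit_col = dose_pct / 100.0 * norm
    interp = calculated.interpolator()
    offsets = _offset_grid(radius, interp_step_mm, measured.ndim_space)
    dist2 = (offsets**2).sum(axis=1) / dta_mm**2
    n_ref = len(ref_pts)
    gamma2 = np.full(n_ref, np.inf)
    block = max(1, chunk_size // n_ref)
    for start in range(0, len(offsets), block):
        offs = offsets[start : start + block]
        pos = ref_pts[:, None, :] + offs[None, :, :]
        d_eval = interp(pos.reshape(-1, measured.ndim_space)).reshape(
            n_ref, len(offs)
        )
        dd2 = ((d_eval - ref_dose[:, None]) / crit_col) ** 2
        cand = dd2 + dist2[start : start + block][None, :]
        gamma2 = np.minimum(gamma2, cand.min(axis=1))
    gamma = np.sqrt(gamma2)
    dd_res = mean_dose_difference(
        measured, calculated, threshold_pct=threshold_pct, norm_dose=norm_dose
    )
    return VerificationResult(
        dd_mean=dd_res.mean,
        dd_sd=dd_res.sd,
        gamma_mean=float(gamma.mean()),
        gamma_sd=_sd(gamma),
        pass_rate=100.0 * float((gamma <= 1.0).mean()),
        n_evaluated=n_ref,
        criteria={
            "dose_pct": dose_pct,
            "dta_mm": dta_mm,
            "threshold_pct": threshold_pct,
            "normalization": "local" if local else "global",
            "search_radius_factor": search_radius_factor,
            "interp_step_mm": interp_step_mm,
        },
        per_point_dd=dd_res.per_point,
        per_point_gamma=gamma,
    )


def pooled_histogram(
    results: list[np.ndarray], bin_width: float
) -> pd.DataFrame:
    """Histogram of per-point values pooled over many verifications.

    Values from all results are concatenated (the pooling is over points,
    not plans) and binned on a deterministic grid aligned to multiples of
    ``bin_width``.  Returns a table with ``bin_low``, ``bin_high`` and
    ``count`` columns whose counts sum to the total number of points.
    """
    if not results:
        raise ValueError("need at least one result to pool")
    values = np.concatenate([np.asarray(r, dtype=float).ravel() for r in results])
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    return pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts}
    )
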