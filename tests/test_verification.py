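"""Dose difference, global gamma (against a brute-force oracle), histograms."""

import numpy as np
import pytest

from duomlc import (
    DoseDistribution,
    gamma_global,
    mean_dose_difference,
    pooled_histogram,
)


def _smooth_blob(axes, center, width, amplitude=2.0):
    mesh = np.meshgrid(*axes, indexing="ij")
    r2 = sum((m - c) ** 2 for m, c in zip(mesh, center))
    return amplitude * np.exp(-r2 / (2.0 * width**2))


class TestDoseDifference:
    def test_identical_distributions_give_zero(self):
        pts = np.random.default_rng(0).uniform(-10, 10, size=(50, 3))
        dose = np.linspace(0.5, 2.0, 50)
        m = DoseDistribution.from_points(pts, dose)
        c = DoseDistribution.from_points(pts, dose.copy())
        dd = mean_dose_difference(m, c)
        assert dd.mean == 0.0 and dd.sd == 0.0

    def test_two_point_hand_arithmetic(self):
        pts = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        m = DoseDistribution.from_points(pts, np.array([2.0, 1.0]))
        c = DoseDistribution.from_points(pts, np.array([1.98, 1.01]))
        dd = mean_dose_difference(m, c)
        np.testing.assert_allclose(dd.per_point, [-1.0, 0.5])
        assert dd.mean == pytest.approx(-0.25)

    def test_uniform_scaling_closed_form(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(-20, 20, size=(200, 3))
        meas = rng.uniform(0.5, 3.0, size=200)
        m = DoseDistribution.from_points(pts, meas)
        c = DoseDistribution.from_points(pts, 0.99 * meas)
        dd = mean_dose_difference(m, c, threshold_pct=0.0, restrict_to_threshold=False)
        assert dd.mean == pytest.approx(-100.0 * 0.01 * meas.mean() / meas.max())

    def test_threshold_excludes_low_dose_points(self):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        m = DoseDistribution.from_points(pts, np.array([2.0, 0.1, 1.0]))
        c = DoseDistribution.from_points(pts, np.array([2.0, 0.5, 1.0]))
        dd = mean_dose_difference(m, c, threshold_pct=10.0)
        assert dd.n_points == 2  # the 0.1 Gy point is below 10% of 2 Gy
        assert dd.mean == 0.0

    def test_no_point_above_threshold_raises(self):
        pts = np.array([[0.0, 0, 0]])
        m = DoseDistribution.from_points(pts, np.array([1.0]))
        c = DoseDistribution.from_points(pts, np.array([1.0]))
        with pytest.raises(ValueError, match="threshold"):
            mean_dose_difference(m, c, threshold_pct=200.0)

    def test_antisymmetric_under_swap_at_equal_maxima(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(-20, 20, size=(100, 2))
        a = rng.uniform(0.5, 2.0, size=100)
        b = a + rng.normal(0, 0.05, size=100)
        a[0] = b[0] = 2.5  # pin a common maximum
        da = DoseDistribution.from_points(pts, a)
        db_ = DoseDistribution.from_points(pts, b)
        f = mean_dose_difference(da, db_, restrict_to_threshold=False)
        r = mean_dose_difference(db_, da, restrict_to_threshold=False)
        assert f.mean == pytest.approx(-r.mean)


def _brute_force_gamma(ref_pts, ref_dose, axes, values, dose_crit, dta, radius, step):
    """Naive exhaustive gamma: nested offset loops, one point at a time."""
    from scipy.interpolate import RegularGridInterpolator

    interp = RegularGridInterpolator(axes, values)
    n = int(np.ceil(radius / step))
    coords = np.arange(-n, n + 1) * (radius / n)
    ndim = ref_pts.shape[1]
    out = []
    for p, dref in zip(ref_pts, ref_dose):
        best = np.inf
        grids = np.meshgrid(*([coords] * ndim), indexing="ij")
        offs = np.stack([g.ravel() for g in grids], axis=1)
        offs = offs[(offs**2).sum(axis=1) <= radius**2 + 1e-12]
        de = interp(p[None, :] + offs)
        g2 = (offs**2).sum(axis=1) / dta**2 + ((de - dref) / dose_crit) ** 2
        best = g2.min()
        out.append(np.sqrt(best))
    return np.array(out)


class TestGammaGlobal:
    def test_identical_distributions_pass_everywhere(self):
        ax = np.arange(-20.0, 20.5, 1.0)
        vals = _smooth_blob((ax, ax), (0, 0), 8.0)
        calc = DoseDistribution.from_grid((ax, ax), vals)
        inner = np.arange(-10.0, 10.5, 2.0)
        mesh = np.meshgrid(inner, inner, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=1)
        meas = DoseDistribution.from_points(pts, calc.evaluate_at(pts))
        res = gamma_global(meas, calc)
        assert res.pass_rate == 100.0
        np.testing.assert_allclose(res.per_point_gamma, 0.0, atol=1e-9)

    def test_flat_field_offset_gives_exact_gamma(self):
        # 3% of max offset in a spatially flat field: distance cannot help,
        # so gamma is exactly 3/2 = 1.5 under a 2% criterion
        ax = np.arange(-30.0, 30.5, 1.0)
        calc = DoseDistribution.from_grid(
            (ax, ax), np.full((len(ax), len(ax)), 1.03)
        )
        inner = np.arange(-15.0, 15.5, 5.0)
        mesh = np.meshgrid(inner, inner, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=1)
        meas = DoseDistribution.from_points(pts, np.full(len(pts), 1.0))
        res = gamma_global(meas, calc, dose_pct=2.0, dta_mm=2.0)
        np.testing.assert_allclose(res.per_point_gamma, 1.5, atol=1e-12)
        assert res.pass_rate == 0.0

    def test_matches_brute_force_oracle_on_3d_grid(self):
        ax = np.arange(-10.0, 10.5, 1.0)
        axes = (ax, ax, ax)
        meas_vals = _smooth_blob(axes, (0, 0, 0), 5.0)
        calc_vals = 1.02 * _smooth_blob(axes, (0.8, -0.5, 0.3), 5.2)
        calc = DoseDistribution.from_grid(axes, calc_vals)
        inner = np.arange(-3.0, 3.5, 1.0)
        mesh = np.meshgrid(inner, inner, inner, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=1)
        from scipy.interpolate import RegularGridInterpolator

        meas_dose = RegularGridInterpolator(axes, meas_vals)(pts)
        meas = DoseDistribution.from_points(pts, meas_dose)
        res = gamma_global(meas, calc, interp_step_mm=0.5)
        oracle = _brute_force_gamma(
            pts,
            meas_dose,
            axes,
            calc_vals,
            dose_crit=0.02 * meas_dose.max(),
            dta=2.0,
            radius=6.0,
            step=0.5,
        )
        np.testing.assert_allclose(res.per_point_gamma, oracle, atol=1e-6)

    def test_gamma_monotone_in_criteria(self):
        ax = np.arange(-20.0, 20.5, 1.0)
        meas_vals = _smooth_blob((ax, ax), (0, 0), 7.0)
        calc = DoseDistribution.from_grid(
            (ax, ax), 1.03 * _smooth_blob((ax, ax), (0.5, 0.5), 7.0)
        )
        inner = np.arange(-8.0, 8.5, 2.0)
        mesh = np.meshgrid(inner, inner, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=1)
        from scipy.interpolate import RegularGridInterpolator

        meas = DoseDistribution.from_points(
            pts, RegularGridInterpolator((ax, ax), meas_vals)(pts)
        )
        tight = gamma_global(meas, calc, dose_pct=2.0, dta_mm=2.0)
        loose_dose = gamma_global(meas, calc, dose_pct=3.0, dta_mm=2.0)
        loose_dta = gamma_global(meas, calc, dose_pct=2.0, dta_mm=3.0)
        assert (loose_dose.per_point_gamma <= tight.per_point_gamma + 1e-9).all()
        assert (loose_dta.per_point_gamma <= tight.per_point_gamma + 1e-9).all()

    def test_invariant_under_axis_relabeling(self):
        ax = np.arange(-15.0, 15.5, 1.0)
        vals = _smooth_blob((ax, ax), (2.0, -1.0), 6.0)
        calc = DoseDistribution.from_grid((ax, ax), 1.01 * vals)
        inner = np.arange(-5.0, 5.5, 2.5)
        mesh = np.meshgrid(inner, inner, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=1)
        from scipy.interpolate import RegularGridInterpolator

        dose = RegularGridInterpolator((ax, ax), vals)(pts)
        res = gamma_global(DoseDistribution.from_points(pts, dose), calc)
        calc_t = DoseDistribution.from_grid((ax, ax), (1.01 * vals).T)
        res_t = gamma_global(
            DoseDistribution.from_points(pts[:, ::-1], dose), calc_t
        )
        np.testing.assert_allclose(
            res.per_point_gamma, res_t.per_point_gamma, atol=1e-12
        )

    def test_refining_interp_step_converges(self):
        ax = np.arange(-20.0, 20.5, 1.0)
        meas_vals = _smooth_blob((ax, ax), (0, 0), 7.0)
        calc = DoseDistribution.from_grid(
            (ax, ax), 1.02 * _smooth_blob((ax, ax), (0.6, 0.0), 7.0)
        )
        inner = np.arange(-6.0, 6.5, 3.0)
        mesh = np.meshgrid(inner, inner, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=1)
        from scipy.interpolate import RegularGridInterpolator

        meas = DoseDistribution.from_points(
            pts, RegularGridInterpolator((ax, ax), meas_vals)(pts)
        )
        coarse = gamma_global(meas, calc, interp_step_mm=0.5)
        fine = gamma_global(meas, calc, interp_step_mm=0.1)
        assert (
            fine.per_point_gamma <= coarse.per_point_gamma + 1e-3
        ).all()

    def test_uncovered_search_sphere_excluded_with_warning(self):
        ax = np.arange(-10.0, 10.5, 1.0)
        calc = DoseDistribution.from_grid(
            (ax, ax), np.full((len(ax), len(ax)), 1.0)
        )
        pts = np.array([[0.0, 0.0], [8.0, 0.0]])  # second sphere exits grid
        meas = DoseDistribution.from_points(pts, np.array([1.0, 1.0]))
        with pytest.warns(UserWarning, match="excluded"):
            res = gamma_global(meas, calc)
        assert res.n_evaluated == 1

    def test_cloud_evaluated_distribution_rejected(self):
        pts = np.array([[0.0, 0.0]])
        m = DoseDistribution.from_points(pts, np.array([1.0]))
        with pytest.raises(ValueError, match="grid"):
            gamma_global(m, m)


class TestPooledHistogram:
    def test_counts_sum_to_total_and_order_invariant(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 500)
        b = rng.normal(0.5, 1.2, 300)
        h_ab = pooled_histogram([a, b], bin_width=0.25)
        h_ba = pooled_histogram([b, a], bin_width=0.25)
        assert h_ab["count"].sum() == 800
        assert h_ab.equals(h_ba)

    def test_single_result_is_its_own_histogram(self):
        vals = np.array([0.1, 0.2, 0.9, 1.4])
        h = pooled_histogram([vals], bin_width=0.5)
        assert h["count"].sum() == 4
        assert h["bin_low"].iloc[0] == pytest.approx(0.0)
        assert h["bin_high"].iloc[-1] == pytest.approx(1.5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pooled_histogram([], bin_width=0.5)
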