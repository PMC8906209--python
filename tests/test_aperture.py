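"""Strip decomposition, effective gaps, trailing classification and stats."""

import dataclasses

import numpy as np
import pytest

from duomlc import (
    Layer,
    build_strips,
    plan_gap_trailing_stats,
    strip_apertures,
    to_single_layer,
)
from duomlc.aperture import TrailingClass, classify_edge
from duomlc.plan import DISTAL_SPEC, PROXIMAL_SPEC, DualLayerPlan
from tests.conftest import make_uniform_plan


class TestBuildStrips:
    def test_stock_geometry_yields_58_strips_56_dual(self, strips):
        assert len(strips) == 58
        dual = [s for s in strips if s.dist_pair is not None]
        assert len(dual) == 56
        assert strips[0].dist_pair is None and strips[-1].dist_pair is None
        assert all(s.y_high - s.y_low == pytest.approx(5.0) for s in strips)

    def test_strips_mirror_about_axis(self, strips):
        for k, s in enumerate(strips):
            m = strips[57 - k]
            assert s.y_low == pytest.approx(-m.y_high)
            assert s.prox_pair == 28 - m.prox_pair
            if s.dist_pair is None:
                assert m.dist_pair is None
            else:
                assert s.dist_pair == 27 - m.dist_pair

    def test_non_half_pitch_offset_rejected(self):
        bad = dataclasses.replace(DISTAL_SPEC, lateral_offset=3.0)
        with pytest.raises(ValueError, match="half"):
            build_strips(PROXIMAL_SPEC, bad)

    def test_mismatched_leaf_width_rejected(self):
        bad = dataclasses.replace(DISTAL_SPEC, leaf_width_iso=5.0)
        with pytest.raises(ValueError):
            build_strips(PROXIMAL_SPEC, bad)


class TestStripApertures:
    def _apertures(self, prox, dist, strips):
        plan = make_uniform_plan(prox=prox, dist=dist)
        return strip_apertures(plan.beams[0].control_points[0], strips)

    def test_identical_layers_give_tie(self, strips):
        aps = self._apertures((-10.0, 10.0), (-10.0, 10.0), strips)
        mid = aps[29]
        assert mid.effective_gap == pytest.approx(20.0)
        assert mid.trailing == (0.0, 0.0)
        assert mid.defining == (None, None)

    def test_hand_geometry_example(self, strips):
        # proximal defines both banks: bank A trails 5 mm, bank B 2 mm
        aps = self._apertures((-10.0, 10.0), (-15.0, 12.0), strips)
        mid = aps[29]
        assert mid.effective_gap == pytest.approx(20.0)
        assert mid.defining == (Layer.PROXIMAL, Layer.PROXIMAL)
        assert mid.trailing == (5.0, 2.0)

    def test_disjoint_gaps_are_closed(self, strips):
        aps = self._apertures((-10.0, -2.0), (3.0, 12.0), strips)
        assert aps[29].effective_gap == 0.0

    def test_effective_gap_never_exceeds_single_layer_gap(self, small_plan, strips):
        for cp in small_plan.beams[0].control_points:
            for ap in strip_apertures(cp, strips):
                gp = ap.prox_tips[1] - ap.prox_tips[0]
                assert ap.effective_gap <= gp + 1e-9
                if ap.has_distal:
                    gd = ap.dist_tips[1] - ap.dist_tips[0]
                    assert ap.effective_gap <= gd + 1e-9

    def test_proximal_only_strips_have_no_classification(self, strips):
        aps = self._apertures((-10.0, 10.0), (-10.0, 10.0), strips)
        assert aps[0].trailing is None and aps[0].defining is None
        assert aps[0].effective_gap == pytest.approx(20.0)


def _brute_force_stats(plan):
    """Independent exhaustive enumeration of gaps and trailing classes."""
    specs = plan.beams[0].layer_specs
    pe = specs[Layer.PROXIMAL].pair_edges()
    de = specs[Layer.DISTAL].pair_edges()
    gaps, classes = [], []
    for beam in plan.beams:
        for cp in beam.control_points:
            pa, pb = cp.positions[Layer.PROXIMAL]
            da, db = cp.positions[Layer.DISTAL]
            for k in range(58):
                ylo, yhi = -145.0 + 5.0 * k, -140.0 + 5.0 * k
                ymid = (ylo + yhi) / 2.0
                jp = int((ymid - pe[0]) // 10.0)
                has_d = de[0] < ymid < de[-1]
                ap_, bp_ = round(pa[jp], 2), round(pb[jp], 2)
                if not has_d:
                    g = max(0.0, bp_ - ap_)
                    if g > 0:
                        gaps.append(g)
                    continue
                jd = int((ymid - de[0]) // 10.0)
                ad_, bd_ = round(da[jd], 2), round(db[jd], 2)
                g = max(0.0, min(bp_, bd_) - max(ap_, ad_))
                if g <= 0:
                    continue
                gaps.append(g)
                for tip_p, tip_d, inner_larger in (
                    (ap_, ad_, True),
                    (bp_, bd_, False),
                ):
                    t = abs(tip_p - tip_d)
                    if t == 0:
                        classes.append("overlap")
                        continue
                    prox_def = (tip_p > tip_d) == inner_larger
                    short = t < 5.0
                    classes.append(
                        ("prox" if prox_def else "dist")
                        + ("_short" if short else "_long")
                    )
    return gaps, classes


class TestPlanStats:
    def test_single_open_strip_identical_layers_all_overlap(self):
        plan = make_uniform_plan(prox=(-10.0, 10.0), dist=(-10.0, 10.0))
        stats = plan_gap_trailing_stats(plan)
        assert stats.class_pct[TrailingClass.OVERLAP] == pytest.approx(100.0)
        assert sum(stats.class_pct.values()) == pytest.approx(100.0)

    def test_stats_match_brute_force_enumeration(self, small_plan):
        stats = plan_gap_trailing_stats(small_plan)
        gaps, classes = _brute_force_stats(small_plan)
        assert stats.n_gap_samples == len(gaps)
        assert stats.gap_median == pytest.approx(np.median(gaps))
        assert stats.gap_p25 == pytest.approx(np.percentile(gaps, 25))
        assert stats.gap_p75 == pytest.approx(np.percentile(gaps, 75))
        n = len(classes)
        expected = {
            TrailingClass.PROX_DEFINING_SHORT: classes.count("prox_short"),
            TrailingClass.PROX_DEFINING_LONG: classes.count("prox_long"),
            TrailingClass.DIST_DEFINING_SHORT: classes.count("dist_short"),
            TrailingClass.DIST_DEFINING_LONG: classes.count("dist_long"),
            TrailingClass.OVERLAP: classes.count("overlap"),
        }
        for cls, count in expected.items():
            assert stats.class_pct[cls] == pytest.approx(100.0 * count / n)

    @pytest.mark.parametrize("weighting", ["unweighted", "mu_weighted"])
    def test_class_percentages_partition(self, small_plan, large_plan, weighting):
        for plan in (small_plan, large_plan):
            stats = plan_gap_trailing_stats(plan, weighting=weighting)
            assert sum(stats.class_pct.values()) == pytest.approx(100.0, abs=0.1)

    def test_gap_median_matches_clinical_class_targets(self, small_plan, large_plan):
        # calibration targets: small 17.5 mm, large 33.5 mm, +/-20%
        s = plan_gap_trailing_stats(small_plan)
        assert s.n_gap_samples >= 1000
        assert 14.0 <= s.gap_median <= 21.0
        lg = plan_gap_trailing_stats(large_plan)
        assert 26.8 <= lg.gap_median <= 40.2

    def test_unweighted_stats_invariant_under_cp_reversal(self, small_plan):
        ref = plan_gap_trailing_stats(small_plan)
        reversed_plan = small_plan.copy()
        for beam in reversed_plan.beams:
            cps = beam.control_points[::-1]
            for i, cp in enumerate(cps):
                cp.index = i
                cp.cumulative_meterset_weight = (
                    beam.control_points[i].cumulative_meterset_weight
                )
            beam.control_points = cps
        assert plan_gap_trailing_stats(reversed_plan) == ref

    def test_stats_invariant_under_beam_relabeling(self, small_plan):
        ref = plan_gap_trailing_stats(small_plan)
        shuffled = DualLayerPlan(
            beams=list(reversed(small_plan.beams)), metadata=small_plan.metadata
        )
        assert plan_gap_trailing_stats(shuffled) == ref

    def test_empty_aperture_raises(self):
        plan = make_uniform_plan(prox=(0.0, 0.0), dist=(0.0, 0.0))
        with pytest.raises(ValueError, match="empty aperture"):
            plan_gap_trailing_stats(plan)

    def test_single_layer_conversion_lands_in_saturated_class(self, small_plan):
        for layer, cls in (
            (Layer.PROXIMAL, TrailingClass.PROX_DEFINING_LONG),
            (Layer.DISTAL, TrailingClass.DIST_DEFINING_LONG),
        ):
            converted = to_single_layer(small_plan, layer, retraction=5.0)
            stats = plan_gap_trailing_stats(converted)
            assert stats.class_pct[cls] == pytest.approx(100.0)


def test_classify_edge_is_exhaustive():
    for layer in (Layer.PROXIMAL, Layer.DISTAL, None):
        for t in (0.0, 2.0, 5.0, 12.0):
            assert classify_edge(layer, t) in TrailingClass
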