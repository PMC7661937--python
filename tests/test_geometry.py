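"""Parametric filter construction, signed distances, solid fractions."""

import math

import numpy as np
import pytest

from cavaflow.geometry import (STATE_ALPHAS, Capsule, DeploymentState,
                               DomainSpec, FilterSpec, WireSegmentSet,
                               build_filter, signed_distance, solid_fraction,
                               solid_fraction_grid)


class TestDeploymentState:
    @pytest.mark.parametrize("name,alpha", STATE_ALPHAS.items())
    def test_converted_states_carry_their_angle(self, name, alpha):
        assert DeploymentState(name).alpha == alpha

    def test_inconsistent_alpha_rejected(self):
        with pytest.raises(ValueError):
            DeploymentState("small_open", alpha=30.0)
        with pytest.raises(ValueError):
            DeploymentState("normal", alpha=10.0)
        with pytest.raises(ValueError):
            DeploymentState("banana")


class TestBuildFilter:
    @pytest.mark.parametrize("name", ["normal", "reverse", "small_open",
                                      "moderate_open", "large_open"])
    def test_arm_tips_touch_the_wall(self, name, tube):
        spec = FilterSpec(state=DeploymentState(name))
        g = build_filter(spec, tube)
        for cap in g.arms:
            tip_r = math.hypot(cap.end[0], cap.end[1])
            assert tip_r + spec.wire_radius == pytest.approx(tube.radius,
                                                             abs=1e-12)

    @pytest.mark.parametrize("name,alpha", STATE_ALPHAS.items())
    def test_converted_arm_angle_recovers_alpha(self, name, alpha, tube):
        g = build_filter(FilterSpec(state=DeploymentState(name)), tube)
        assert g.head is None  # the head is detached on conversion
        for cap in g.arms:
            d = np.asarray(cap.end) - np.asarray(cap.start)
            ang = math.degrees(math.atan2(math.hypot(d[0], d[1]), abs(d[2])))
            assert ang == pytest.approx(alpha, abs=1e-9)

    def test_reverse_is_mirror_of_normal(self, tube, normal_filter):
        rev = build_filter(FilterSpec(state=DeploymentState("reverse")), tube)
        for cn, cr in zip(normal_filter.arms, rev.arms):
            m = cn.mirrored_z(0.0)
            assert np.allclose(m.start, cr.start) and np.allclose(m.end, cr.end)
        assert np.allclose(normal_filter.head.mirrored_z(0.0).end, rev.head.end)

    def test_eightfold_rotational_symmetry(self, normal_filter):
        th = 2 * np.pi / 8
        rot = np.array([[np.cos(th), -np.sin(th), 0],
                        [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        tips = sorted(tuple(np.round(rot @ np.asarray(c.end), 12))
                      for c in normal_filter.arms)
        tips_orig = sorted(tuple(np.round(np.asarray(c.end), 12))
                           for c in normal_filter.arms)
        assert tips == tips_orig

    def test_radial_penetration_shrinks_as_filter_opens(self, tube):
        """The cone flattens toward the wall as alpha decreases."""
        spans = []
        for name in ("small_open", "moderate_open", "large_open"):
            g = build_filter(FilterSpec(state=DeploymentState(name)), tube)
            r_free = min(math.hypot(c.start[0], c.start[1]) for c in g.arms)
            spans.append(tube.radius - r_free)
        assert spans[0] > spans[1] > spans[2]

    def test_ivc_only_has_no_geometry(self, tube):
        with pytest.raises(ValueError):
            build_filter(FilterSpec(state=DeploymentState("ivc_only")), tube)


class TestSignedDistance:
    def test_on_axis_and_outside(self, normal_filter):
        spec = normal_filter.spec
        cap = normal_filter.arms[0]
        mid = cap.point_at(0.5)
        assert signed_distance(normal_filter, mid) == pytest.approx(
            -spec.wire_radius, abs=1e-15)
        # far point: distance to nearest capsule via brute-force sampling
        far = np.array([0.0, 0.0, 0.1])
        s = np.linspace(0, 1, 4001)
        brute = min(
            np.min(np.linalg.norm(c.point_at(s) - far, axis=1)) - c.radius
            for c in normal_filter.segments)
        assert signed_distance(normal_filter, far) == pytest.approx(brute,
                                                                    abs=1e-7)

    def test_lipschitz_property(self, normal_filter):
        rng = np.random.default_rng(42)
        p = rng.uniform(-0.03, 0.03, (500, 3))
        q = p + rng.normal(0, 0.002, (500, 3))
        dp = signed_distance(normal_filter, p)
        dq = signed_distance(normal_filter, q)
        assert np.all(np.abs(dp - dq) <= np.linalg.norm(p - q, axis=1) + 1e-12)

    def test_nonfinite_rejected(self, normal_filter):
        with pytest.raises(ValueError):
            signed_distance(normal_filter, [np.nan, 0, 0])


class TestSolidFraction:
    def test_inside_and_outside_boxes(self, normal_filter, tube):
        fat = WireSegmentSet(
            arms=(Capsule((0, 0, -1), (0, 0, 1), 0.5),), head=None,
            state=DeploymentState("normal"), spec=FilterSpec(), domain=tube)
        assert solid_fraction(fat, ((-0.1, -0.1, -0.1), (0.1, 0.1, 0.1))) == 1.0
        assert solid_fraction(normal_filter,
                              ((0.05, 0.05, 0.05), (0.06, 0.06, 0.06))) == 0.0

    def test_box_straddling_a_planar_face(self, tube):
        # giant capsule: its surface is locally a plane at x = 1
        wall = WireSegmentSet(
            arms=(Capsule((-99, 0, 0), (-99, 0, 1e-6), 100.0),), head=None,
            state=DeploymentState("normal"), spec=FilterSpec(), domain=tube)
        frac = solid_fraction(wall, ((0.5, -0.5, -0.5), (1.5, 0.5, 0.5)),
                              n_sub=6)
        assert frac == pytest.approx(0.5, abs=0.02)

    def test_grid_fractions_match_per_cell_queries(self, normal_filter):
        xe = np.linspace(-0.01, 0.01, 9)
        ye = np.linspace(-0.01, 0.01, 9)
        ze = np.linspace(-0.05, 0.01, 13)
        grid = solid_fraction_grid(normal_filter, xe, ye, ze, n_sub=3)
        for (i, j, k) in [(4, 4, 11), (0, 4, 2), (4, 0, 2), (2, 2, 6)]:
            cell = ((xe[i], ye[j], ze[k]), (xe[i + 1], ye[j + 1], ze[k + 1]))
            assert grid[i, j, k] == pytest.approx(
                solid_fraction(normal_filter, cell, n_sub=3), abs=1e-12)

    def test_total_solid_volume_close_to_wire_volume(self, normal_filter):
        xe = np.linspace(-0.01, 0.01, 26)
        ye = np.linspace(-0.01, 0.01, 26)
        ze = np.linspace(-0.06, 0.02, 81)
        grid = solid_fraction_grid(normal_filter, xe, ye, ze, n_sub=4)
        vol = grid.sum() * np.diff(xe)[0] * np.diff(ye)[0] * np.diff(ze)[0]
        spec = normal_filter.spec
        arm_len = normal_filter.arms[0].axis_length
        expect = (8 * np.pi * spec.wire_radius**2 * arm_len
                  + np.pi * spec.head_radius**2 * spec.head_length)
        # capsule caps and sampling bias allow a generous band
        assert expect * 0.7 < vol < expect * 1.6
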