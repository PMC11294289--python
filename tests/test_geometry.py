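"""Shape descriptors of polygonal language profiles, against independent oracles.

The shoelace/centroid oracle is shapely (an implementation entirely
independent of the origin-anchored triangle decomposition used here); the
ordering search is checked against full permutation enumeration; the
centroid additionally against seeded Monte-Carlo rejection sampling.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Polygon as ShapelyPolygon

from voxplp import (
    AxisValues,
    RadarConfig,
    build_profile,
    centroid,
    centroidal_distance,
    describe,
    first_moment,
    maximize_area_ordering,
    polygon_area,
    quadrant_convergence,
    triangle_decomposition,
)
from voxplp.plp_geometry import _cyclic_orderings, axis_unit_vectors

CFG = RadarConfig()
CFG12 = RadarConfig(property_radius=12)

axis_value = st.floats(min_value=0.0, max_value=100.0, allow_nan=False)


def profile(tact, mand, echoic, sequelic, config=CFG):
    return build_profile(AxisValues(tact=tact, mand=mand, echoic=echoic, sequelic=sequelic), config)


def shapely_oracle(plp):
    poly = ShapelyPolygon(plp.vertices)
    area = poly.area
    center = (poly.centroid.x, poly.centroid.y) if area > 0 else None
    return area, center


class TestBuildProfile:
    def test_worked_example_vertices(self, worked_values):
        plp = build_profile(worked_values, CFG)
        assert plp.vertices == ((12.0, 0.0), (0.0, 10.0), (-8.0, 0.0), (0.0, -12.0))

    def test_all_zero_profile_collapses_to_origin(self):
        plp = profile(0, 0, 0, 0)
        assert plp.vertices == ((0.0, 0.0),) * 4

    def test_assessment_totals_mapping(self, assessment):
        from voxplp import operant_totals

        plp = build_profile(operant_totals(assessment), CFG)
        assert plp.vertices == ((5.0, 0.0), (0.0, 2.0), (-1.0, 0.0), (0.0, -5.0))

    def test_vertex_lies_on_its_axis_at_its_value(self):
        plp = profile(3, 7, 2, 5)
        for (x, y), v in zip(plp.vertices, plp.values_in_order):
            assert math.hypot(x, y) == pytest.approx(v)

    def test_value_exceeding_property_radius_warns_or_errors(self, worked_values):
        small = RadarConfig(property_radius=5)
        with pytest.warns(UserWarning, match="property_radius"):
            build_profile(worked_values, small)
        strict = RadarConfig(property_radius=5, radius_policy="error")
        with pytest.raises(ValueError, match="property_radius"):
            build_profile(worked_values, strict)


class TestPolygonArea:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ((12, 10, 12, 8), 220.0),  # the worked example
            ((12, 12, 12, 12), 288.0),  # balanced: 2 v^2
            ((5, 2, 5, 1), 21.0),  # the assessment totals
            ((0, 0, 0, 0), 0.0),
        ],
    )
    def test_known_areas(self, values, expected):
        tact, mand, echoic, sequelic = values
        assert polygon_area(profile(tact, mand, echoic, sequelic)) == pytest.approx(expected)

    @given(t=axis_value, m=axis_value, e=axis_value, s=axis_value)
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_equals_shoelace_on_vertices(self, t, m, e, s):
        plp = profile(t, m, e, s)
        oracle_area, _ = shapely_oracle(plp)
        assert polygon_area(plp) == pytest.approx(oracle_area, abs=1e-9)

    @given(v=st.floats(min_value=0.1, max_value=50))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_balanced_closed_form(self, v):
        assert polygon_area(profile(v, v, v, v)) == pytest.approx(2 * v * v)


class TestQuadrantConvergence:
    def test_worked_example_ranking(self, worked_values):
        areas, shares = quadrant_convergence(build_profile(worked_values, CFG))
        assert areas == pytest.approx((60.0, 40.0, 48.0, 72.0))
        # convergence ranking: tact&echoic (Q4) strongest, mand&sequelic (Q2) weakest
        order = sorted(range(4), key=lambda i: -areas[i])
        assert order == [3, 0, 2, 1]
        assert sum(shares) == pytest.approx(1.0)

    def test_balanced_profile_equal_shares(self, balanced_values):
        _, shares = quadrant_convergence(build_profile(balanced_values, CFG))
        assert shares == pytest.approx((0.25,) * 4)

    def test_assessment_totals_quadrants(self):
        areas, shares = quadrant_convergence(profile(5, 2, 5, 1))
        assert areas == pytest.approx((5.0, 1.0, 2.5, 12.5))
        assert sum(areas) == pytest.approx(21.0)

    def test_degenerate_profile_has_null_shares(self):
        areas, shares = quadrant_convergence(profile(0, 0, 0, 0))
        assert areas == (0.0,) * 4
        assert shares is None


class TestOrderingSearch:
    def test_worked_example_canonical_attains_maximum(self, worked_values):
        ordering, a_tilde = maximize_area_ordering(worked_values)
        assert a_tilde == pytest.approx(220.0)
        assert ordering == ("echoic", "mand", "sequelic", "tact")

    def test_equal_values_tie_returns_canonical(self, balanced_values):
        ordering, a_tilde = maximize_area_ordering(balanced_values)
        assert ordering == ("echoic", "mand", "sequelic", "tact")
        assert a_tilde == pytest.approx(288.0)

    def test_assessment_magnitudes(self):
        values = AxisValues(tact=5, mand=2, echoic=5, sequelic=1)
        ordering, a_tilde = maximize_area_ordering(values)
        assert a_tilde == pytest.approx(21.0)
        assert ordering == ("echoic", "mand", "sequelic", "tact")  # tie-break

    def test_number_of_distinct_cyclic_orderings(self):
        assert len(_cyclic_orderings(4)) == 3
        assert len(_cyclic_orderings(5)) == 12
        assert len(_cyclic_orderings(6)) == 60

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_maximum_over_exhaustive_permutations(self, n):
        rng = np.random.default_rng(n)
        sin_term = 0.5 * math.sin(2 * math.pi / n)
        for _ in range(5):
            vals = rng.uniform(0, 10, size=n)
            _, a_tilde = maximize_area_ordering(vals)
            best = max(
                sin_term * sum(vals[p[i]] * vals[p[(i + 1) % n]] for i in range(n))
                for p in itertools.permutations(range(n))
            )
            assert a_tilde == pytest.approx(best)


class TestCentroid:
    def test_worked_example(self, worked_values):
        c = centroid(build_profile(worked_values, CFG))
        assert c == pytest.approx((4 / 3, -2 / 3))
        assert (round(c[0], 2), round(c[1], 2)) == (1.33, -0.67)

    def test_balanced_repertoire_centered_at_origin(self, balanced_values):
        c = centroid(build_profile(balanced_values, CFG))
        assert c == pytest.approx((0.0, 0.0), abs=1e-12)

    def test_single_quadrant_profile_closed_form(self):
        # only tact=2 and sequelic=1 nonzero: one triangle, centroid at (-1/3, -2/3)
        c = centroid(profile(2, 0, 0, 1))
        assert c == pytest.approx((-1 / 3, -2 / 3))

    def test_degenerate_profile_has_no_centroid(self):
        assert centroid(profile(0, 0, 0, 0)) is None
        assert centroidal_distance(None) is None

    @given(t=axis_value, m=axis_value, e=axis_value, s=axis_value)
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_matches_shapely_centroid(self, t, m, e, s):
        plp = profile(t, m, e, s)
        oracle_area, oracle_center = shapely_oracle(plp)
        ours = centroid(plp)
        if oracle_area < 1e-9:
            return
        assert ours == pytest.approx(oracle_center, abs=1e-9)

    def test_matches_monte_carlo_centroid(self, worked_values):
        plp = build_profile(worked_values, CFG)
        poly = ShapelyPolygon(plp.vertices)
        rng = np.random.default_rng(2024)
        xs = rng.uniform(-12, 12, size=60_000)
        ys = rng.uniform(-12, 12, size=60_000)
        from shapely import points as shapely_points
        from shapely import contains

        inside = contains(poly, shapely_points(np.column_stack([xs, ys])))
        hits_x, hits_y = xs[inside], ys[inside]
        n = inside.sum()
        mc = (hits_x.mean(), hits_y.mean())
        ours = centroid(plp)
        for est, ref, spread in ((mc[0], ours[0], hits_x.std()), (mc[1], ours[1], hits_y.std())):
            assert abs(est - ref) <= 3 * spread / math.sqrt(n)

    def test_triangle_decomposition_conserves_area(self):
        plp = profile(3, 8, 1, 6)
        decomp = triangle_decomposition(plp)
        assert decomp.total_area == pytest.approx(polygon_area(plp))

    def test_axis_swap_reflects_centroid(self):
        # swapping echoic and sequelic reflects the centroid across the y-axis
        a = centroid(profile(3, 8, 10, 2))
        b = centroid(profile(3, 8, 2, 10))
        assert b[0] == pytest.approx(-a[0])
        assert b[1] == pytest.approx(a[1])
        # swapping tact and mand reflects across the x-axis
        c = centroid(profile(8, 3, 10, 2))
        assert c[1] == pytest.approx(-a[1])
        assert c[0] == pytest.approx(a[0])

    @given(
        t=st.floats(min_value=0.1, max_value=20),
        m=st.floats(min_value=0.1, max_value=20),
        e=st.floats(min_value=0.1, max_value=20),
        s=st.floats(min_value=0.1, max_value=20),
        k=st.floats(min_value=0.1, max_value=10),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_scaling_equivariance(self, t, m, e, s, k):
        base = AxisValues(t, m, e, s)
        a0 = polygon_area(build_profile(base, CFG))
        a1 = polygon_area(build_profile(base.scaled(k), CFG))
        assert a1 == pytest.approx(k * k * a0, rel=1e-9)
        c0 = centroid(build_profile(base, CFG))
        c1 = centroid(build_profile(base.scaled(k), CFG))
        assert c1 == pytest.approx((k * c0[0], k * c0[1]), rel=1e-9)
        r0 = centroidal_distance(c0)
        assert centroidal_distance(c1) == pytest.approx(k * r0, rel=1e-9)


class TestFirstMoment:
    def test_balanced_profile(self, config12):
        assert first_moment(288.0, 0.0, config12) == pytest.approx(3456.0)

    def test_reported_single_quadrant_profile(self, config12):
        assert first_moment(1.0, 0.75, config12) == pytest.approx(11.25)

    def test_zero_area_profile_has_zero_moment(self, config12):
        assert first_moment(0.0, None, config12) == 0.0

    def test_missing_property_radius_is_hard_error(self):
        with pytest.raises(ValueError, match="property radius"):
            first_moment(10.0, 1.0, RadarConfig())

    def test_centroid_outside_property_space(self, config12):
        with pytest.raises(ValueError, match="exceeds property radius"):
            first_moment(10.0, 13.0, config12)
        with pytest.warns(UserWarning):
            q = first_moment(10.0, 13.0, config12, permissive=True)
        assert q == pytest.approx(-10.0)


class TestDescribe:
    def test_worked_example_full_descriptor_set(self, worked_values, config12):
        d = describe(worked_values, config12)
        assert d.area == pytest.approx(220.0)
        assert d.centroidal_distance == pytest.approx(1.4907, abs=5e-5)
        assert round(d.first_moment, 2) == 2312.04
        assert d.area_max == pytest.approx(220.0)
        assert sum(d.quadrant_shares) == pytest.approx(1.0)
        assert not d.degenerate

    def test_first_moment_identity(self, config12):
        rng = np.random.default_rng(11)
        for _ in range(20):
            vals = AxisValues(*rng.uniform(0, 12, size=4))
            d = describe(vals, config12)
            assert d.first_moment == pytest.approx(
                d.area * (12 - d.centroidal_distance)
            )

    def test_all_zero_values_degenerate(self, config12):
        d = describe(AxisValues(0, 0, 0, 0), config12)
        assert d.degenerate
        assert d.area == 0.0
        assert d.centroid is None and d.centroidal_distance is None
        assert d.first_moment == 0.0
        assert d.quadrant_shares is None

    def test_maximize_mode_reorders_axes(self):
        # values where the canonical order is suboptimal: large values opposite
        vals = AxisValues(tact=1, mand=1, echoic=10, sequelic=10)
        cfg = RadarConfig(property_radius=12, ordering_mode="maximize")
        d = describe(vals, cfg)
        canonical = describe(vals, RadarConfig(property_radius=12))
        assert canonical.area == pytest.approx(20.0)
        assert d.area == pytest.approx(d.area_max) == pytest.approx(60.5)
        assert d.area > canonical.area
        assert d.axis_order != canonical.axis_order

    def test_monte_carlo_descriptor_agreement(self, config12):
        rng = np.random.default_rng(5)
        vals = AxisValues(*rng.uniform(1, 12, size=4))
        d = describe(vals, config12)
        poly = ShapelyPolygon(build_profile(vals, config12).vertices)
        n = 40_000
        xs = rng.uniform(-12, 12, size=n)
        ys = rng.uniform(-12, 12, size=n)
        from shapely import contains, points as shapely_points

        inside = contains(poly, shapely_points(np.column_stack([xs, ys])))
        frac = inside.mean()
        mc_area = frac * 24 * 24
        sigma_area = 24 * 24 * math.sqrt(frac * (1 - frac) / n)
        assert abs(mc_area - d.area) <= 3 * sigma_area


def test_axis_unit_vectors_are_exact_on_quarter_turns():
    assert axis_unit_vectors(4) == [(1.0, 0.0), (0.0, 1.0), (-1.0, 0.0), (0.0, -1.0)]
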