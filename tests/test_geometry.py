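import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from confinetrack.geometry import (
    BoundaryClass,
    CornerPointError,
    Difference,
    Disk,
    NotOnBoundaryError,
    Point2D,
    PolygonRegion,
    Rectangle,
    region_from_dict,
    region_to_dict,
)


def brute_force_signed_distance(region, p, n_samples=200_000):
    """Independent oracle: sign from containment, magnitude by dense boundary
    sampling (disk boundary parametrised directly)."""
    theta = np.linspace(0.0, 2.0 * math.pi, n_samples, endpoint=False)
    boundary = region.center + region.radius * np.column_stack(
        [np.cos(theta), np.sin(theta)]
    )
    d = np.linalg.norm(boundary - np.asarray(p), axis=1).min()
    return d if region.contains(p) else -d


class TestContains:
    def test_disk_center_inside(self, disk50):
        assert disk50.contains((0.0, 0.0))

    def test_disk_outside(self, disk50):
        assert not disk50.contains((60.0, 0.0))

    def test_boundary_counts_as_inside(self, disk50):
        assert disk50.contains((50.0, 0.0))

    def test_difference_hole_center_outside(self):
        region = Difference(
            Rectangle((-300.0, -300.0), 600.0, 600.0), Disk((0.0, 0.0), 100.0)
        )
        assert not region.contains((0.0, 0.0))
        assert region.contains((250.0, 250.0))


class TestSignedDistance:
    def test_disk_center(self, disk50):
        assert disk50.signed_distance((0.0, 0.0)) == pytest.approx(50.0)

    def test_disk_boundary(self, disk50):
        assert disk50.signed_distance((50.0, 0.0)) == pytest.approx(0.0, abs=1e-12)

    def test_disk_outside_matches_brute_force(self, disk50):
        assert disk50.signed_distance((70.0, 0.0)) == pytest.approx(-20.0)
        assert disk50.signed_distance((70.0, 0.0)) == pytest.approx(
            brute_force_signed_distance(disk50, (70.0, 0.0)), abs=1e-6
        )

    @settings(max_examples=50, derandomize=True)
    @given(
        x=st.floats(-80, 80), y=st.floats(-80, 80),
        r=st.floats(1.0, 60.0),
    )
    def test_disk_closed_form_and_containment_consistency(self, x, y, r):
        disk = Disk((0.0, 0.0), r)
        p = (x, y)
        sd = disk.signed_distance(p)
        assert sd == pytest.approx(r - math.hypot(x, y), abs=1e-9)
        assert disk.contains(p) == (sd >= -1e-6)

    def test_rectangle_inside_outside(self):
        rect = Rectangle((0.0, 0.0), 10.0, 20.0)
        assert rect.signed_distance((5.0, 10.0)) == pytest.approx(5.0)
        assert rect.signed_distance((15.0, 10.0)) == pytest.approx(-5.0)
        # outside a corner: Euclidean distance to the corner
        assert rect.signed_distance((13.0, 24.0)) == pytest.approx(-5.0)

    def test_vectorised_matches_scalar(self, disk50):
        pts = np.array([[0.0, 0.0], [50.0, 0.0], [70.0, 0.0], [-20.0, 30.0]])
        np.testing.assert_allclose(
            disk50.signed_distance_many(pts),
            [disk50.signed_distance(p) for p in pts],
        )


class TestTangentAndClass:
    def test_disk_rim_is_concave_arc(self, disk50):
        t, cls = disk50.boundary_tangent_and_class((50.0, 0.0))
        np.testing.assert_allclose(t, [0.0, 1.0], atol=1e-12)
        assert cls is BoundaryClass.CONCAVE_ARC

    def test_rectangle_edge_is_linear(self):
        rect = Rectangle((0.0, 0.0), 10.0, 10.0)
        t, cls = rect.boundary_tangent_and_class((5.0, 0.0))
        np.testing.assert_allclose(t, [1.0, 0.0])
        assert cls is BoundaryClass.LINEAR

    def test_hole_rim_is_convex_arc(self):
        region = Difference(
            Rectangle((-300.0, -300.0), 600.0, 600.0), Disk((0.0, 0.0), 100.0)
        )
        t, cls = region.boundary_tangent_and_class((100.0, 0.0))
        assert cls is BoundaryClass.CONVEX_ARC
        np.testing.assert_allclose(t, [0.0, -1.0], atol=1e-12)

    def test_corner_is_unclassifiable(self):
        rect = Rectangle((0.0, 0.0), 10.0, 10.0)
        with pytest.raises(CornerPointError):
            rect.boundary_tangent_and_class((0.0, 0.0))

    def test_point_off_boundary_rejected(self, disk50):
        with pytest.raises(NotOnBoundaryError):
            disk50.boundary_tangent_and_class((10.0, 0.0))

    @settings(max_examples=50, derandomize=True)
    @given(angle=st.floats(0.0, 2.0 * math.pi), r=st.floats(5.0, 80.0))
    def test_tangent_is_unit_norm(self, angle, r):
        disk = Disk((3.0, -7.0), r)
        p = disk.center + r * np.array([math.cos(angle), math.sin(angle)])
        t, _ = disk.boundary_tangent_and_class(p, tol=1e-6)
        assert np.linalg.norm(t) == pytest.approx(1.0, abs=1e-9)

    @settings(max_examples=30, derandomize=True)
    @given(
        dx=st.floats(-100, 100), dy=st.floats(-100, 100),
        rot=st.floats(0.0, 2.0 * math.pi),
    )
    def test_boundary_class_invariant_under_rigid_motion(self, dx, dy, rot):
        # a triangle rotated and translated keeps linear boundaries
        base = np.array([[0.0, 0.0], [30.0, 0.0], [15.0, 25.0]])
        R = np.array([[math.cos(rot), -math.sin(rot)], [math.sin(rot), math.cos(rot)]])
        moved = base @ R.T + (dx, dy)
        poly = PolygonRegion(moved)
        mid = (moved[0] + moved[1]) / 2.0
        _, cls = poly.boundary_tangent_and_class(mid, tol=1e-6)
        assert cls is BoundaryClass.LINEAR


class TestPolygon:
    def test_rejects_self_intersecting(self):
        with pytest.raises(ValueError):
            PolygonRegion([(0, 0), (10, 10), (10, 0), (0, 10)])

    def test_tangent_follows_ccw_interior(self):
        poly = PolygonRegion([(0, 0), (10, 0), (10, 10), (0, 10)])
        t, _ = poly.boundary_tangent_and_class((5.0, 0.0))
        np.testing.assert_allclose(t, [1.0, 0.0])


class TestConfigRoundTrip:
    @pytest.mark.parametrize(
        "cfg",
        [
            {"kind": "disk", "center_um": [0.0, 0.0], "radius_um": 50.0},
            {"kind": "rectangle", "corner_um": [0.0, 0.0], "width_um": 15.0,
             "height_um": 15.0},
            {"kind": "polygon", "vertices_um": [[0.0, 0.0], [30.0, 0.0], [15.0, 25.0]]},
            {"kind": "difference",
             "outer": {"kind": "rectangle", "corner_um": [-300.0, -300.0],
                       "width_um": 600.0, "height_um": 600.0},
             "hole": {"kind": "disk", "center_um": [0.0, 0.0], "radius_um": 100.0}},
        ],
    )
    def test_round_trip(self, cfg):
        region = region_from_dict(cfg)
        assert region_to_dict(region) == cfg

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown region kind"):
            region_from_dict({"kind": "blob"})

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown region config keys"):
            region_from_dict({"kind": "disk", "radius_um": 50.0, "colour": "red"})


def test_point2d_requires_finite():
    with pytest.raises(ValueError):
        Point2D(math.nan, 0.0)
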