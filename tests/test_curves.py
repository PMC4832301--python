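"""Feature-point detection, curve tracing, continuation and the catalog."""

import numpy as np
import pytest

from conftest import random_rotation
from curvemark.curvature import compute_fields
from curvemark.curves import (AnatomicalCurveSpec, ConnectivityError,
                              SeedError, TracedCurve, closest_point_on_polyline,
                              continue_curve, curve_catalog,
                              detect_feature_points, trace_curve)
from curvemark.io import DimensionError, NamedCurve, SurfaceMesh
from curvemark.phantoms import PhantomSpec, make_surface


@pytest.fixture(scope="module")
def ridge_fields(ridge_phantom):
    mesh, truth = ridge_phantom
    return mesh, truth, compute_fields(mesh, radius=2.5)


class TestDetection:
    def test_ridge_points_on_crest(self, ridge_fields):
        """Flagged vertices lie within one grid spacing of the crest x=0."""
        mesh, truth, fields = ridge_fields
        fps = detect_feature_points(fields, "ridge")
        assert len(fps) > 0
        assert np.abs(fps.points[:, 0]).max() <= 1.0

    def test_non_maximum_suppression_one_per_row(self, ridge_fields):
        """At most one flagged vertex per mesh row transverse to the crest."""
        mesh, truth, fields = ridge_fields
        fps = detect_feature_points(fields, "ridge")
        ys = np.round(fps.points[:, 1], 6)
        assert len(np.unique(ys)) == len(ys)

    def test_sphere_has_no_ridge_points(self, sphere50):
        mesh, _ = sphere50
        fields = compute_fields(mesh, radius=10.0)
        fps = detect_feature_points(fields, "ridge")
        assert len(fps) == 0  # every vertex is a spherical cap

    def test_plane_has_no_feature_points(self):
        mesh, _ = make_surface(PhantomSpec(kind="quadric-patch", kappa1=0.0,
                                           kappa2=0.0, spacing=1.0,
                                           extent=8.0))
        fields = compute_fields(mesh, radius=4.0)
        for kind in ("ridge", "rut"):
            assert len(detect_feature_points(fields, kind)) == 0

    def test_rigid_motion_invariance(self, ridge_phantom):
        """Rotating + translating the mesh flags the same vertex set."""
        mesh, _ = ridge_phantom
        base = detect_feature_points(compute_fields(mesh, radius=2.5),
                                     "ridge")
        R = random_rotation(7)
        moved = SurfaceMesh(vertices=mesh.vertices @ R.T + [13.0, -4.0, 8.0],
                            faces=mesh.faces)
        rotated = detect_feature_points(compute_fields(moved, radius=2.5),
                                        "ridge")
        assert np.array_equal(np.sort(base.indices), np.sort(rotated.indices))

    def test_empty_fields_rejected(self):
        from curvemark.curvature import (PrincipalCurvatureField,
                                         ShapeIndexField)
        empty = np.empty(0)
        pcf = PrincipalCurvatureField(empty, empty, empty.reshape(0, 3),
                                      empty.reshape(0, 3),
                                      empty.reshape(0, 3),
                                      np.empty(0, dtype=bool), mesh=None)
        sif = ShapeIndexField(empty, np.empty(0, dtype=bool),
                              np.empty(0, dtype=object),
                              np.empty((0, 3), dtype=np.uint8))
        with pytest.raises(DimensionError):
            detect_feature_points((pcf, sif), "ridge")


class TestTracing:
    def test_trace_follows_crest(self, ridge_fields):
        mesh, truth, fields = ridge_fields
        fps = detect_feature_points(fields, "ridge")
        tc = trace_curve(fps, AnatomicalCurveSpec("crest", "ridge"),
                         seed=np.array([0.4, 0.0, 5.0]))
        assert np.abs(tc.curve.points[:, 0]).max() <= 1.0
        # ordered: strictly increasing cumulative arc length
        arc = tc.curve.arc_lengths()
        assert np.all(np.diff(arc) > 0)

    def test_no_jump_between_parallel_ridges(self):
        """Two crests farther apart than the link radius stay separate."""
        spec = PhantomSpec(kind="composite-face", height=5.0, width=2.0,
                           spacing=1.0, extent=15.0, ridge_offset=0.0)
        # build two parallel ridges by summing two x-offset Gaussians
        xs = np.arange(-15.0, 15.5, 1.0)
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        Z = 5 * np.exp(-(X - 7) ** 2 / 8) + 5 * np.exp(-(X + 7) ** 2 / 8)
        n = len(xs)
        idx = np.arange(n * n).reshape(n, n)
        f1 = np.stack([idx[:-1, :-1], idx[1:, :-1], idx[1:, 1:]], -1)
        f2 = np.stack([idx[:-1, :-1], idx[1:, 1:], idx[:-1, 1:]], -1)
        mesh = SurfaceMesh(
            vertices=np.column_stack([X.ravel(), Y.ravel(), Z.ravel()]),
            faces=np.concatenate([f1.reshape(-1, 3), f2.reshape(-1, 3)]))
        fields = compute_fields(mesh, radius=2.5)
        fps = detect_feature_points(fields, "ridge")
        tc = trace_curve(fps, None, seed=np.array([7.0, 0.0, 5.0]))
        assert tc.curve.points[:, 0].min() > 0  # never crosses to x = -7

    def test_empty_feature_set_is_seed_error(self, ridge_fields):
        mesh, truth, fields = ridge_fields
        from curvemark.curves import FeaturePointSet
        empty = FeaturePointSet(mesh=mesh,
                                indices=np.empty(0, dtype=np.int64),
                                strength=np.empty(0), kind="ridge",
                                directions=np.empty((0, 3)))
        with pytest.raises(SeedError):
            trace_curve(empty, None, seed=np.zeros(3))

    def test_far_seed_is_seed_error(self, ridge_fields):
        mesh, truth, fields = ridge_fields
        fps = detect_feature_points(fields, "ridge")
        with pytest.raises(SeedError):
            trace_curve(fps, None, seed=np.array([200.0, 0.0, 0.0]))


class TestContinuation:
    def test_same_direction_along_flat_crest(self, ridge_phantom):
        """A straight ridge continued 10 mm ends 10 mm down the crest."""
        mesh, _ = ridge_phantom
        fields = compute_fields(mesh, radius=2.5)
        fps = detect_feature_points(fields, "ridge")
        tr = trace_curve(fps, None, seed=np.array([0.0, -14.0, 5.0]))
        pts = tr.curve.points[tr.curve.points[:, 1] <= 0.0]
        half = TracedCurve(NamedCurve("half", pts, kind="ridge"),
                           np.zeros(len(pts), dtype=np.int64))
        ext = continue_curve(half, mesh, "same-direction", length=10.0)
        end = ext.curve.points[-1]
        expected = pts[-1] + np.array([0.0, 10.0, 0.0])
        assert np.linalg.norm(end - expected) <= 1.0
        assert ext.continuation_mask.sum() > 0
        assert np.all(ext.vertex_ids[ext.continuation_mask] == -1)

    def test_closest_point_on_curve_ends_at_foot(self, ridge_phantom):
        """Continuation toward a transverse curve ends at the analytic
        foot of perpendicular (brute-force distance oracle)."""
        mesh, _ = ridge_phantom
        pts = np.column_stack([np.zeros(10), np.linspace(-14, -5, 10),
                               np.full(10, 5.0)])
        half = TracedCurve(NamedCurve("half", pts, kind="ridge"),
                           np.zeros(10, dtype=np.int64))
        t = np.linspace(-15, 15, 61)
        target = NamedCurve("transverse", np.column_stack(
            [t, np.full_like(t, 8.0), 5.0 * np.exp(-t**2 / 18.0)]),
            kind="ridge")
        ext = continue_curve(half, mesh, "closest-point-on-curve",
                             target=target)
        # oracle: brute-force minimum distance from the trace end
        d = np.linalg.norm(target.points - pts[-1], axis=1)
        foot = target.points[np.argmin(d)]
        assert np.linalg.norm(ext.curve.points[-1] - foot) <= 1.0

    def test_single_point_curve_rejected(self, ridge_phantom):
        mesh, _ = ridge_phantom
        single = TracedCurve.__new__(TracedCurve)  # bypass NamedCurve min-2
        single.curve = type("C", (), {"points": np.zeros((1, 3))})()
        single.vertex_ids = np.zeros(1, dtype=np.int64)
        single.continuation_mask = np.zeros(1, dtype=bool)
        with pytest.raises(ValueError):
            continue_curve(single, mesh, "same-direction", length=5.0)

    def test_leaving_the_mesh_is_connectivity_error(self, ridge_phantom):
        mesh, _ = ridge_phantom
        pts = np.column_stack([np.zeros(5), np.linspace(5, 14, 5),
                               np.full(5, 5.0)])
        tc = TracedCurve(NamedCurve("c", pts, kind="ridge"),
                         np.zeros(5, dtype=np.int64))
        with pytest.raises(ConnectivityError):
            continue_curve(tc, mesh, "toward-target",
                           target=np.array([0.0, 500.0, 0.0]))


class TestCatalog:
    def test_sixteen_entries(self):
        catalog = curve_catalog()
        assert len(catalog) == 16
        assert len({c.name for c in catalog}) == 16

    def test_feature_kind_census(self):
        kinds = {}
        for c in curve_catalog():
            kinds.setdefault(c.kind, []).append(c.name)
        assert len(kinds["ridge"]) == 8
        assert len(kinds["rut"]) == 3
        assert kinds["edge"] == ["lower/upper eye lid"]
        assert len(kinds["continuation"]) == 4

    def test_midline_chin_targets_mandible(self):
        chin = {c.name: c for c in curve_catalog()}["mid-line chin"]
        assert chin.kind == "continuation"
        assert chin.mode == "closest-point-on-curve"
        assert chin.target_curve == "mandible"

    def test_continuation_targets_resolve(self):
        catalog = curve_catalog()
        names = {c.name for c in catalog}
        for c in catalog:
            if c.kind == "continuation":
                assert (c.target_curve in names) or (c.target_feature
                                                     is not None)
                assert c.source_curve in names


def test_closest_point_on_polyline_matches_bruteforce():
    rng = np.random.default_rng(5)
    poly = np.cumsum(rng.normal(size=(30, 3)), axis=0)
    for _ in range(20):
        p = rng.uniform(-5, 5, 3)
        q, d = closest_point_on_polyline(p, poly)
        dense = []
        for a, b in zip(poly[:-1], poly[1:]):
            ts = np.linspace(0, 1, 200)[:, None]
            dense.append(np.min(np.linalg.norm(a + ts * (b - a) - p, axis=1)))
        assert d == pytest.approx(min(dense), abs=1e-3)
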