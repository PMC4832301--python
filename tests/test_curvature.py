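"""Quadric fitting, principal curvatures, shape index and classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from curvemark.curvature import (DegenerateNeighborhoodError,
                                 InsufficientSupportError, classify_shape,
                                 compute_fields, fit_local_quadric,
                                 principal_curvatures, shape_index)
from curvemark.io import SurfaceMesh
from curvemark.phantoms import PhantomSpec, make_surface


def _patch_mesh(f, extent=6.0, spacing=1.0):
    xs = np.arange(-extent, extent + 0.5 * spacing, spacing)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    Z = f(X, Y)
    n = len(xs)
    idx = np.arange(n * n).reshape(n, n)
    f1 = np.stack([idx[:-1, :-1], idx[1:, :-1], idx[1:, 1:]], -1).reshape(-1, 3)
    f2 = np.stack([idx[:-1, :-1], idx[1:, 1:], idx[:-1, 1:]], -1).reshape(-1, 3)
    return SurfaceMesh(
        vertices=np.column_stack([X.ravel(), Y.ravel(), Z.ravel()]),
        faces=np.concatenate([f1, f2]))


class TestLocalQuadric:
    def test_exact_model_recovery(self):
        mesh = _patch_mesh(lambda x, y: 0.5 * (0.02 * x**2 + 0.02 * y**2))
        center = mesh.n_vertices // 2
        q = fit_local_quadric(mesh, center, radius=5.0)
        # frame normal at the center is +z, so a, c are the raw curvatures
        assert abs(q.a - 0.02) < 1e-8
        assert abs(q.c - 0.02) < 1e-8
        assert abs(q.b) < 1e-8

    def test_planar_patch_all_zero(self):
        mesh = _patch_mesh(lambda x, y: np.zeros_like(x))
        q = fit_local_quadric(mesh, mesh.n_vertices // 2, radius=5.0)
        assert max(abs(q.a), abs(q.b), abs(q.c)) < 1e-8

    def test_insufficient_support(self):
        mesh = _patch_mesh(lambda x, y: np.zeros_like(x), extent=2, spacing=1)
        with pytest.raises(InsufficientSupportError) as exc:
            fit_local_quadric(mesh, 0, radius=1.1)
        assert exc.value.n_neighbors < 6

    def test_collinear_neighborhood_is_degenerate(self):
        # points on a single line: the quadric is unidentifiable
        verts = np.column_stack([np.linspace(0, 10, 12), np.zeros(12),
                                 np.zeros(12)])
        faces = np.array([[i, i + 1, (i + 2) % 12] for i in range(10)])
        mesh = SurfaceMesh(vertices=verts, faces=faces,
                           normals=np.tile([0.0, 0.0, 1.0], (12, 1)))
        with pytest.raises(DegenerateNeighborhoodError):
            fit_local_quadric(mesh, 5, radius=20.0)


class TestPrincipalCurvatures:
    def _quadric(self, a, b, c, e=0.0, f=0.0):
        from curvemark.curvature import LocalQuadric
        return LocalQuadric(origin=np.zeros(3), t1=np.array([1.0, 0, 0]),
                            t2=np.array([0.0, 1, 0]),
                            normal=np.array([0.0, 0, 1]), a=a, b=b, c=c,
                            e=e, f=f, n_points=10, radius=5.0)

    def test_umbilic_diagonal(self):
        k1, k2, _, _ = principal_curvatures(self._quadric(0.02, 0.0, 0.02))
        assert k1 == pytest.approx(0.02, abs=1e-12)
        assert k2 == pytest.approx(0.02, abs=1e-12)

    def test_saddle_directions(self):
        k1, k2, e1, e2 = principal_curvatures(self._quadric(0.05, 0.0, -0.05))
        assert (k1, k2) == pytest.approx((0.05, -0.05))
        assert abs(e1 @ np.array([1.0, 0, 0])) > 1 - 1e-9
        assert abs(e1 @ e2) < 1e-9

    def test_ordering_and_orthogonality_random(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c = rng.uniform(-0.1, 0.1, 3)
            e, f = rng.uniform(-0.3, 0.3, 2)
            k1, k2, e1, e2 = principal_curvatures(self._quadric(a, b, c, e, f))
            assert k1 >= k2
            assert abs(e1 @ e2) < 1e-9

    def test_sphere_curvature_within_5_percent(self, sphere50):
        mesh, truth = sphere50
        pcf, _ = compute_fields(mesh, radius=10.0)
        assert pcf.valid.all()
        for k in (pcf.kappa1, pcf.kappa2):
            rel = np.abs(k - (-0.02)) / 0.02
            assert rel.max() < 0.05


class TestShapeIndex:
    def test_printed_examples(self):
        assert shape_index(0.02, 0.02) == -1.0          # spherical cup
        assert shape_index(0.05, -0.05) == 0.0          # symmetric saddle
        assert shape_index(-0.02, -0.02) == 1.0         # spherical cap
        # direct evaluation of the formula: (2/pi) atan(2)
        assert shape_index(-0.01, -0.03) == pytest.approx(
            2.0 / np.pi * np.arctan(2.0), abs=1e-12)

    def test_requires_ordering(self):
        with pytest.raises(ValueError):
            shape_index(-0.05, 0.05)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(k1=st.floats(-1, 1), gap=st.floats(0, 1),
           c=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, k1, gap, c):
        """Multiplying both curvatures by c > 0 leaves S unchanged."""
        k2 = k1 - gap
        if abs(k1) < 1e-12 and abs(k2) < 1e-12:
            return
        s0 = shape_index(k1, k2)
        s1 = shape_index(c * k1, c * k2)
        assert s1 == pytest.approx(s0, abs=1e-9)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(k1=st.floats(-1, 1), gap=st.floats(1e-6, 1))
    def test_flip_antisymmetry(self, k1, gap):
        """Flipping the surface (negating both curvatures) negates S."""
        k2 = k1 - gap
        assert shape_index(-k2, -k1) == pytest.approx(
            -shape_index(k1, k2), abs=1e-9)


class TestClassification:
    @pytest.mark.parametrize("S,expected", [
        (-1.0, "spherical cup"),
        (-0.75, "trough"),
        (-0.5, "rut"),
        (-0.25, "saddle rut"),
        (0.0, "saddle"),
        (0.25, "saddle ridge"),
        (0.5, "ridge"),
        (0.7048, "dome"),
        (1.0, "spherical cap"),
        (7 / 8, "spherical cap"),      # left-closed cap band
        (3 / 8, "ridge"),              # left-closed interior boundary
    ])
    def test_bands(self, S, expected):
        assert classify_shape(S)[0] == expected

    def test_planar_flag(self):
        assert classify_shape(np.nan)[0] == "flat"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_shape(1.5)


class TestComputeFields:
    def test_sphere_all_caps(self, sphere50):
        mesh, _ = sphere50
        _, sif = compute_fields(mesh, radius=10.0)
        assert (sif.categories == "spherical cap").all()
        assert np.all(sif.S[~sif.planar] > 7 / 8)

    def test_saddle_phantom_center(self):
        mesh, truth = make_surface(PhantomSpec(
            kind="quadric-patch", kappa1=0.05, kappa2=-0.05, spacing=1.0,
            extent=10.0))
        pcf, sif = compute_fields(mesh, radius=4.0)
        center = np.linalg.norm(mesh.vertices[:, :2], axis=1) < 2.0
        assert np.all(np.abs(sif.S[center]) < 1 / 8)

    def test_plane_planar_flagged(self):
        mesh = _patch_mesh(lambda x, y: np.zeros_like(x), extent=8)
        pcf, sif = compute_fields(mesh, radius=4.0)
        assert sif.planar[pcf.valid].all()
        assert (sif.categories[pcf.valid] == "flat").all()

    def test_error_decreases_with_density(self):
        """Sphere curvature error shrinks as the mesh is refined."""
        errs = []
        for spacing in (10.0, 5.0, 2.5):
            mesh, _ = make_surface(PhantomSpec(kind="sphere", radius=50.0,
                                               spacing=spacing))
            radius = 3.0 * float(np.median(mesh.edge_lengths()))
            pcf, _ = compute_fields(mesh, radius=radius)
            errs.append(np.abs(pcf.kappa1[pcf.valid] + 0.02).mean())
        assert errs[0] > errs[1] > errs[2]

    def test_noise_free_quadric_recovery(self):
        """Estimated curvatures match the generating quadric exactly."""
        mesh, _ = make_surface(PhantomSpec(
            kind="quadric-patch", kappa1=0.03, kappa2=0.01, spacing=1.0,
            extent=8.0))
        center = int(np.argmin(np.linalg.norm(mesh.vertices[:, :2], axis=1)))
        q = fit_local_quadric(mesh, center, radius=4.0)
        k1, k2, _, _ = principal_curvatures(q)
        assert k1 == pytest.approx(0.03, abs=1e-6)
        assert k2 == pytest.approx(0.01, abs=1e-6)
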