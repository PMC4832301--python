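"""P-spline smoothing, curve curvature, peaks, crossings and landmark rules."""

import numpy as np
import pytest

from conftest import random_rotation
from curvemark.io import NamedCurve
from curvemark.landmarks import (CurvatureProfile, NoPeakError, SupportError,
                                 apply_landmark_rules, crossing_point,
                                 curvature_from_derivatives, curve_curvature,
                                 dominant_peak, effective_df,
                                 landmark_catalog, smooth_curve)
from curvemark.phantoms import PhantomSpec, make_curve


class TestSmoothing:
    def test_straight_segment_reproduced_exactly(self):
        """Linear data lie in the penalty null space: exact for any df."""
        t = np.linspace(0.0, 1.0, 40)
        line = np.column_stack([30 * t, 10 * t, 5 * t])
        for df in (3, 8, 12):
            sc = smooth_curve(line, df=df)
            fit = sc.evaluate(np.linspace(0, sc.length, 40))
            start, end = line[0], line[-1]
            u = (end - start) / np.linalg.norm(end - start)
            offsets = fit - start
            dist = np.linalg.norm(offsets - (offsets @ u)[:, None] * u, axis=1)
            assert dist.max() < 1e-6

    def test_noisy_circle_radius_recovered(self):
        """df=8 smoothing of a noisy 10 mm circle: fitted radius 10 +- 0.2
        (algebraic least-squares circle as the oracle)."""
        curve, _ = make_curve(PhantomSpec(kind="circle-curve", radius=10.0,
                                          noise_sd=0.1, seed=4), n_points=200)
        sc = smooth_curve(curve, df=8)
        pts = sc.evaluate(np.linspace(0.03 * sc.length, 0.97 * sc.length, 300))
        x, y = pts[:, 0], pts[:, 1]
        A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
        sol, *_ = np.linalg.lstsq(A, x**2 + y**2, rcond=None)
        radius = np.sqrt(sol[2] + sol[0]**2 + sol[1]**2)
        assert radius == pytest.approx(10.0, abs=0.2)

    def test_effective_df_matches_request(self):
        curve, _ = make_curve(PhantomSpec(kind="circle-curve", radius=10.0),
                              n_points=120)
        sc = smooth_curve(curve, df=8)
        assert effective_df(sc, curve) == pytest.approx(8.0, abs=0.01)

    def test_too_few_points(self):
        with pytest.raises(SupportError):
            smooth_curve(np.random.default_rng(0).normal(size=(6, 3)), df=8)


class TestCurveCurvature:
    def test_circle_closed_form(self):
        """kappa = 1/r for an arc-length parameterised planar circle."""
        r = 10.0
        s = np.linspace(0.0, np.pi * r, 200)
        th = s / r
        d1 = np.column_stack([-np.sin(th), np.cos(th), np.zeros_like(th)])
        d2 = np.column_stack([-np.cos(th) / r, -np.sin(th) / r,
                              np.zeros_like(th)])
        prof = curvature_from_derivatives(s, d1, d2)
        assert np.abs(prof.kappa - 1.0 / r).max() < 1e-6

    def test_straight_line_zero(self):
        t = np.linspace(0, 1, 60)
        sc = smooth_curve(np.column_stack([t * 20, t * 7, -t * 3]), df=4)
        prof = curve_curvature(sc)
        assert np.nanmax(prof.kappa) < 1e-9

    def test_helix_closed_form(self):
        """kappa = a/(a^2+b^2) = 0.08 for a helix with a=10, b=5."""
        a, b = 10.0, 5.0
        th = np.linspace(0, 4 * np.pi, 300)
        c = np.sqrt(a * a + b * b)
        s = c * th
        d1 = np.column_stack([-a * np.sin(th), a * np.cos(th),
                              np.full_like(th, b)]) / c
        d2 = np.column_stack([-a * np.cos(th), -a * np.sin(th),
                              np.zeros_like(th)]) / c**2
        prof = curvature_from_derivatives(s, d1, d2)
        assert np.abs(prof.kappa - 0.08).max() < 1e-9

    def test_helix_through_pspline_pipeline(self):
        curve, truth = make_curve(PhantomSpec(kind="helix-curve",
                                              helix_a=10.0, helix_b=5.0),
                                  n_points=400)
        sc = smooth_curve(curve, df=30, n_basis=40)
        prof = curve_curvature(sc)
        interior = prof.kappa[60:-60]
        assert np.abs(interior - 0.08).max() / 0.08 < 0.02

    def test_planar_formula_agreement(self):
        """On planar curves the space formula equals |x'y''-y'x''|/speed^3."""
        rng = np.random.default_rng(1)
        t = np.linspace(0, 2, 100)
        d1 = np.column_stack([1 + 0.3 * np.sin(t), 0.5 * np.cos(t),
                              np.zeros_like(t)])
        d2 = np.column_stack([0.3 * np.cos(t), -0.5 * np.sin(t),
                              np.zeros_like(t)])
        prof = curvature_from_derivatives(t, d1, d2)
        planar = np.abs(d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]) \
            / (d1[:, 0]**2 + d1[:, 1]**2) ** 1.5
        assert np.abs(prof.kappa - planar).max() < 1e-9

    def test_parameterisation_invariance(self):
        """Non-uniform resampling changes kappa at matched points by < 1%."""
        theta = np.linspace(0, 1.5 * np.pi, 300)
        circle = np.column_stack([10 * np.cos(theta), 10 * np.sin(theta),
                                  np.zeros_like(theta)])
        warp = np.linspace(0, 1, 300) ** 1.5 * 1.5 * np.pi
        warped = np.column_stack([10 * np.cos(warp), 10 * np.sin(warp),
                                  np.zeros_like(warp)])
        k = []
        for pts in (circle, warped):
            sc = smooth_curve(pts, df=20, n_basis=30)
            prof = curve_curvature(sc)
            mid = prof.s[len(prof.s) // 2]
            k.append(np.interp(mid, prof.s, prof.kappa))
        assert abs(k[0] - k[1]) / k[0] < 0.01

    def test_profile_nonnegative(self):
        with pytest.raises(ValueError):
            CurvatureProfile(s=np.arange(3.0), kappa=np.array([0.1, -0.1, 0.2]),
                             singular=np.zeros(3, dtype=bool))


class TestDominantPeak:
    def _profile(self, kappa):
        s = np.linspace(0.0, 100.0, len(kappa))
        return CurvatureProfile(s=s, kappa=np.asarray(kappa, float),
                                singular=np.zeros(len(kappa), dtype=bool))

    def test_gaussian_bump(self):
        s = np.linspace(0, 100, 501)
        prof = self._profile(np.exp(-(s - 30.0) ** 2 / 20.0))
        s_star, k_star, dom = dominant_peak(prof)
        assert s_star == pytest.approx(30.0, abs=0.2)
        assert dom == np.inf  # single peak

    def test_tied_maxima_take_smaller_s(self):
        s = np.linspace(0, 100, 501)
        k = np.exp(-(s - 30.0) ** 2 / 20.0) + np.exp(-(s - 70.0) ** 2 / 20.0)
        with pytest.warns(UserWarning, match="equal curvature maxima"):
            s_star, _, dom = dominant_peak(self._profile(k))
        assert s_star == pytest.approx(30.0, abs=0.2)

    def test_constant_profile_has_no_peak(self):
        with pytest.raises(NoPeakError):
            dominant_peak(self._profile(np.full(101, 0.3)))

    def test_window_restriction(self):
        s = np.linspace(0, 100, 501)
        k = 2 * np.exp(-(s - 80.0) ** 2 / 20.0) + np.exp(-(s - 20.0) ** 2 / 20.0)
        s_star, _, _ = dominant_peak(self._profile(k), window=(0.0, 50.0))
        assert s_star == pytest.approx(20.0, abs=0.2)


class TestCrossing:
    def test_exact_intersection(self):
        a = np.array([1.0, 2.0, 3.0]) + np.outer(np.linspace(-5, 5, 11),
                                                 [1.0, 0, 0])
        b = np.array([1.0, 2.0, 3.0]) + np.outer(np.linspace(-4, 6, 9),
                                                 [0.0, 1, 0.3])
        res = crossing_point(NamedCurve("a", a), NamedCurve("b", b))
        assert np.abs(res.point - [1, 2, 3]).max() < 1e-6
        assert res.distance < 1e-9
        assert not res.out_of_tolerance

    def test_skew_lines_flagged(self):
        """Skew lines 2 mm apart: midpoint returned, flagged at tol=1."""
        a = np.outer(np.linspace(-5, 5, 21), [1.0, 0, 0])
        b = np.array([0.0, 0, 2.0]) + np.outer(np.linspace(-5, 5, 21),
                                               [0.0, 1, 0])
        res = crossing_point(NamedCurve("a", a), NamedCurve("b", b), tol=1.0)
        # closed-form: minimal distance between the skew lines is 2
        assert res.distance == pytest.approx(2.0, abs=1e-9)
        assert np.abs(res.point - [0, 0, 1]).max() < 1e-9
        assert res.out_of_tolerance

    def test_self_crossing_degenerate(self):
        a = NamedCurve("a", np.outer(np.linspace(0, 5, 6), [1.0, 0, 0]))
        with pytest.warns(UserWarning, match="degenerate"):
            res = crossing_point(a, a)
        assert res.distance == 0.0


class TestLandmarkCatalog:
    def test_rule_census(self):
        rules = [r for r in landmark_catalog() if not r.optional]
        single = [r for r in rules if len(r.source_curves) == 1]
        crossing = [r for r in rules if r.kind == "crossing"]
        assert len(single) == 8
        assert len(crossing) == 9

    def test_otobasion_inferius_is_endpoint(self):
        rule = {r.name: r for r in landmark_catalog()}["otobasion inferius"]
        assert rule.kind == "endpoint"
        assert rule.source_curves == ("ear rim",)

    def test_pogonion_fallback(self):
        rule = {r.name: r for r in landmark_catalog()}["pogonion"]
        assert rule.kind == "fallback-distance"
        assert set(rule.reference_landmarks) == {"sublabiale", "gnathion"}


class TestApplyRules:
    def test_gnathion_at_exact_polyline_crossing(self):
        chin = NamedCurve("mid-line chin", np.column_stack(
            [np.zeros(21), np.linspace(-20, 0, 21), np.zeros(21)]))
        mand = NamedCurve("mandible", np.column_stack(
            [np.linspace(-10, 10, 21), np.full(21, -6.0), np.zeros(21)]))
        res = apply_landmark_rules(
            {"mid-line chin": chin, "mandible": mand},
            [r for r in landmark_catalog() if r.name == "gnathion"])
        assert np.abs(res.config["gnathion"] - [0, -6, 0]).max() < 1e-6

    def test_sellion_on_arc_chain(self):
        """The tight 8 mm arc inside a 40/8/40 chain carries the peak."""
        curve, truth = make_curve(PhantomSpec(
            kind="arc-chain", arc_radii=(40.0, 8.0, 40.0),
            arc_lengths=(10.0, 8.0, 20.0)), n_points=150)
        res = apply_landmark_rules(
            {"mid-line nasal profile": curve},
            [r for r in landmark_catalog() if r.name == "sellion"])
        i = np.argmin(np.abs(truth.s - truth.peak_s))
        assert np.linalg.norm(res.config["sellion"] - curve.points[i]) < 1.0

    def test_missing_curves_reported_not_raised(self):
        chin = NamedCurve("mid-line chin", np.column_stack(
            [np.zeros(21), np.linspace(-20, 0, 21), np.zeros(21)]))
        res = apply_landmark_rules({"mid-line chin": chin})
        assert "alare" in res.skipped
        assert "pronasale" in res.skipped
        assert "alar" in res.skipped["alare"]
        assert "alar" in res.skipped["pronasale"]

    def test_rigid_motion_equivariance(self):
        """Rotating + translating all curves moves landmarks identically."""
        curve, _ = make_curve(PhantomSpec(
            kind="arc-chain", arc_radii=(40.0, 8.0, 40.0),
            arc_lengths=(10.0, 8.0, 20.0)), n_points=150)
        mand = NamedCurve("mandible", np.column_stack(
            [np.linspace(-10, 10, 21), np.full(21, -6.0), np.zeros(21)]))
        chin = NamedCurve("mid-line chin", np.column_stack(
            [np.zeros(21), np.linspace(-20, 0, 21), np.zeros(21)]))
        curves = {"mid-line nasal profile": curve, "mid-line chin": chin,
                  "mandible": mand}
        rules = [r for r in landmark_catalog()
                 if r.name in ("sellion", "gnathion")]
        base = apply_landmark_rules(curves, rules)
        R = random_rotation(11)
        t = np.array([5.0, -7.0, 2.0])
        moved = {k: NamedCurve(k, c.points @ R.T + t, kind=c.kind)
                 for k, c in curves.items()}
        shifted = apply_landmark_rules(moved, rules)
        for name in base.config.names:
            expect = base.config[name] @ R.T + t
            assert np.abs(shifted.config[name] - expect).max() < 1e-6
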