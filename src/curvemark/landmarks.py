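"""Curve smoothing, curve curvature, and curvature-based landmark rules.

Anatomical curves are smoothed coordinate-wise with penalised B-splines
(p-splines): cubic B-splines on uniform knots with a second-order difference
penalty on the coefficients, the penalty weight solved so that the
smoother's effective degrees of freedom equal a requested value (default 8).
Because the smoother matrix depends only on the parameterisation, the same
penalty applies to x(s), y(s) and z(s) and the fit is exactly equivariant
under rigid motions.

The bending rate of a smoothed space curve (x(s), y(s), z(s)) is

    kappa(s) = sqrt((z''y' - y''z')^2 + (x''z' - z''x')^2
                    + (y''x' - x''y')^2) / (x'^2 + y'^2 + z'^2)^(3/2),

a non-negative norm ratio that is invariant to re-parameterisation and, for
planar curves, coincides with the magnitude of the signed planar curvature.

Landmarks are located on these curves by four rule kinds: the dominant peak
of the curvature profile (sellion, alare, cheilion, ...), the crossing of
two curves (nasion, pronasale, gnathion, ...), a curve endpoint (otobasion
inferius), or a furthest-from-a-chord fallback (pogonion, for chins too flat
for a curvature peak).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy.interpolate import BSpline

from .io import LandmarkConfiguration, NamedCurve

__all__ = [
    "SmoothedCurve",
    "CurvatureProfile",
    "LandmarkRule",
    "LandmarkingResult",
    "CrossingResult",
    "NoPeakError",
    "smooth_curve",
    "curve_curvature",
    "dominant_peak",
    "crossing_point",
    "landmark_catalog",
    "apply_landmark_rules",
    "DEFAULT_DF",
    "DEFAULT_GRID",
    "DEFAULT_CROSSING_TOL",
]

DEFAULT_DF = 8.0
DEFAULT_GRID = 512        # profile grid density (convergence-tested vs 2048)
DEFAULT_CROSSING_TOL = 2.0   # mm
DEFAULT_END_EXCLUSION = 0.05  # fraction of arc length dropped at each end
ALARE_DOMINANCE_MIN = 1.2


class NoPeakError(ValueError):
    """The curvature profile has no usable peak."""


class SupportError(ValueError):
    """Too few points to smooth at the requested degrees of freedom."""


# ---------------------------------------------------------------------------
# p-spline smoothing


def _uniform_bspline_knots(u0: float, u1: float, n_basis: int) -> np.ndarray:
    """Uniform (unclamped) cubic B-spline knots spanning [u0, u1].

    Uniform knots keep the second-difference penalty's null space exactly
    the linear functions, so straight data are reproduced for any penalty.
    """
    nseg = n_basis - 3
    h = (u1 - u0) / nseg
    return u0 + h * np.arange(-3, nseg + 4)


def _design_matrix(u: np.ndarray, knots: np.ndarray) -> np.ndarray:
    n_basis = len(knots) - 4
    B = np.zeros((len(u), n_basis))
    # avoid the open right end of the last basis interval
    uu = np.minimum(u, knots[-4] - 1e-12 * (knots[-1] - knots[0]))
    for j in range(n_basis):
        c = np.zeros(n_basis)
        c[j] = 1.0
        B[:, j] = BSpline(knots, c, 3, extrapolate=False)(uu)
    B[np.isnan(B)] = 0.0
    return B


def _edf(BtB: np.ndarray, P: np.ndarray, lam: float) -> float:
    return float(np.trace(np.linalg.solve(BtB + lam * P, BtB)))


@dataclass
class SmoothedCurve:
    """P-spline representation of a space curve with derivative access.

    Coordinates are cubic B-spline expansions in an internal chord-length
    parameter u; the public domain is fitted arc length s in [0, L] (mm),
    mapped to u through a dense monotone table.
    """

    splines: tuple[BSpline, BSpline, BSpline]
    u_domain: tuple[float, float]
    length: float
    df: float
    lam: float
    _s_table: np.ndarray = field(repr=False)
    _u_table: np.ndarray = field(repr=False)

    def _s_to_u(self, s: np.ndarray) -> np.ndarray:
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.length)
        return np.interp(s, self._s_table, self._u_table)

    def _eval_u(self, u: np.ndarray, der: int = 0) -> np.ndarray:
        u = np.atleast_1d(np.asarray(u, dtype=float))
        cols = [sp(u) if der == 0 else sp.derivative(der)(u)
                for sp in self.splines]
        return np.column_stack(cols)

    def evaluate(self, s) -> np.ndarray:
        """Points (n, 3) of the fitted curve at arc lengths ``s``."""
        return self._eval_u(self._s_to_u(s))

    def derivatives(self, s) -> tuple[np.ndarray, np.ndarray]:
        """First and second derivatives with respect to arc length.

        Uses the chain rule through the internal parameter:
        r_s = r_u u', r_ss = r_uu u'^2 + r_u u'' with u' = 1/|r_u| and
        u'' = -(r_u . r_uu)/|r_u|^4.
        """
        u = self._s_to_u(s)
        ru = self._eval_u(u, 1)
        ruu = self._eval_u(u, 2)
        speed = np.linalg.norm(ru, axis=1)
        speed = np.where(speed == 0, np.nan, speed)
        up = 1.0 / speed
        upp = -np.einsum("ij,ij->i", ru, ruu) / speed**4
        r_s = ru * up[:, None]
        r_ss = ruu * (up**2)[:, None] + ru * upp[:, None]
        return r_s, r_ss


def smooth_curve(polyline: NamedCurve | np.ndarray,
                 df: float = DEFAULT_DF,
                 n_basis: int | None = None) -> SmoothedCurve:
    """Fit a p-spline space curve through an ordered polyline.

    Each coordinate is fitted by cubic B-splines on uniform knots with a
    second-order difference penalty; the penalty weight is solved so that
    the effective degrees of freedom of the smoother equal ``df`` within
    0.01.  The curve is parameterised by chord length and re-normalised to
    the fitted arc length.
    """
    pts = polyline.points if isinstance(polyline, NamedCurve) else \
        np.asarray(polyline, dtype=float)
    n = len(pts)
    if n < df + 2:
        raise SupportError(f"{n} points cannot support df={df} "
                           f"(need >= {int(df) + 2})")
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(steps)])
    if n_basis is None:
        n_basis = int(min(n - 1, max(20, df + 10)))
    if df > n_basis - 1e-6:
        raise ValueError(f"df={df} exceeds the basis size {n_basis}")
    if df < 2:
        raise ValueError("df must be >= 2 (the penalty null space)")
    knots = _uniform_bspline_knots(u[0], u[-1], n_basis)
    B = _design_matrix(u, knots)
    D = np.diff(np.eye(n_basis), 2, axis=0)
    P = D.T @ D
    BtB = B.T @ B + 1e-12 * np.trace(B.T @ B) / n_basis * np.eye(n_basis)

    def gap(log_lam: float) -> float:
        return _edf(BtB, P, 10.0 ** log_lam) - df

    lo, hi = -12.0, 14.0
    if gap(lo) < 0:       # even an unpenalised fit has fewer df than asked
        lam = 10.0 ** lo
    elif gap(hi) > 0:
        lam = 10.0 ** hi
    else:
        log_lam = optimize.brentq(gap, lo, hi, xtol=1e-10)
        lam = 10.0 ** log_lam
    A = BtB + lam * P
    coefs = np.linalg.solve(A, B.T @ pts)
    splines = tuple(BSpline(knots, coefs[:, d], 3, extrapolate=True)
                    for d in range(3))

    # re-normalise: build the arc-length table of the fitted curve
    dense_u = np.linspace(u[0], u[-1], 4 * DEFAULT_GRID + 1)
    deriv = np.column_stack([sp.derivative(1)(dense_u) for sp in splines])
    speed = np.linalg.norm(deriv, axis=1)
    s_dense = np.concatenate([
        [0.0],
        np.cumsum(0.5 * (speed[1:] + speed[:-1]) * np.diff(dense_u)),
    ])
    return SmoothedCurve(
        splines=splines, u_domain=(float(u[0]), float(u[-1])),
        length=float(s_dense[-1]), df=float(df), lam=float(lam),
        _s_table=s_dense, _u_table=dense_u,
    )


def effective_df(curve: SmoothedCurve, polyline: NamedCurve | np.ndarray
                 ) -> float:
    """Trace of the smoother (hat) matrix actually applied to the data."""
    pts = polyline.points if isinstance(polyline, NamedCurve) else \
        np.asarray(polyline, dtype=float)
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(steps)])
    knots = curve.splines[0].t
    n_basis = len(knots) - 4
    B = _design_matrix(u, knots)
    D = np.diff(np.eye(n_basis), 2, axis=0)
    return _edf(B.T @ B, D.T @ D, curve.lam)


# ---------------------------------------------------------------------------
# curve curvature (bending-rate profile)


@dataclass
class CurvatureProfile:
    """kappa(s) >= 0 on a uniform arc-length grid; singular points flagged."""

    s: np.ndarray
    kappa: np.ndarray
    singular: np.ndarray

    def __post_init__(self) -> None:
        finite = self.kappa[~self.singular]
        if np.any(finite < 0):
            raise ValueError("curvature must be non-negative")


def curve_curvature(curve: SmoothedCurve, grid: int = DEFAULT_GRID
                    ) -> CurvatureProfile:
    """Evaluate the space-curve bending rate on a uniform arc-length grid.

    kappa = sqrt((z''y'-y''z')^2 + (x''z'-z''x')^2 + (y''x'-x''y')^2)
            / (x'^2+y'^2+z'^2)^(3/2), evaluated in the internal parameter
    (the expression is invariant to re-parameterisation).  Grid points with
    zero speed are flagged singular.
    """
    s = np.linspace(0.0, curve.length, grid)
    u = curve._s_to_u(s)
    d1 = curve._eval_u(u, 1)
    d2 = curve._eval_u(u, 2)
    return _profile_from_derivatives(s, d1, d2)


def curvature_from_derivatives(s, d1, d2) -> CurvatureProfile:
    """Bending-rate profile from explicit first/second derivative arrays.

    Useful when a curve is known analytically: pass the parameter grid and
    the derivatives of (x, y, z) with respect to it (any regular
    parameterisation; the expression is invariant to the choice).
    """
    return _profile_from_derivatives(s, np.asarray(d1, float),
                                     np.asarray(d2, float))


def _profile_from_derivatives(s, d1, d2) -> CurvatureProfile:
    xp, yp, zp = d1[:, 0], d1[:, 1], d1[:, 2]
    xpp, ypp, zpp = d2[:, 0], d2[:, 1], d2[:, 2]
    num = np.sqrt((zpp * yp - ypp * zp) ** 2
                  + (xpp * zp - zpp * xp) ** 2
                  + (ypp * xp - xpp * yp) ** 2)
    speed2 = xp**2 + yp**2 + zp**2
    singular = speed2 == 0
    kappa = np.full_like(num, np.nan)
    kappa[~singular] = num[~singular] / speed2[~singular] ** 1.5
    return CurvatureProfile(s=np.asarray(s, float), kappa=kappa,
                            singular=singular)


def dominant_peak(profile: CurvatureProfile,
                  exclude_ends: float = DEFAULT_END_EXCLUSION,
                  window: tuple[float, float] | None = None
                  ) -> tuple[float, float, float]:
    """Locate the global curvature maximum; returns (s*, kappa*, dominance).

    ``exclude_ends`` drops that fraction of arc length at each end (spline
    boundary derivatives are unreliable); ``window`` further restricts the
    search, e.g. to the named half of a curve.  The dominance ratio is the
    peak height over the second-highest interior local maximum (inf when
    there is none) and serves as a quality metric.  Exact ties resolve to
    the smaller s with a warning.
    """
    L = profile.s[-1] - profile.s[0]
    lo = profile.s[0] + exclude_ends * L
    hi = profile.s[-1] - exclude_ends * L
    if window is not None:
        lo, hi = max(lo, window[0]), min(hi, window[1])
    keep = (profile.s >= lo) & (profile.s <= hi) & ~profile.singular
    keep &= np.isfinite(profile.kappa)
    if np.count_nonzero(keep) < 3:
        raise NoPeakError("fewer than 3 usable grid points in the window")
    s = profile.s[keep]
    k = profile.kappa[keep]
    if np.ptp(k) == 0:
        raise NoPeakError("constant curvature profile: dominance undefined")
    k_max = k.max()
    at_max = np.nonzero(np.isclose(k, k_max, rtol=1e-9, atol=0.0))[0]
    i_star = at_max[0]
    # distinct tied maxima (not a flat plateau of adjacent grid points)
    if len(at_max) > 1 and np.any(np.diff(at_max) > 1):
        warnings.warn("multiple equal curvature maxima; returning the "
                      "smallest arc length")
    # interior local maxima for the dominance ratio
    interior = np.nonzero((k[1:-1] >= k[:-2]) & (k[1:-1] >= k[2:]))[0] + 1
    others = [k[i] for i in interior if abs(int(i) - int(i_star)) > 1
              and not np.isclose(k[i], k_max, rtol=1e-9)]
    dominance = float(k_max / max(others)) if others else np.inf
    return float(s[i_star]), float(k_max), dominance


# ---------------------------------------------------------------------------
# curve crossings


@dataclass
class CrossingResult:
    """Closest-approach midpoint of two curves with its QC distance."""

    point: np.ndarray
    distance: float
    out_of_tolerance: bool


def _segment_closest(p1, q1, p2, q2):
    """Closest points between segments [p1,q1] and [p2,q2]."""
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = d1 @ d1
    e = d2 @ d2
    f = d2 @ r
    if a <= 1e-30 and e <= 1e-30:
        return p1, p2
    if a <= 1e-30:
        t = np.clip(f / e, 0.0, 1.0)
        return p1, p2 + t * d2
    c = d1 @ r
    if e <= 1e-30:
        s = np.clip(-c / a, 0.0, 1.0)
        return p1 + s * d1, p2
    b = d1 @ d2
    denom = a * e - b * b
    s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > 1e-30 else 0.0
    t = (b * s + f) / e
    if t < 0.0:
        t = 0.0
        s = np.clip(-c / a, 0.0, 1.0)
    elif t > 1.0:
        t = 1.0
        s = np.clip((b - c) / a, 0.0, 1.0)
    return p1 + s * d1, p2 + t * d2


def _as_samples(curve, window: str | None = None,
                grid: int = DEFAULT_GRID) -> np.ndarray:
    if isinstance(curve, SmoothedCurve):
        s = np.linspace(0.0, curve.length, grid)
        pts = curve.evaluate(s)
    elif isinstance(curve, NamedCurve):
        pts = curve.points
    else:
        pts = np.asarray(curve, dtype=float)
    if window == "start-half":
        pts = pts[: max(2, len(pts) // 2 + 1)]
    elif window == "end-half":
        pts = pts[len(pts) // 2:]
    return pts


def crossing_point(a, b, tol: float = DEFAULT_CROSSING_TOL,
                   window_a: str | None = None,
                   window_b: str | None = None) -> CrossingResult:
    """Crossing of two curves as the midpoint of their closest approach.

    Traced polylines rarely intersect exactly, so the crossing is the
    midpoint of the closest pair of points, found by dense sampling plus
    exact local refinement over the neighbouring segments.  If the minimal
    distance exceeds ``tol`` the point is still returned, flagged
    out-of-tolerance.
    """
    if a is b:
        warnings.warn("curve crossed with itself: degenerate input")
        pts = _as_samples(a)
        return CrossingResult(point=pts[0].copy(), distance=0.0,
                              out_of_tolerance=False)
    A = _as_samples(a, window_a)
    B = _as_samples(b, window_b)
    d2 = np.sum((A[:, None, :] - B[None, :, :]) ** 2, axis=2)
    i, j = np.unravel_index(np.argmin(d2), d2.shape)
    best = (np.inf, None, None)
    for si in range(max(0, i - 2), min(len(A) - 1, i + 2)):
        for sj in range(max(0, j - 2), min(len(B) - 1, j + 2)):
            pa, pb = _segment_closest(A[si], A[si + 1], B[sj], B[sj + 1])
            d = float(np.linalg.norm(pa - pb))
            if d < best[0]:
                best = (d, pa, pb)
    if best[1] is None:  # single-point windows: fall back to sample pair
        best = (float(np.sqrt(d2[i, j])), A[i], B[j])
    dist, pa, pb = best
    return CrossingResult(point=0.5 * (pa + pb), distance=dist,
                          out_of_tolerance=dist > tol)


# ---------------------------------------------------------------------------
# the landmark catalog and rule dispatch


@dataclass
class LandmarkRule:
    """How one landmark is derived from the anatomical curves.

    ``kind`` is one of max-curvature-on-curve, crossing, endpoint or
    fallback-distance.  ``qualifiers`` align with ``source_curves`` and
    restrict the search to a half of the curve ("start-half" / "end-half",
    following the curve's tracing direction) or pick an endpoint
    ("start" / "end").
    """

    name: str
    kind: str
    source_curves: tuple[str, ...]
    qualifiers: tuple[str | None, ...] = ()
    reference_landmarks: tuple[str, ...] = ()
    optional: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        if not self.qualifiers:
            self.qualifiers = tuple(None for _ in self.source_curves)


def landmark_catalog(include_optional: bool = True) -> list[LandmarkRule]:
    """Curve-based landmark definitions.

    Eight landmarks on single curves (seven curvature maxima and one
    endpoint), nine at the crossing of two curves, plus the optional
    ektokonchion (for closed-eye images) and the pogonion
    furthest-from-chord fallback.  Curve tracing directions assumed:
    mid-line curves superior to inferior, paired/lateral curves medial to
    lateral, tragus superior to inferior, ear rim from helix to the
    preauricular lobe end.
    """
    R = LandmarkRule
    rules = [
        # --- single-curve rules
        R("sellion", "max-curvature-on-curve", ("mid-line nasal profile",),
          ("start-half",),
          description="maximal curvature at the nasal root end of the "
                      "mid-line nasal profile"),
        R("subnasale", "max-curvature-on-curve", ("mid-line nasal profile",),
          ("end-half",),
          description="maximal curvature at the base of the nasal septum"),
        R("alare", "max-curvature-on-curve", ("alar",),
          description="maximal curvature along the alar curve"),
        R("alare crest", "max-curvature-on-curve", ("alar",), ("end-half",),
          description="maximal curvature where the alar curve meets the "
                      "paranasal area"),
        R("cheilion", "max-curvature-on-curve", ("labial seal",),
          ("end-half",),
          description="maximal curvature at the lateral end of the labial "
                      "seal"),
        R("sublabiale", "max-curvature-on-curve", ("mid-line mentolabial",),
          description="maximal curvature of the mid-line curve through the "
                      "mentolabial sulcus"),
        R("tragion", "max-curvature-on-curve", ("tragus",), ("start-half",),
          description="maximal curvature at the superior end of the tragus "
                      "curve"),
        R("otobasion inferius", "endpoint", ("ear rim",), ("end",),
          description="the final point at the preauricular end of the ear "
                      "rim curve"),
        # --- crossing rules
        R("exocanthion", "crossing", ("lower eye lid", "upper eye lid"),
          ("end-half", "end-half"),
          description="crossing of the lateral ends of the eyelid curves"),
        R("endocanthion", "crossing", ("lower eye lid", "upper eye lid"),
          ("start-half", "start-half"),
          description="crossing of the medial ends of the eyelid curves"),
        R("nasion", "crossing", ("brow ridge", "mid-line nasal profile"),
          (None, "start-half"),
          description="brow ridge meets the superior extension of the "
                      "mid-line nasal profile"),
        R("pronasale", "crossing", ("mid-line nasal profile", "alar"),
          description="crossing of the mid-line nasal profile and alar "
                      "curves"),
        R("crista philtri", "crossing", ("upper lip", "philtrum ridge"),
          description="crossing of the upper lip and philtrum ridge curves"),
        R("labiale superius", "crossing", ("upper lip", "mid-line philtrum"),
          description="crossing of the upper lip and mid-line philtrum "
                      "curves"),
        R("stomion", "crossing", ("mid-line upper lip", "labial seal"),
          description="crossing of the mid-line upper lip and labial seal "
                      "curves"),
        R("labiale inferius", "crossing", ("lower lip", "mid-line lower lip"),
          description="crossing of the lower lip and mid-line lower lip "
                      "curves"),
        R("gnathion", "crossing", ("mid-line chin", "mandible"),
          description="crossing of the mid-line chin and mandible curves"),
    ]
    if include_optional:
        rules += [
            R("ektokonchion", "crossing", ("inferior orbital", "brow ridge"),
              optional=True,
              description="crossing of the extensions of the inferior "
                          "orbital and brow ridge curves"),
            R("pogonion", "fallback-distance", ("mid-line chin",),
              reference_landmarks=("sublabiale", "gnathion"), optional=True,
              description="point on the mid-line chin curve furthest from "
                          "the sublabiale-gnathion chord"),
        ]
    return rules


@dataclass
class LandmarkingResult:
    """Produced landmarks, per-landmark QC records, and skipped rules."""

    config: LandmarkConfiguration
    qc: dict[str, dict[str, object]]
    skipped: dict[str, str]


def _window_for(curve: SmoothedCurve, qualifier: str | None
                ) -> tuple[float, float] | None:
    if qualifier == "start-half":
        return (0.0, curve.length / 2.0)
    if qualifier == "end-half":
        return (curve.length / 2.0, curve.length)
    return None


def apply_landmark_rules(
    curves: Mapping[str, NamedCurve | SmoothedCurve],
    rules: Sequence[LandmarkRule] | None = None,
    *,
    df: float = DEFAULT_DF,
    grid: int = DEFAULT_GRID,
    crossing_tol: float = DEFAULT_CROSSING_TOL,
    exclude_ends: float = DEFAULT_END_EXCLUSION,
) -> LandmarkingResult:
    """Apply landmark rules to a named set of curves.

    Rules whose source curves (or reference landmarks) are unavailable are
    skipped and reported, not raised.  Polyline inputs are smoothed on
    demand for curvature rules; crossings run on the raw polylines (or on
    dense samples of already-smoothed curves).  If the alar curvature peak
    is weak (dominance < 1.2), alare is reported coincident with alare
    crest, the behaviour of flat alar curves.
    """
    if rules is None:
        rules = landmark_catalog()
    smoothed: dict[str, SmoothedCurve] = {}

    def get_smoothed(name: str) -> SmoothedCurve:
        if name not in smoothed:
            c = curves[name]
            smoothed[name] = c if isinstance(c, SmoothedCurve) else \
                smooth_curve(c, df=df)
        return smoothed[name]

    names: list[str] = []
    points: list[np.ndarray] = []
    qc: dict[str, dict[str, object]] = {}
    skipped: dict[str, str] = {}
    deferred: list[LandmarkRule] = []

    def missing_sources(rule: LandmarkRule) -> list[str]:
        return [c for c in rule.source_curves if c not in curves]

    for rule in rules:
        miss = missing_sources(rule)
        if miss:
            skipped[rule.name] = f"missing curve(s): {', '.join(miss)}"
            continue
        if rule.kind == "fallback-distance":
            deferred.append(rule)
            continue
        try:
            if rule.kind == "max-curvature-on-curve":
                sc = get_smoothed(rule.source_curves[0])
                profile = curve_curvature(sc, grid=grid)
                s_star, k_star, dominance = dominant_peak(
                    profile, exclude_ends=exclude_ends,
                    window=_window_for(sc, rule.qualifiers[0]))
                pt = sc.evaluate([s_star])[0]
                names.append(rule.name)
                points.append(pt)
                qc[rule.name] = {"rule": rule.kind,
                                 "quality_metric": dominance, "flag": ""}
            elif rule.kind == "endpoint":
                c = curves[rule.source_curves[0]]
                pts = c.evaluate(np.array([0.0, c.length])) \
                    if isinstance(c, SmoothedCurve) else c.points
                pt = pts[0] if rule.qualifiers[0] == "start" else pts[-1]
                names.append(rule.name)
                points.append(np.asarray(pt, float))
                qc[rule.name] = {"rule": rule.kind, "quality_metric": np.nan,
                                 "flag": ""}
            elif rule.kind == "crossing":
                res = crossing_point(curves[rule.source_curves[0]],
                                     curves[rule.source_curves[1]],
                                     tol=crossing_tol,
                                     window_a=rule.qualifiers[0],
                                     window_b=rule.qualifiers[1])
                names.append(rule.name)
                points.append(res.point)
                qc[rule.name] = {
                    "rule": rule.kind, "quality_metric": res.distance,
                    "flag": "out-of-tolerance" if res.out_of_tolerance else "",
                }
            else:
                skipped[rule.name] = f"unknown rule kind {rule.kind!r}"
        except (NoPeakError, SupportError) as exc:
            skipped[rule.name] = str(exc)

    # alare flatness fallback: weak peak => coincident with alare crest
    if "alare" in names and "alare crest" in names:
        dom = qc["alare"]["quality_metric"]
        if np.isfinite(dom) and dom < ALARE_DOMINANCE_MIN:
            points[names.index("alare")] = points[names.index("alare crest")]
            qc["alare"]["flag"] = "coincident-with-alare-crest"

    for rule in deferred:
        miss_refs = [r for r in rule.reference_landmarks if r not in names]
        if miss_refs:
            skipped[rule.name] = f"missing landmark(s): {', '.join(miss_refs)}"
            continue
        a = points[names.index(rule.reference_landmarks[0])]
        b = points[names.index(rule.reference_landmarks[1])]
        sc = get_smoothed(rule.source_curves[0])
        samples = sc.evaluate(np.linspace(0.0, sc.length, grid))
        chord = b - a
        nrm = np.linalg.norm(chord)
        if nrm == 0:
            skipped[rule.name] = "degenerate reference chord"
            continue
        d = np.linalg.norm(np.cross(samples - a, chord / nrm), axis=1)
        i = int(np.argmax(d))
        names.append(rule.name)
        points.append(samples[i])
        qc[rule.name] = {"rule": rule.kind, "quality_metric": float(d[i]),
                         "flag": ""}

    config = LandmarkConfiguration(names, np.vstack(points)
                                   if points else np.empty((0, 3)))
    return LandmarkingResult(config=config, qc=qc, skipped=skipped)
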