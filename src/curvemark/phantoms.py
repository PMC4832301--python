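"""Synthetic surfaces, curves and hierarchical datasets with known truth.

Every other module is testable without external data: phantom surfaces carry
closed-form principal curvatures and shape indices, phantom curves carry
closed-form bending profiles, and the hierarchical simulator draws landmark
datasets from the nested random-effects model with known standard
deviations.

Surface kinds
-------------
``quadric-patch``   z = (kappa1 x^2 + kappa2 y^2) / 2 over a square grid.
``sphere``          icosphere of given radius (outward winding).
``gaussian-ridge``  z = h exp(-x^2 / (2 w^2)) extruded along y; the crest
                    line x = 0 is the analytic ridge.
``composite-face``  plane plus two orthogonal Gaussian ridges (a "mid-line"
                    crest x = 0 and a transverse "mandible" crest y = y0)
                    whose crest lines cross at a known point.

Curve kinds: ``circle-curve`` (kappa = 1/r), ``helix-curve``
(kappa = a / (a^2 + b^2)), and ``arc-chain`` (consecutive tangent circular
arcs with piecewise-constant curvature 1/R_i).

All randomness is driven by explicit seeds; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import trimesh

from .curvature import shape_index
from .io import LandmarkConfiguration, NamedCurve, SurfaceMesh
from .reproducibility import (HierarchicalDataset, HierarchicalRecord, LEVELS)

__all__ = [
    "PhantomSpec",
    "SurfaceTruth",
    "CurveTruth",
    "SimulationTruth",
    "make_surface",
    "make_curve",
    "simulate_hierarchy",
    "paper_design",
    "confirmation_design",
    "TABLE4_CURVATURE",
    "TABLE4_ORIENTATION",
]

SURFACE_KINDS = ("quadric-patch", "sphere", "gaussian-ridge", "composite-face")
CURVE_KINDS = ("circle-curve", "helix-curve", "arc-chain")

# Published per-level SDs (mm), averaged over landmarks and dimensions, for
# the curvature- and orientation-based definition groups: observer, subject,
# day, capture (image), repeat.
TABLE4_CURVATURE = {"observer": 0.361, "subject": 1.645, "day": 0.288,
                    "capture": 0.103, "repeat": 0.562}
TABLE4_ORIENTATION = {"observer": 0.553, "subject": 1.670, "day": 0.323,
                      "capture": 0.086, "repeat": 0.587}


@dataclass
class PhantomSpec:
    """Parameters of a synthetic surface or curve phantom (lengths in mm)."""

    kind: str
    kappa1: float = 0.0          # 1/mm (quadric-patch)
    kappa2: float = 0.0
    radius: float = 50.0         # sphere / circle radius
    height: float = 5.0          # Gaussian ridge height h
    width: float = 3.0           # Gaussian ridge scale w
    helix_a: float = 10.0
    helix_b: float = 5.0
    arc_radii: tuple[float, ...] = (40.0, 8.0, 40.0)
    arc_lengths: tuple[float, ...] = (15.0, 8.0, 15.0)
    extent: float = 15.0         # half-width of grid phantoms
    ridge_offset: float = 0.0    # y0 of the transverse composite crest
    spacing: float = 1.0         # grid spacing
    noise_sd: float = 0.0        # Gaussian noise along the normal
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")


@dataclass
class SurfaceTruth:
    """Closed-form ground truth attached to a phantom surface."""

    kappa1: np.ndarray
    kappa2: np.ndarray
    S: np.ndarray
    crest: NamedCurve | None = None          # gaussian-ridge / composite
    second_crest: NamedCurve | None = None   # composite transverse crest
    crossing: np.ndarray | None = None       # analytic crest intersection


@dataclass
class CurveTruth:
    """Closed-form curvature profile of a phantom curve."""

    s: np.ndarray           # arc length at the sampled points
    kappa: np.ndarray       # 1/mm at each sample
    peak_s: float | None = None  # arc length of the curvature maximum


def _grid(extent: float, spacing: float,
          extent_y: float | None = None) -> tuple[np.ndarray, np.ndarray,
                                                  np.ndarray]:
    ey = extent if extent_y is None else extent_y
    xs = np.arange(-extent, extent + 0.5 * spacing, spacing)
    ys = np.arange(-ey, ey + 0.5 * spacing, spacing)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    nx, ny = X.shape
    idx = np.arange(nx * ny).reshape(nx, ny)
    # counter-clockwise seen from +z so face winding gives upward normals
    f1 = np.stack([idx[:-1, :-1], idx[1:, :-1], idx[1:, 1:]], axis=-1)
    f2 = np.stack([idx[:-1, :-1], idx[1:, 1:], idx[:-1, 1:]], axis=-1)
    faces = np.concatenate([f1.reshape(-1, 3), f2.reshape(-1, 3)])
    return X.ravel(), Y.ravel(), faces


def _graph_curvatures(fx, fy, fxx, fxy, fyy):
    """Principal curvatures of z = f(x, y) with the upward (+z) normal."""
    w2 = 1.0 + fx**2 + fy**2
    w = np.sqrt(w2)
    # Gaussian and mean curvature of a Monge patch
    K = (fxx * fyy - fxy**2) / w2**2
    H = ((1.0 + fy**2) * fxx - 2.0 * fx * fy * fxy
         + (1.0 + fx**2) * fyy) / (2.0 * w**3)
    disc = np.sqrt(np.maximum(H**2 - K, 0.0))
    return H + disc, H - disc


def make_surface(spec: PhantomSpec) -> tuple[SurfaceMesh, SurfaceTruth]:
    """Build a phantom surface mesh with its analytic curvature truth.

    Noise, when requested, is Gaussian displacement along the analytic
    surface normal, reproducible from ``spec.seed``.  Ground-truth values are
    evaluated at the noise-free vertex locations.
    """
    if spec.kind not in SURFACE_KINDS:
        raise ValueError(f"unknown surface kind {spec.kind!r}")
    rng = np.random.default_rng(spec.seed)

    if spec.kind == "sphere":
        subdiv = max(1, int(np.round(np.log2(1.1 * spec.radius / spec.spacing))))
        tm = trimesh.creation.icosphere(subdivisions=subdiv, radius=spec.radius)
        verts = np.asarray(tm.vertices, float)
        faces = np.asarray(tm.faces, np.int64)
        if spec.noise_sd > 0:
            normals = verts / np.linalg.norm(verts, axis=1, keepdims=True)
            verts = verts + rng.normal(scale=spec.noise_sd,
                                       size=len(verts))[:, None] * normals
        k = -1.0 / spec.radius  # convex with outward normals
        n = len(verts)
        truth = SurfaceTruth(
            kappa1=np.full(n, k), kappa2=np.full(n, k), S=np.full(n, 1.0)
        )
        return SurfaceMesh(vertices=verts, faces=faces), truth

    x, y, faces = _grid(spec.extent, spec.spacing)
    if spec.kind == "quadric-patch":
        z = 0.5 * (spec.kappa1 * x**2 + spec.kappa2 * y**2)
        fx = spec.kappa1 * x
        fy = spec.kappa2 * y
        fxx = np.full_like(x, spec.kappa1)
        fyy = np.full_like(x, spec.kappa2)
        fxy = np.zeros_like(x)
        crest = second = crossing = None
    elif spec.kind == "gaussian-ridge":
        h, wdt = spec.height, spec.width
        g = np.exp(-x**2 / (2 * wdt**2))
        z = h * g
        fx = -h * x / wdt**2 * g
        fy = np.zeros_like(x)
        fxx = h * g * (x**2 / wdt**4 - 1.0 / wdt**2)
        fyy = np.zeros_like(x)
        fxy = np.zeros_like(x)
        ys = np.unique(y)
        crest = NamedCurve("crest", np.column_stack(
            [np.zeros_like(ys), ys, np.full_like(ys, h)]), kind="ridge")
        second = crossing = None
    else:  # composite-face
        h, wdt, y0 = spec.height, spec.width, spec.ridge_offset
        g1 = np.exp(-x**2 / (2 * wdt**2))
        g2 = np.exp(-(y - y0)**2 / (2 * wdt**2))
        z = h * g1 + h * g2
        fx = -h * x / wdt**2 * g1
        fy = -h * (y - y0) / wdt**2 * g2
        fxx = h * g1 * (x**2 / wdt**4 - 1.0 / wdt**2)
        fyy = h * g2 * ((y - y0)**2 / wdt**4 - 1.0 / wdt**2)
        fxy = np.zeros_like(x)
        ys = np.unique(y)
        xs = np.unique(x)
        crest = NamedCurve("mid-line crest", np.column_stack(
            [np.zeros_like(ys), ys,
             h + h * np.exp(-(ys - y0)**2 / (2 * wdt**2))]), kind="ridge")
        second = NamedCurve("transverse crest", np.column_stack(
            [xs, np.full_like(xs, y0),
             h + h * np.exp(-xs**2 / (2 * wdt**2))]), kind="ridge")
        crossing = np.array([0.0, y0, 2.0 * h])

    k1, k2 = _graph_curvatures(fx, fy, fxx, fxy, fyy)
    # shape index undefined (NaN) where the surface is exactly flat
    S = np.full_like(k1, np.nan)
    nz = (np.abs(k1) > 1e-12) | (np.abs(k2) > 1e-12)
    if np.any(nz):
        S[nz] = np.asarray(shape_index(k1[nz], k2[nz]))

    verts = np.column_stack([x, y, z])
    if spec.noise_sd > 0:
        w = np.sqrt(1.0 + fx**2 + fy**2)
        normals = np.column_stack([-fx, -fy, np.ones_like(fx)]) / w[:, None]
        verts = verts + rng.normal(scale=spec.noise_sd,
                                   size=len(verts))[:, None] * normals
    mesh = SurfaceMesh(vertices=verts, faces=faces)
    return mesh, SurfaceTruth(kappa1=k1, kappa2=k2, S=S, crest=crest,
                              second_crest=second, crossing=crossing)


def make_curve(spec: PhantomSpec, n_points: int = 200,
               name: str | None = None) -> tuple[NamedCurve, CurveTruth]:
    """Sample a phantom curve with its analytic curvature profile.

    Noise (``spec.noise_sd``) is isotropic Gaussian on the sampled points,
    reproducible from ``spec.seed``.
    """
    if spec.kind not in CURVE_KINDS:
        raise ValueError(f"unknown curve kind {spec.kind!r}")
    if n_points < 10:
        raise ValueError("need at least 10 points")
    rng = np.random.default_rng(spec.seed)

    if spec.kind == "circle-curve":
        r = spec.radius
        theta = np.linspace(0.0, 2 * np.pi, n_points, endpoint=False)
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta),
                               np.zeros_like(theta)])
        s = r * theta
        kappa = np.full(n_points, 1.0 / r)
        peak = None
    elif spec.kind == "helix-curve":
        a, b = spec.helix_a, spec.helix_b
        theta = np.linspace(0.0, 4 * np.pi, n_points)
        pts = np.column_stack([a * np.cos(theta), a * np.sin(theta), b * theta])
        s = np.sqrt(a * a + b * b) * theta
        kappa = np.full(n_points, a / (a * a + b * b))
        peak = None
    else:  # arc-chain: consecutive tangent planar arcs, same bending sense
        radii = spec.arc_radii
        lengths = spec.arc_lengths
        if len(radii) != len(lengths):
            raise ValueError("arc_radii and arc_lengths must match in length")
        total = sum(lengths)
        s = np.linspace(0.0, total, n_points)
        pts = np.zeros((n_points, 3))
        kappa = np.zeros(n_points)
        pos = np.zeros(2)
        heading = 0.0
        s0 = 0.0
        for R, L in zip(radii, lengths):
            sel = (s >= s0 - 1e-12) & (s <= s0 + L + 1e-12)
            ds = s[sel] - s0
            phi = ds / R
            # arc turning left with curvature 1/R from (pos, heading)
            cx = pos[0] - R * np.sin(heading)
            cy = pos[1] + R * np.cos(heading)
            pts[sel, 0] = cx + R * np.sin(heading + phi)
            pts[sel, 1] = cy - R * np.cos(heading + phi)
            kappa[sel] = 1.0 / R
            pos = np.array([cx + R * np.sin(heading + L / R),
                            cy - R * np.cos(heading + L / R)])
            heading += L / R
            s0 += L
        # analytic curvature peak: centre of the tightest arc
        i_min = int(np.argmin(radii))
        peak = sum(lengths[:i_min]) + lengths[i_min] / 2.0

    if spec.noise_sd > 0:
        pts = pts + rng.normal(scale=spec.noise_sd, size=pts.shape)
    curve = NamedCurve(name or spec.kind, pts, kind="ridge")
    return curve, CurveTruth(s=s, kappa=kappa, peak_s=peak)


# ---------------------------------------------------------------------------
# hierarchical simulator


@dataclass
class SimulationTruth:
    """True means and level SDs driving the hierarchical simulator.

    ``mu`` is an (n_landmarks, 3) array of true landmark positions (mm);
    ``sds`` maps each level name to its SD (mm), shared across landmarks and
    dimensions as in the fitted model.  The balanced design is
    observers x subjects x days x captures x repeats per definition group.
    """

    landmark_names: list[str]
    mu: np.ndarray
    sds: dict[str, float]
    n_observers: int = 2
    n_subjects: int = 4
    n_days: int = 2
    n_captures: int = 2
    n_repeats: int = 2
    groups: tuple[str, ...] = ("curvature", "orientation")
    perturb: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        if self.mu.shape != (len(self.landmark_names), 3):
            raise ValueError("mu must be (n_landmarks, 3)")
        if set(self.sds) != set(LEVELS):
            raise ValueError(f"sds must have keys {LEVELS}")
        if any(v < 0 for v in self.sds.values()):
            raise ValueError("SDs must be non-negative")
        for cnt in (self.n_observers, self.n_subjects, self.n_days,
                    self.n_captures, self.n_repeats):
            if cnt < 1:
                raise ValueError("design counts must be >= 1")


def _random_similarity(rng: np.random.Generator,
                       max_angle_deg: float = 10.0,
                       scale_range: tuple[float, float] = (0.97, 1.03),
                       max_translation: float = 20.0):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(-max_angle_deg, max_angle_deg))
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    scale = rng.uniform(*scale_range)
    t = rng.uniform(-max_translation, max_translation, size=3)
    return R, scale, t


def simulate_hierarchy(truth: SimulationTruth) -> HierarchicalDataset:
    """Draw a balanced hierarchical landmark dataset from the nested model.

    Each effect is drawn once per index from a centred Gaussian with its
    level SD: observer effects o_i per (group, observer), subject effects
    s_j per subject, day effects d_jk per (subject, day), capture effects
    c_jkl per (subject, day, capture) -- shared across observers, as the day
    and capture variation belong to the imaged face -- and repeat effects
    per record.  Subject/day/capture draws are shared across definition
    groups (the groups annotate the same images).  With ``perturb`` each
    image's configurations are wrapped in a random similarity transform
    (rotation <= 10 degrees, scale 0.97..1.03, translation <= 20 mm) so that
    registration is exercised.  Fully reproducible from ``truth.seed``.
    """
    rng = np.random.default_rng(truth.seed)
    L = len(truth.landmark_names)
    shape = (L, 3)

    def draw(sd):
        return rng.normal(scale=sd, size=shape) if sd > 0 else np.zeros(shape)

    subj = [draw(truth.sds["subject"]) for _ in range(truth.n_subjects)]
    day = {(j, k): draw(truth.sds["day"])
           for j in range(truth.n_subjects) for k in range(truth.n_days)}
    cap = {(j, k, l): draw(truth.sds["capture"])
           for j in range(truth.n_subjects) for k in range(truth.n_days)
           for l in range(truth.n_captures)}
    obs = {(g, i): draw(truth.sds["observer"])
           for g in truth.groups for i in range(truth.n_observers)}
    image_tf = {}
    if truth.perturb:
        for j in range(truth.n_subjects):
            for k in range(truth.n_days):
                for l in range(truth.n_captures):
                    image_tf[(j, k, l)] = _random_similarity(rng)

    records = []
    for g in truth.groups:
        for i in range(truth.n_observers):
            for j in range(truth.n_subjects):
                for k in range(truth.n_days):
                    for l in range(truth.n_captures):
                        for m in range(truth.n_repeats):
                            v = (truth.mu + obs[(g, i)] + subj[j]
                                 + day[(j, k)] + cap[(j, k, l)]
                                 + draw(truth.sds["repeat"]))
                            if truth.perturb:
                                R, sc, t = image_tf[(j, k, l)]
                                v = sc * (v @ R.T) + t
                            records.append(HierarchicalRecord(
                                observer=f"o{i + 1}", subject=f"s{j + 1}",
                                day=f"d{k + 1}", capture=f"c{l + 1}",
                                repeat=f"r{m + 1}", group=g,
                                config=LandmarkConfiguration(
                                    list(truth.landmark_names), v),
                            ))
    return HierarchicalDataset(records)


def _default_face_mu(names: Sequence[str]) -> np.ndarray:
    """Rough frontal-face coordinates (mm) for common landmark names."""
    table = {
        "exocanthion right": (45.0, 35.0, -20.0),
        "exocanthion left": (-45.0, 35.0, -20.0),
        "nasion": (0.0, 40.0, -5.0),
        "subnasale": (0.0, -5.0, 5.0),
        "pronasale": (0.0, 10.0, 20.0),
        "gnathion": (0.0, -65.0, -5.0),
        "alare crest right": (15.0, -2.0, 0.0),
        "alare crest left": (-15.0, -2.0, 0.0),
        "crista philtri right": (5.0, -18.0, 8.0),
        "crista philtri left": (-5.0, -18.0, 8.0),
    }
    rng = np.random.default_rng(12345)
    return np.array([table.get(n, tuple(rng.uniform(-50, 50, 3)))
                     for n in names])


def paper_design(sds: Mapping[str, float] | None = None, seed: int = 0,
                 perturb: bool = False) -> SimulationTruth:
    """The validation-study design: 2 observers per definition group,
    4 subjects imaged twice on each of 2 days, each image landmarked twice
    (64 records per group)."""
    names = ["exocanthion right", "exocanthion left", "nasion", "subnasale",
             "pronasale", "gnathion"]
    return SimulationTruth(
        landmark_names=names, mu=_default_face_mu(names),
        sds=dict(sds or TABLE4_CURVATURE),
        n_observers=2, n_subjects=4, n_days=2, n_captures=2, n_repeats=2,
        seed=seed, perturb=perturb,
    )


def confirmation_design(sds: Mapping[str, float] | None = None,
                        seed: int = 0) -> SimulationTruth:
    """The follow-up design: 10 observers per group locating gnathion on
    5 subjects with 2 repeat images each, plus the 4 registration landmarks."""
    names = ["gnathion", "alare crest right", "alare crest left",
             "crista philtri right", "crista philtri left"]
    return SimulationTruth(
        landmark_names=names, mu=_default_face_mu(names),
        sds=dict(sds or TABLE4_CURVATURE),
        n_observers=10, n_subjects=5, n_days=1, n_captures=2, n_repeats=2,
        seed=seed,
    )
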