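"""Per-vertex principal curvatures and the shape index of a surface mesh.

The local shape of a smooth surface around a point is captured, up to second
order, by the height of the surface over its tangent plane,

    z = e*x + f*y + (1/2) * (a*x**2 + 2*b*x*y + c*y**2),

with the z axis along the surface normal.  The eigen-decomposition of the
shape operator built from this fit gives the principal curvatures
``kappa1 >= kappa2`` (units 1/mm) and their directions.  The shape index

    S = (2/pi) * arctan((kappa2 + kappa1) / (kappa2 - kappa1))

collapses the pair into a single orientation-free scale in [-1, 1] running
from spherical cup (-1) through rut, saddle (0) and ridge to spherical cap
(+1).  S depends only on the *ratio* of curvatures, so it is invariant to
uniform scaling of the surface.

Sign convention: curvature is the second derivative of height along the
*outward* normal, so convex, protruding features (nose tip, chin) have
negative principal curvatures and S near +1 (cap), while concave features
have positive curvatures and S near -1 (cup).

Each vertex is fitted by least squares to its Euclidean-ball neighbourhood
(default radius 10 mm) using the vertex normal from face winding to set the
local frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.spatial import cKDTree

from .io import DimensionError, SurfaceMesh

__all__ = [
    "LocalQuadric",
    "PrincipalCurvatureField",
    "ShapeIndexField",
    "InsufficientSupportError",
    "DegenerateNeighborhoodError",
    "fit_local_quadric",
    "principal_curvatures",
    "shape_index",
    "classify_shape",
    "compute_fields",
    "SHAPE_CATEGORIES",
    "FLAT_CATEGORY",
    "DEFAULT_FLAT_THRESHOLD",
]

DEFAULT_RADIUS = 10.0  # mm neighbourhood ball
DEFAULT_FLAT_THRESHOLD = 1e-4  # 1/mm; both |kappa| below => planar flag
MIN_NEIGHBORS = 6

# Koenderink-style nine-category partition of [-1, 1] into eighths.
# Half-open on the left, the cap band closed on both ends.  The bands are
# configuration: pass a modified list to classify_shape to change them.
SHAPE_CATEGORIES: list[tuple[str, float, float, tuple[int, int, int]]] = [
    ("spherical cup", -1.0, -7 / 8, (32, 64, 160)),
    ("trough", -7 / 8, -5 / 8, (64, 128, 208)),
    ("rut", -5 / 8, -3 / 8, (96, 192, 240)),
    ("saddle rut", -3 / 8, -1 / 8, (160, 224, 240)),
    ("saddle", -1 / 8, 1 / 8, (208, 224, 200)),
    ("saddle ridge", 1 / 8, 3 / 8, (240, 224, 144)),
    ("ridge", 3 / 8, 5 / 8, (240, 176, 80)),
    ("dome", 5 / 8, 7 / 8, (224, 112, 64)),
    ("spherical cap", 7 / 8, 1.0, (192, 48, 32)),
]
FLAT_CATEGORY = ("flat", (200, 200, 200))


class InsufficientSupportError(ValueError):
    """Too few neighbours inside the fitting radius."""

    def __init__(self, n_neighbors: int, radius: float):
        self.n_neighbors = n_neighbors
        super().__init__(
            f"only {n_neighbors} neighbours within {radius} mm "
            f"(need >= {MIN_NEIGHBORS})"
        )


class DegenerateNeighborhoodError(ValueError):
    """Neighbourhood is rank-deficient (e.g. collinear points)."""


@dataclass
class LocalQuadric:
    """Least-squares local height model at one vertex.

    The frame is (origin; tangent basis t1, t2; unit normal n), orthonormal.
    Coefficients follow ``z = e*x + f*y + (a*x^2 + 2*b*x*y + c*y^2) / 2``
    with a, b, c in 1/mm.
    """

    origin: np.ndarray
    t1: np.ndarray
    t2: np.ndarray
    normal: np.ndarray
    a: float
    b: float
    c: float
    e: float
    f: float
    n_points: int
    radius: float

    def __post_init__(self) -> None:
        F = np.stack([self.t1, self.t2, self.normal])
        if not np.allclose(F @ F.T, np.eye(3), atol=1e-8):
            raise ValueError("frame must be orthonormal")
        if self.n_points < MIN_NEIGHBORS:
            raise InsufficientSupportError(self.n_points, self.radius)


@dataclass
class PrincipalCurvatureField:
    """Per-vertex kappa1 >= kappa2 (1/mm), principal directions and validity."""

    kappa1: np.ndarray
    kappa2: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    normals: np.ndarray  # fitted-surface unit normals
    valid: np.ndarray
    mesh: SurfaceMesh | None = None  # the substrate the field was computed on


@dataclass
class ShapeIndexField:
    """Per-vertex shape index, planar flag, category and colour code."""

    S: np.ndarray            # NaN where planar or invalid
    planar: np.ndarray       # bool
    categories: np.ndarray   # object (str)
    colors: np.ndarray       # (n, 3) uint8


def _tangent_frame(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = normal / np.linalg.norm(normal)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(n[0]) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    t1 = np.cross(ref, n)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(n, t1)
    return t1, t2


def fit_local_quadric(
    mesh: SurfaceMesh,
    vertex: int,
    radius: float = DEFAULT_RADIUS,
    *,
    tree: cKDTree | None = None,
    normals: np.ndarray | None = None,
) -> LocalQuadric:
    """Fit the local height quadric at ``vertex`` over a Euclidean ball.

    The frame normal is the mesh vertex normal (outward for consistently
    wound meshes); linear terms e, f absorb residual tilt of the frame.
    """
    if not 0 <= vertex < mesh.n_vertices:
        raise IndexError(f"vertex {vertex} out of range")
    if tree is None:
        tree = cKDTree(mesh.vertices)
    if normals is None:
        normals = mesh.vertex_normals()
    idx = tree.query_ball_point(mesh.vertices[vertex], r=radius)
    idx = np.asarray(idx, dtype=np.int64)
    if len(idx) < MIN_NEIGHBORS:
        raise InsufficientSupportError(len(idx), radius)
    origin = mesh.vertices[vertex]
    n = normals[vertex] / np.linalg.norm(normals[vertex])
    t1, t2 = _tangent_frame(n)
    rel = mesh.vertices[idx] - origin
    x = rel @ t1
    y = rel @ t2
    z = rel @ n
    design = np.column_stack([x, y, 0.5 * x**2, x * y, 0.5 * y**2])
    if np.linalg.matrix_rank(design, tol=1e-9 * max(1.0, radius**2)) < 5:
        raise DegenerateNeighborhoodError(
            f"rank-deficient neighbourhood at vertex {vertex}"
        )
    coef, *_ = np.linalg.lstsq(design, z, rcond=None)
    e, f, a, b, c = coef
    return LocalQuadric(
        origin=origin, t1=t1, t2=t2, normal=n,
        a=float(a), b=float(b), c=float(c), e=float(e), f=float(f),
        n_points=len(idx), radius=radius,
    )


def principal_curvatures(
    q: LocalQuadric,
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Principal curvatures and 3D directions from a fitted quadric.

    The curvatures are the eigenvalues of the shape operator at the origin,
    i.e. the second fundamental form ``[[a, b], [b, c]] / w`` measured
    against the first fundamental form induced by the fitted gradient
    ``(e, f)`` with ``w = sqrt(1 + e^2 + f^2)``.  Returns
    ``(kappa1, kappa2, e1, e2)`` with ``kappa1 >= kappa2`` and e1, e2 unit
    tangent vectors of the fitted surface.
    """
    e, f = q.e, q.f
    w = np.sqrt(1.0 + e * e + f * f)
    I = np.array([[1.0 + e * e, e * f], [e * f, 1.0 + f * f]])
    II = np.array([[q.a, q.b], [q.b, q.c]]) / w
    vals, vecs = linalg.eigh(II, I)
    # eigh returns ascending; kappa1 is the larger
    kappa2, kappa1 = float(vals[0]), float(vals[1])
    ru = q.t1 + e * q.normal
    rv = q.t2 + f * q.normal
    d1 = vecs[0, 1] * ru + vecs[1, 1] * rv
    d2 = vecs[0, 0] * ru + vecs[1, 0] * rv
    d1 /= np.linalg.norm(d1)
    d2 /= np.linalg.norm(d2)
    return kappa1, kappa2, d1, d2


def shape_index(kappa1, kappa2):
    """Shape index S = (2/pi) arctan((k2 + k1) / (k2 - k1)), in [-1, 1].

    At umbilic points (kappa1 == kappa2) the limiting convention applies:
    -1 when both curvatures are positive (cup), +1 when both are negative
    (cap).  Accepts scalars or arrays; requires kappa1 >= kappa2.
    """
    k1 = np.asarray(kappa1, dtype=float)
    k2 = np.asarray(kappa2, dtype=float)
    if np.any(k1 < k2 - 1e-15 * np.maximum(1.0, np.abs(k1))):
        raise ValueError("requires kappa1 >= kappa2")
    denom = k2 - k1
    with np.errstate(divide="ignore", invalid="ignore"):
        S = (2.0 / np.pi) * np.arctan((k2 + k1) / denom)
    umbilic = denom == 0
    if np.any(umbilic):
        S = np.where(umbilic & (k1 > 0), -1.0, S)
        S = np.where(umbilic & (k1 < 0), 1.0, S)
        S = np.where(umbilic & (k1 == 0), np.nan, S)
    if np.ndim(kappa1) == 0 and np.ndim(kappa2) == 0:
        return float(S)
    return S


def classify_shape(
    S: float,
    bands: list[tuple[str, float, float, tuple[int, int, int]]] | None = None,
) -> tuple[str, tuple[int, int, int]]:
    """Map a shape index to its Koenderink category and colour code.

    NaN (planar flag) maps to the neutral "flat" category.  Band edges are
    half-open on the left; the cap band includes both ends.
    """
    if bands is None:
        bands = SHAPE_CATEGORIES
    if np.isnan(S):
        return FLAT_CATEGORY
    if not -1.0 <= S <= 1.0:
        raise ValueError(f"shape index {S} outside [-1, 1]")
    for name, lo, hi, color in bands:
        if lo <= S < hi:
            return name, color
    # S == upper end of the last band
    name, lo, hi, color = bands[-1]
    return name, color


def compute_fields(
    mesh: SurfaceMesh,
    radius: float = DEFAULT_RADIUS,
    *,
    flat_threshold: float = DEFAULT_FLAT_THRESHOLD,
    flip_normals: bool = False,
) -> tuple[PrincipalCurvatureField, ShapeIndexField]:
    """Estimate curvature and shape-index fields over all mesh vertices.

    Vertices with too few neighbours or degenerate neighbourhoods are
    flagged invalid (NaN entries), never silently zeroed.  ``flip_normals``
    flips the global orientation when the mesh winding points inward.
    """
    n = mesh.n_vertices
    if n == 0:
        raise DimensionError("empty mesh")
    tree = cKDTree(mesh.vertices)
    normals = mesh.vertex_normals()
    if flip_normals:
        normals = -normals
    k1 = np.full(n, np.nan)
    k2 = np.full(n, np.nan)
    e1 = np.full((n, 3), np.nan)
    e2 = np.full((n, 3), np.nan)
    fit_normals = np.full((n, 3), np.nan)
    valid = np.zeros(n, dtype=bool)
    for v in range(n):
        try:
            q = fit_local_quadric(mesh, v, radius, tree=tree, normals=normals)
            kk1, kk2, d1, d2 = principal_curvatures(q)
        except (InsufficientSupportError, DegenerateNeighborhoodError):
            continue
        k1[v], k2[v] = kk1, kk2
        e1[v], e2[v] = d1, d2
        nn = np.cross(d1, d2)
        fit_normals[v] = nn / np.linalg.norm(nn)
        valid[v] = True

    planar = valid & (np.abs(k1) < flat_threshold) & (np.abs(k2) < flat_threshold)
    S = np.full(n, np.nan)
    ok = valid & ~planar
    if np.any(ok):
        S[ok] = shape_index(k1[ok], k2[ok])
    categories = np.empty(n, dtype=object)
    colors = np.zeros((n, 3), dtype=np.uint8)
    for v in range(n):
        if not valid[v] or planar[v]:
            cat, col = FLAT_CATEGORY
        else:
            cat, col = classify_shape(S[v])
        categories[v] = cat
        colors[v] = col
    pcf = PrincipalCurvatureField(
        kappa1=k1, kappa2=k2, e1=e1, e2=e2, normals=fit_normals, valid=valid,
        mesh=mesh,
    )
    sif = ShapeIndexField(S=S, planar=planar, categories=categories, colors=colors)
    return pcf, sif
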