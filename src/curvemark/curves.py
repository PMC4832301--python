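"""Ridge/rut feature detection, curve tracing and continuation.

A ridge is a connected set of surface points whose shape index sits in the
convex-crest range and which are locally *more* ridge-like than their
neighbours transverse to the ridge direction; a rut is the concave
counterpart.  The feature direction at a point is the principal direction of
the curvature that is smaller in magnitude (a crest bends strongly across
itself and weakly along itself); the transverse direction is the other one.

Non-maximum suppression scores each candidate with an S-weighted curvedness
|S| * sqrt((kappa1^2 + kappa2^2) / 2): on an extruded crest the shape index
is constant across the whole convex flank, so the transverse bending rate is
what singles out the crest line, while on surfaces where S varies the score
also favours the most ridge-like shape.

Flagged points are linked into ordered polylines by greedy nearest-neighbour
chaining under a direction-consistency gate, and curves can be extended
("continued") across regions where the curvature signature vanishes: in the
last identified direction, toward a target point, or to the closest point on
another curve.  The curve catalog lists the sixteen named facial curves with
their feature kinds and continuation targets; eyelid curves are edges of the
palpebral fissure, not curvature features, and are accepted as user-supplied
polylines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curvature import PrincipalCurvatureField, ShapeIndexField
from .io import DimensionError, NamedCurve, SurfaceMesh

__all__ = [
    "FeaturePointSet",
    "AnatomicalCurveSpec",
    "TracedCurve",
    "SeedError",
    "TraceError",
    "ConnectivityError",
    "detect_feature_points",
    "trace_curve",
    "continue_curve",
    "curve_catalog",
    "closest_point_on_polyline",
    "RIDGE_BAND",
    "RUT_BAND",
]

# Feature bands include the dome/cup ends so that curved crests on rounded
# features (e.g. the nasal dorsum) are not dropped.
RIDGE_BAND = (3.0 / 8.0, 1.0)
RUT_BAND = (-1.0, -3.0 / 8.0)

MIN_CURVE_SUPPORT = 5       # traces shorter than this are noise
MIN_ANISOTROPY = 0.05       # |k_strong - k_weak| / |k_strong| below this is
                            # umbilic: no feature direction exists
LINK_RADIUS_FACTOR = 3.0    # x median edge length
ANGULAR_GATE_DEG = 60.0
CONTINUATION_STEP_FACTOR = 0.5


class SeedError(ValueError):
    """No feature point near the requested seed."""


class TraceError(ValueError):
    """Tracing produced no usable curve."""


class ConnectivityError(ValueError):
    """The continuation target is unreachable on the mesh component."""


@dataclass
class FeaturePointSet:
    """Vertices flagged as ridge or rut candidates with their NMS strength."""

    mesh: SurfaceMesh
    indices: np.ndarray          # flagged vertex ids
    strength: np.ndarray         # suppression-score margin per flagged vertex
    kind: str                    # "ridge" | "rut"
    directions: np.ndarray       # feature (along-crest) unit vector per point

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def points(self) -> np.ndarray:
        return self.mesh.vertices[self.indices]


@dataclass
class AnatomicalCurveSpec:
    """Named catalog entry: what feature the curve is and how it terminates."""

    name: str
    kind: str                        # ridge | rut | edge | continuation
    description: str = ""
    source_curve: str | None = None  # continuation: the curve being extended
    target_curve: str | None = None  # continuation: catalog curve it runs to
    target_feature: str | None = None  # continuation target not in the catalog
    mode: str | None = None          # same-direction | toward-target
                                     # | closest-point-on-curve


@dataclass
class TracedCurve:
    """A traced polyline plus its provenance."""

    curve: NamedCurve
    vertex_ids: np.ndarray           # flagged vertex per point; -1 = continuation
    spec: AnatomicalCurveSpec | None = None
    continuation_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.continuation_mask is None:
            self.continuation_mask = np.zeros(len(self.curve.points),
                                              dtype=bool)


def detect_feature_points(
    fields: tuple[PrincipalCurvatureField, ShapeIndexField],
    kind: str,
    band: tuple[float, float] | None = None,
    min_anisotropy: float = MIN_ANISOTROPY,
) -> FeaturePointSet:
    """Flag ridge (or rut) points of the shape-index field.

    A vertex is flagged iff its shape index lies in the band for ``kind``,
    its principal curvatures are anisotropic enough for a feature direction
    to exist (umbilic points such as a sphere's have none), and its feature
    score is a strict local maximum over its one-ring neighbours transverse
    to the feature direction.
    """
    pcf, sif = fields
    if kind not in ("ridge", "rut"):
        raise ValueError("kind must be 'ridge' or 'rut'")
    if len(sif.S) == 0 or pcf.mesh is None or pcf.mesh.n_vertices == 0:
        raise DimensionError("empty mesh or fields")
    if len(sif.S) != pcf.mesh.n_vertices:
        raise DimensionError("fields not aligned to the mesh")
    if band is None:
        band = RIDGE_BAND if kind == "ridge" else RUT_BAND
    mesh = pcf.mesh
    S = sif.S
    in_band = np.isfinite(S) & (S >= band[0]) & (S <= band[1]) & pcf.valid
    strong = np.maximum(np.abs(pcf.kappa1), np.abs(pcf.kappa2))
    with np.errstate(invalid="ignore", divide="ignore"):
        anisotropy = np.abs(pcf.kappa1 - pcf.kappa2) / strong
    in_band &= np.nan_to_num(anisotropy) >= min_anisotropy
    score = np.full(len(S), -np.inf)
    ok = pcf.valid & np.isfinite(S)
    score[ok] = np.abs(S[ok]) * np.sqrt(
        (pcf.kappa1[ok] ** 2 + pcf.kappa2[ok] ** 2) / 2.0
    )

    adjacency = mesh.vertex_adjacency()
    weaker_is_1 = np.abs(pcf.kappa1) <= np.abs(pcf.kappa2)
    flagged, margins, directions = [], [], []
    for v in np.nonzero(in_band)[0]:
        along = pcf.e1[v] if weaker_is_1[v] else pcf.e2[v]
        transverse = pcf.e2[v] if weaker_is_1[v] else pcf.e1[v]
        margin = np.inf
        is_max = True
        has_transverse = False
        for nb in adjacency[v]:
            d = mesh.vertices[nb] - mesh.vertices[v]
            if abs(d @ transverse) < abs(d @ along):
                continue  # neighbour lies along the feature, not across it
            has_transverse = True
            diff = score[v] - score[nb]
            if diff <= 0:
                is_max = False
                break
            margin = min(margin, diff)
        if is_max and has_transverse:
            flagged.append(v)
            margins.append(margin if np.isfinite(margin) else 0.0)
            directions.append(along)
    return FeaturePointSet(
        mesh=mesh,
        indices=np.asarray(flagged, dtype=np.int64),
        strength=np.asarray(margins, dtype=float),
        kind=kind,
        directions=np.asarray(directions, dtype=float).reshape(-1, 3),
    )


def _pick_candidate(order: np.ndarray, dists: np.ndarray,
                    strengths: np.ndarray, vertex_ids: np.ndarray) -> int:
    """Nearest candidate; ties by larger strength, then smaller vertex id."""
    best = order[0]
    for j in order[1:]:
        if dists[j] > dists[best] + 1e-9:
            break
        if (strengths[j], -vertex_ids[j]) > (strengths[best], -vertex_ids[best]):
            best = j
    return int(best)


def trace_curve(
    points: FeaturePointSet,
    spec: AnatomicalCurveSpec | None,
    seed: np.ndarray,
    link_radius: float | None = None,
    angular_gate_deg: float = ANGULAR_GATE_DEG,
) -> TracedCurve:
    """Chain flagged feature points into an ordered polyline from a seed.

    Greedy nearest-neighbour linking: from the current endpoint, the nearest
    unused flagged point within the link radius (default 3x the median mesh
    edge length) whose step direction stays within the angular gate of the
    running direction is appended; ties are broken by larger strength, then
    smaller vertex index.  The trace grows in both directions from the seed
    and stops when no candidate passes the gate.
    """
    seed = np.asarray(seed, dtype=float)
    if len(points) == 0:
        raise SeedError("feature point set is empty")
    if link_radius is None:
        link_radius = LINK_RADIUS_FACTOR * float(
            np.median(points.mesh.edge_lengths()))
    pts = points.points
    d_seed = np.linalg.norm(pts - seed, axis=1)
    start = int(np.argmin(d_seed))
    if d_seed[start] > link_radius:
        raise SeedError(
            f"nearest feature point is {d_seed[start]:.2f} mm from the seed "
            f"(capture radius {link_radius:.2f} mm)")
    cos_gate = np.cos(np.deg2rad(angular_gate_deg))

    def grow(start_idx: int, init_dir: np.ndarray | None,
             used: set[int]) -> list[int]:
        chain = [start_idx]
        used.add(start_idx)
        direction = init_dir
        while True:
            cur = pts[chain[-1]]
            dvec = pts - cur
            dists = np.linalg.norm(dvec, axis=1)
            mask = (dists > 1e-12) & (dists <= link_radius)
            mask &= ~np.isin(np.arange(len(pts)),
                             np.fromiter(used, dtype=np.int64))
            if direction is not None:
                with np.errstate(invalid="ignore"):
                    cosang = (dvec @ direction) / np.where(dists > 0, dists, 1)
                mask &= cosang >= cos_gate
            cand = np.nonzero(mask)[0]
            if len(cand) == 0:
                return chain
            order = cand[np.argsort(dists[cand], kind="stable")]
            nxt = _pick_candidate(order, dists, points.strength,
                                  points.indices)
            step = pts[nxt] - cur
            direction = step / np.linalg.norm(step)
            chain.append(nxt)
            used.add(nxt)

    used: set[int] = set()
    forward = grow(start, None, used)
    backward: list[int] = []
    if len(forward) >= 2:
        back_dir = pts[forward[0]] - pts[forward[1]]
        back_dir /= np.linalg.norm(back_dir)
        backward = grow(start, back_dir, used - {start})[1:]
    chain = backward[::-1] + forward
    if len(chain) < MIN_CURVE_SUPPORT:
        raise TraceError(
            f"trace has only {len(chain)} points (< {MIN_CURVE_SUPPORT}); "
            "discarded as noise")
    name = spec.name if spec is not None else f"{points.kind} trace"
    polyline = pts[chain]
    curve = NamedCurve(name=name, points=polyline, kind=points.kind)
    return TracedCurve(curve=curve, vertex_ids=points.indices[chain],
                       spec=spec)


def _closest_on_triangles(p: np.ndarray, tri: np.ndarray
                          ) -> tuple[np.ndarray, float]:
    """Closest point to ``p`` over a (m, 3, 3) triangle array (Ericson)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac = b - a, c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = d1 / (d1 - d3)
        t_ac = d2 / (d2 - d6)
        t_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        denom = va + vb + vc
        v_in = vb / denom
        w_in = vc / denom
    out = a + ab * np.nan_to_num(v_in)[:, None] \
        + ac * np.nan_to_num(w_in)[:, None]
    m_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    out[m_bc] = b[m_bc] + np.nan_to_num(t_bc)[m_bc, None] * (c - b)[m_bc]
    m_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    out[m_ac] = a[m_ac] + np.nan_to_num(t_ac)[m_ac, None] * ac[m_ac]
    m_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    out[m_ab] = a[m_ab] + np.nan_to_num(t_ab)[m_ab, None] * ab[m_ab]
    m_c = (d6 >= 0) & (d5 <= d6)
    out[m_c] = c[m_c]
    m_b = (d3 >= 0) & (d4 <= d3)
    out[m_b] = b[m_b]
    m_a = (d1 <= 0) & (d2 <= 0)
    out[m_a] = a[m_a]
    dist = np.linalg.norm(out - p, axis=1)
    i = int(np.argmin(dist))
    return out[i], float(dist[i])


def project_point_to_mesh(mesh: SurfaceMesh, point: np.ndarray,
                          _tri_cache: dict | None = None
                          ) -> tuple[np.ndarray, float]:
    """Exact closest point on the triangulated surface and its distance."""
    tri = mesh.vertices[mesh.faces]
    return _closest_on_triangles(np.asarray(point, float), tri)


def closest_point_on_polyline(point: np.ndarray, polyline: np.ndarray
                              ) -> tuple[np.ndarray, float]:
    """Closest point on a polyline (exact over segments) and its distance."""
    p = np.asarray(point, dtype=float)
    a = polyline[:-1]
    b = polyline[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom[denom == 0] = 1.0
    t = np.clip(np.einsum("ij,ij->i", p - a, ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    d = np.linalg.norm(proj - p, axis=1)
    i = int(np.argmin(d))
    return proj[i], float(d[i])


def continue_curve(
    curve: TracedCurve,
    mesh: SurfaceMesh,
    mode: str,
    target: np.ndarray | NamedCurve | TracedCurve | None = None,
    length: float | None = None,
    step: float | None = None,
) -> TracedCurve:
    """Extend a curve across the surface where its feature signature ends.

    Modes: ``same-direction`` walks on in the last identified direction for
    ``length`` mm; ``toward-target`` walks to a 3D point; and
    ``closest-point-on-curve`` walks to (and ends at) the point of the
    target curve closest to the current endpoint.  The walk takes small
    straight steps (default half the median mesh edge length) projected back
    onto the mesh surface rather than exact geodesics.
    """
    pts = curve.curve.points
    if len(pts) < 2:
        raise ValueError("continuation needs a curve with >= 2 points "
                         "(a last direction must exist)")
    if step is None:
        step = CONTINUATION_STEP_FACTOR * float(np.median(mesh.edge_lengths()))
    tri = mesh.vertices[mesh.faces]

    def project(p: np.ndarray) -> np.ndarray:
        on_surf, dist = _closest_on_triangles(p, tri)
        if dist > max(10.0 * step, 5.0):
            raise ConnectivityError(
                f"continuation left the mesh (projection {dist:.2f} mm "
                "away)")
        return on_surf

    if mode == "closest-point-on-curve":
        if target is None:
            raise ValueError("closest-point-on-curve needs a target curve")
        tgt_poly = (target.curve.points if isinstance(target, TracedCurve)
                    else np.asarray(
                        target.points if isinstance(target, NamedCurve)
                        else target))
        end_point, _ = closest_point_on_polyline(pts[-1], tgt_poly)
        mode_walk = "toward-point"
    elif mode == "toward-target":
        if target is None:
            raise ValueError("toward-target needs a target point")
        end_point = np.asarray(target, dtype=float)
        mode_walk = "toward-point"
    elif mode == "same-direction":
        if length is None:
            raise ValueError("same-direction needs a length")
        end_point = None
        mode_walk = "same-direction"
    else:
        raise ValueError(f"unknown continuation mode {mode!r}")

    new_pts: list[np.ndarray] = []
    cur = pts[-1]
    direction = pts[-1] - pts[-2]
    direction = direction / np.linalg.norm(direction)
    travelled = 0.0
    max_steps = 100000
    for _ in range(max_steps):
        if mode_walk == "same-direction":
            if travelled >= length - 1e-9:
                break
            this_step = min(step, length - travelled)
            cand = cur + this_step * direction
        else:
            remaining = np.linalg.norm(end_point - cur)
            if remaining <= step:
                new_pts.append(project(end_point))
                break
            cand = cur + step * (end_point - cur) / remaining
        nxt = project(cand)
        advance = np.linalg.norm(nxt - cur)
        if advance < 1e-9:
            raise ConnectivityError("continuation made no progress on the "
                                    "surface")
        direction = (nxt - cur) / advance
        travelled += advance
        new_pts.append(nxt)
        cur = nxt
    if not new_pts:
        return curve
    all_pts = np.vstack([pts, new_pts])
    mask = np.concatenate([
        np.asarray(curve.continuation_mask, dtype=bool),
        np.ones(len(new_pts), dtype=bool),
    ])
    ids = np.concatenate([curve.vertex_ids,
                          np.full(len(new_pts), -1, dtype=np.int64)])
    new_curve = NamedCurve(curve.curve.name, all_pts, kind=curve.curve.kind)
    return TracedCurve(curve=new_curve, vertex_ids=ids, spec=curve.spec,
                       continuation_mask=mask)


def curve_catalog() -> list[AnatomicalCurveSpec]:
    """The sixteen named anatomical curves of the face.

    Ridge curves follow convex crests (brow, nose, lips, jaw, ear), rut
    curves follow concave troughs (below the eyes, the labial seal, the
    philtrum mid-line), the eyelid curves are edges of the palpebral fissure
    supplied by the user, and four mid-line curves are continuations that
    chain down from the philtrum to the chin.
    """
    C = AnatomicalCurveSpec
    return [
        C("brow ridge", "ridge",
          "Ridge points at the supra-orbital region of the forehead"),
        C("inferior orbital", "rut",
          "Rut points immediately below the lower eyelids"),
        C("lower/upper eye lid", "edge",
          "The superior and inferior edges of the palpebral fissure"),
        C("alar", "ridge",
          "Ridge points on the lateral extension of the nasal cartilage"),
        C("philtrum ridge", "ridge",
          "Ridge points immediately lateral to the mid-line philtrum"),
        C("labial seal", "rut",
          "Rut points where the upper and lower lips meet"),
        C("lower/upper lip", "ridge",
          "Ridge points along the lower/upper lip"),
        C("ear rim", "ridge",
          "Ridge points on the peripheral boundary of the ear cartilage "
          "(helix and lobe)"),
        C("tragus", "ridge",
          "Ridge points on the rim of the tragus, terminating at its "
          "superior and inferior points of maximum curvature"),
        C("mandible", "ridge",
          "Ridge points across the entire mandible (lower jaw)"),
        C("mid-line nasal profile", "ridge",
          "Ridge points from the nasal root along the dorsum of the nose "
          "and the columella"),
        C("mid-line philtrum", "rut",
          "Rut points between the columella and the upper lip"),
        C("mid-line upper lip", "continuation",
          "The continuation of the philtrum curve to the closest point on "
          "the labial seal curve",
          source_curve="mid-line philtrum", target_curve="labial seal",
          mode="closest-point-on-curve"),
        C("mid-line lower lip", "continuation",
          "The continuation of the mid-line upper lip curve to the closest "
          "point on the lower lip curve",
          source_curve="mid-line upper lip", target_curve="lower/upper lip",
          mode="closest-point-on-curve"),
        C("mid-line mentolabial", "continuation",
          "The continuation of the mid-line lower lip curve to the closest "
          "point of the mentolabial sulcus (rut)",
          source_curve="mid-line lower lip",
          target_feature="mentolabial sulcus",
          mode="closest-point-on-curve"),
        C("mid-line chin", "continuation",
          "The continuation of the mid-line mentolabial curve to the "
          "closest point on the mandible curve",
          source_curve="mid-line mentolabial", target_curve="mandible",
          mode="closest-point-on-curve"),
    ]
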