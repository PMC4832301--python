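# curvemark

Orientation-free 3D facial landmarking from surface curvature, with a
hierarchical reproducibility analysis.

Traditional anthropometric landmark definitions ("the most anterior
mid-point of the chin") only make sense after the head has been carefully
oriented, typically via the Frankfurt horizontal plane — itself built from
landmarks that are hard to place. `curvemark` implements the alternative:
define landmarks through the *differential geometry* of the facial surface,
which is intrinsic to the shape and independent of how the head is held.
It is written for morphometricians, clinical shape researchers and
computer-vision practitioners working with stereophotogrammetry or laser
surface scans (triangle meshes in mm).

## What it computes

**Shape-index fields.** Around any surface point the local shape is
`z = ½(κ₁x² + κ₂y²)` with principal curvatures κ₁ ≥ κ₂ (1/mm). The shape
index

&nbsp;&nbsp;&nbsp;&nbsp;S = (2/π)·tan⁻¹[(κ₂ + κ₁)/(κ₂ − κ₁)] ∈ [−1, 1]

runs from spherical cup (−1) through rut, saddle (0) and ridge to spherical
cap (+1), depends only on the *ratio* of curvatures, and is estimated per
vertex by least-squares quadric fitting over 10 mm neighbourhoods.
Convex/protruding anatomy (nose tip, chin) has negative curvatures and
S → +1 under outward normals.

**Anatomical curves.** Ridges (ruts) are chains of vertices whose shape
index lies in the convex (concave) band and which are locally most
ridge-like transverse to the crest. A catalog of sixteen named facial
curves (brow ridge, alar, labial seal, mid-line nasal profile, mandible,
…) covers the face; curves whose curvature signature fades (the mid-line
chain from philtrum to chin) are *continued* across the surface toward a
target curve.

**Landmarks from curves.** Curves are smoothed coordinate-wise with
penalised B-splines (p-splines, 8 effective degrees of freedom) and their
bending rate

&nbsp;&nbsp;&nbsp;&nbsp;κ(s) = |r′(s) × r″(s)| / |r′(s)|³

is evaluated along arc length. Landmarks are then the dominant curvature
peak of a curve (sellion, alare, cheilion, …), the crossing of two curves
(nasion, pronasale, gnathion, …), a curve endpoint (otobasion inferius),
or a furthest-from-chord fallback (pogonion). Each landmark carries a QC
metric (peak dominance ratio or crossing distance).

**Reproducibility analysis.** For a study in which observers repeatedly
landmark repeatedly-imaged subjects, the package registers all
configurations by Generalised Procrustes Analysis applied to repeat-pair
averages (propagating each pair's transform to its members), rotates the
collection into an anatomical x/y/z convention, and fits, per landmark
coordinate, the nested Gaussian random-effects model

&nbsp;&nbsp;&nbsp;&nbsp;v<sub>ijklm</sub> = μ + o<sub>i</sub> + s<sub>j</sub> + d<sub>jk</sub> + c<sub>jkl</sub> + r<sub>ijklm</sub>

by maximum likelihood (observer, subject, day, capture and repeat effects,
each with its own SD in mm). Balanced designs use an exact closed-form
spectral likelihood, so fits with tens of thousands of records take well
under a second. Summaries average the level SDs over landmarks and
dimensions and combine them into a per-identification reproducibility
`sqrt(3·(σ_o² + σ_d² + σ_c² + σ_r²))`.

A synthetic-phantom module generates surfaces, curves and hierarchical
datasets with closed-form ground truth, so the whole pipeline is testable
without any imaging data.

## Worked example

`examples/trace_ridge_curves.py` builds a phantom with two orthogonal
Gaussian ridges (stand-ins for the mid-line chin and mandible crests),
detects and traces the ridges, and locates gnathion as their crossing:

```
composite phantom: 961 vertices, 45 ridge points flagged
traced mid-line chin : 20 points
traced mandible      : 22 points
gnathion (crossing)  : (+0.76, +6.00, +9.55) mm
analytic intersection: (+0.00, +6.00, +10.00) mm
localisation error   : 0.88 mm (grid spacing 1.0 mm)
```

The crossing rule recovers the analytic crest intersection to within one
grid spacing with no orientation information at all. The other examples
cover shape-index estimation on a sphere (`shape_index_fields.py`, 0.5 %
mean curvature error), a maximal-curvature landmark on an arc-chain
phantom (`landmark_from_curvature_peak.py`), and a full simulated
reproducibility study (`reproducibility_study.py`).

A thin CLI wraps the same library surface:

```bash
curvemark phantom  --kind composite-face --out out/ph
curvemark curvature --mesh out/ph/composite-face.ply --radius 10 --out out/cv
curvemark simulate --preset paper --seed 1 --out out/sim
curvemark validate --design out/sim/design.csv --out out/val
```

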