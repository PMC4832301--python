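"""Ridge detection, tracing and a curve-crossing landmark.

Builds the composite phantom (two orthogonal Gaussian ridges standing in
for the mid-line chin and mandible crests), flags ridge points by shape
index with transverse non-maximum suppression, chains them into curves and
locates 'gnathion' as the crossing of the two smoothed curves.  The
analytic crest intersection is known by construction, so the localisation
error is printed in mm.
"""

import numpy as np

from curvemark import compute_fields, smooth_curve
from curvemark.curves import (AnatomicalCurveSpec, detect_feature_points,
                              trace_curve)
from curvemark.landmarks import apply_landmark_rules, landmark_catalog
from curvemark.phantoms import PhantomSpec, make_surface

spec = PhantomSpec(kind="composite-face", height=5.0, width=3.0,
                   spacing=1.0, extent=15.0, ridge_offset=6.0)
mesh, truth = make_surface(spec)
fields = compute_fields(mesh, radius=2.5)
points = detect_feature_points(fields, "ridge")
print(f"composite phantom: {mesh.n_vertices} vertices, "
      f"{len(points)} ridge points flagged")

chin = trace_curve(points, AnatomicalCurveSpec("mid-line chin", "ridge"),
                   seed=np.array([0.0, -12.0, 5.0]), link_radius=6.0)
mand = trace_curve(points, AnatomicalCurveSpec("mandible", "ridge"),
                   seed=np.array([-12.0, 6.0, 5.0]), link_radius=6.0)
print(f"traced mid-line chin : {len(chin.curve)} points")
print(f"traced mandible      : {len(mand.curve)} points")

result = apply_landmark_rules(
    {"mid-line chin": smooth_curve(chin.curve),
     "mandible": smooth_curve(mand.curve)},
    [r for r in landmark_catalog() if r.name == "gnathion"])
gn = result.config["gnathion"]
err = np.linalg.norm(gn - truth.crossing)
print(f"gnathion (crossing)  : ({gn[0]:+.2f}, {gn[1]:+.2f}, {gn[2]:+.2f}) mm")
print(f"analytic intersection: ({truth.crossing[0]:+.2f}, "
      f"{truth.crossing[1]:+.2f}, {truth.crossing[2]:+.2f}) mm")
print(f"localisation error   : {err:.2f} mm "
      f"(grid spacing {spec.spacing} mm)")
print("-> the crossing rule recovers the crest intersection to within one "
      "grid spacing without any orientation of the surface.")
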