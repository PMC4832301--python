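"""Shape-index fields on a surface of known curvature.

Builds a 50 mm sphere phantom, estimates per-vertex principal curvatures by
local quadric fitting (10 mm neighbourhoods) and prints how well the
estimates recover the analytic curvature -1/r = -0.02 / mm, together with
the shape-category census (a sphere is a 'spherical cap' everywhere under
outward normals).
"""

import numpy as np

from curvemark import compute_fields
from curvemark.phantoms import PhantomSpec, make_surface

mesh, truth = make_surface(PhantomSpec(kind="sphere", radius=50.0,
                                       spacing=5.0))
pcf, sif = compute_fields(mesh, radius=10.0)

rel_err = np.abs(pcf.kappa1[pcf.valid] - truth.kappa1[pcf.valid]) / 0.02
print(f"sphere phantom: {mesh.n_vertices} vertices")
print(f"analytic curvature     : {truth.kappa1[0]:+.4f} / mm")
print(f"estimated kappa1 (mean): {pcf.kappa1[pcf.valid].mean():+.4f} / mm")
print(f"relative error         : mean {rel_err.mean():.2%}, "
      f"max {rel_err.max():.2%}")
cats, counts = np.unique(sif.categories, return_counts=True)
print("shape categories       :",
      ", ".join(f"{c} x{n}" for c, n in zip(cats, counts)))
print("-> every vertex of a convex sphere is a spherical cap (S = +1); "
      "the curvature error is the quadric-fit truncation bias.")
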