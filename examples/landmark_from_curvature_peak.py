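"""A maximal-curvature landmark on a smoothed curve.

Builds an arc-chain phantom standing in for the mid-line nasal profile: a
gentle 40 mm-radius arc, a tight 8 mm-radius arc (the nasal root), then a
long 40 mm-radius arc.  The curve is smoothed with p-splines (8 effective
degrees of freedom), its bending rate kappa(s) is evaluated along arc
length, and 'sellion' is placed at the dominant curvature peak in the
nasal-root half of the curve.
"""

import numpy as np

from curvemark import smooth_curve
from curvemark.landmarks import (apply_landmark_rules, curve_curvature,
                                 dominant_peak, landmark_catalog)
from curvemark.phantoms import PhantomSpec, make_curve

curve, truth = make_curve(PhantomSpec(
    kind="arc-chain", arc_radii=(40.0, 8.0, 40.0),
    arc_lengths=(10.0, 8.0, 20.0), noise_sd=0.05, seed=1), n_points=150)
sc = smooth_curve(curve, df=8)
profile = curve_curvature(sc)
s_star, k_star, dominance = dominant_peak(profile, window=(0, sc.length / 2))

print(f"arc-chain phantom: radii 40/8/40 mm, curve length "
      f"{sc.length:.1f} mm, noise 0.05 mm")
print(f"curvature peak    : kappa = {k_star:.3f} /mm at s = {s_star:.1f} mm")
print(f"analytic peak     : kappa = {1 / 8:.3f} /mm at s = "
      f"{truth.peak_s:.1f} mm (centre of the tight arc)")
print(f"dominance ratio   : {dominance:.1f} (peak vs next local maximum)")

result = apply_landmark_rules(
    {"mid-line nasal profile": curve},
    [r for r in landmark_catalog() if r.name == "sellion"])
pt = result.config["sellion"]
i = int(np.argmin(np.abs(truth.s - truth.peak_s)))
print(f"sellion           : ({pt[0]:+.2f}, {pt[1]:+.2f}, {pt[2]:+.2f}) mm, "
      f"{np.linalg.norm(pt - curve.points[i]):.2f} mm from the analytic "
      "peak point")
print("-> a dominant curvature peak makes the maximal-curvature definition "
      "well founded; the dominance ratio is the per-landmark QC metric.")
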