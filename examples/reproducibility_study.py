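"""A full hierarchical reproducibility analysis on simulated data.

Simulates the validation-study design (2 observers per definition group, 4
subjects imaged twice on each of 2 days, every image landmarked twice) with
each image wrapped in a random similarity transform, registers the dataset
by GPA on repeat-pair averages, rotates it into the anatomical convention,
fits the nested random-effects model per landmark and dimension by ML, and
prints the per-level SDs averaged over landmarks/dimensions together with
the combined per-identification reproducibility.
"""

import warnings

import numpy as np

from curvemark.phantoms import TABLE4_CURVATURE, paper_design, \
    simulate_hierarchy
from curvemark.reproducibility import (fit_components, orient_to_convention,
                                       register_hierarchical, summarize)

warnings.filterwarnings("ignore")

truth = paper_design(sds=TABLE4_CURVATURE, seed=0, perturb=True)
data = simulate_hierarchy(truth)
print(f"simulated {len(data)} annotations "
      f"({len(data.subset_group('curvature'))} per definition group), "
      "each image in its own scanner frame")

registered = orient_to_convention(register_hierarchical(data))
group = registered.subset_group("curvature")
components = [fit_components(group, lm, dim)
              for lm in group.common_landmarks() for dim in range(3)]
summary = summarize(components)

print("\nfitted level SDs, averaged over landmarks and dimensions (mm):")
for level in ("observer", "day", "capture", "repeat", "subject"):
    print(f"  {level:<9} {summary.level_sds[level]:5.3f}   "
          f"(simulation truth {truth.sds[level]:5.3f})")
print(f"\ncombined per-identification SD: {summary.combined:.2f} mm")
print("  = sqrt(3 x sum of squared SDs over observer/day/capture/repeat);")
print("  the subject level is excluded: it is anatomy, not error.")
print("\nper-landmark reproducibility sphere radii (mm):")
for name, radius in summary.sphere_radii.items():
    print(f"  {name:<18} {radius:5.2f}")
print("-> at this small design the per-level estimates are noisy (2 "
      "observers!), which is the point the expanded simulations make.")
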