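"""Sholl branching profiles of synthetic nerves, with polynomial fits.

Builds a Y-shaped nerve whose geometry makes the expected profile obvious
(one stem crossing each inner sphere once, two branches beyond the
bifurcation), computes the exact 3D Sholl profile with 10 μm shells, and
fits a polynomial summary to a larger random tree.
"""

import numpy as np

from ancmorph import fit_profile, sholl_profile
from ancmorph.synthetic import TraceSpec, gen_trace

# A nerve that runs straight for 50 μm, then splits into two branches whose
# tips sit exactly 100 μm from the exit point.
trace, _ = gen_trace(TraceSpec(kind="y_tree", bifurcation_radius=50.0,
                               tip_radius=100.0, name="y_nerve"))
profile = sholl_profile(trace, step=10.0)
print("Y-tree Sholl profile (radius μm -> crossings):")
for r, n in zip(profile.radii, profile.counts):
    print(f"  {r:5.0f}  {n}")
print("-> one crossing per sphere inside the bifurcation radius, two "
      "between the bifurcation and the tips, zero at the tip sphere "
      "(the nerve never passes it).\n")

# A random branching tree, denser sampling, with a degree-5 polynomial fit —
# the standard smooth summary of a branching profile.
trace, _ = gen_trace(TraceSpec(kind="random_tree", seed=7, name="rnd"))
profile = sholl_profile(trace, step=5.0)
fit = fit_profile(profile, degree=5)
print(f"random tree: {len(trace.nodes)} nodes, "
      f"{int(profile.counts.sum())} total crossings over "
      f"{len(profile.radii)} shells")
print("degree-5 fit coefficients (ascending powers):")
print("  " + np.array2string(fit.coefficients, precision=6))
peak = profile.radii[np.argmax(profile.counts)]
print(f"branching peaks near r = {peak:.0f} μm; the fitted curve smooths "
      "the integer counts for comparing nerves exiting different septa.")
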