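# Methods

## Scope and data model

`ancmorph` quantifies the anatomy of the cephalopod axial nerve cord (ANC)
from three kinds of input: neurite reconstructions in SWC format (one
rooted tree per traced nerve, coordinates in μm), tidy tables of manual
measurements (segment widths and counts, sucker widths, nuclei patch
counts/areas) with the factors *position* (proximal / intermediate /
distal), *side* (anterior / posterior) and *territory* (external side ExA /
internal side InA), and 2D grayscale image patches for nuclei counting.
SWC has no label field, so group labels and the `reaches_skin` flag travel
in a sidecar CSV (`trace,group,reaches_skin`). Units are μm throughout; no
conversion is attempted.

SWC parsing accepts space- or tab-delimited lines, comments, blank lines,
non-consecutive ids and child-before-parent order (two-pass parse), and
rejects duplicate ids, dangling parents, multiple roots and cycles with
errors naming the offending node or line. One SWC file is treated as one
nerve; whether paths sharing an exit should be merged upstream is a
tracing decision this package does not make.

## Sholl analysis

The branching profile of a nerve is the number of intersections between
its traced polyline and spheres of radius `step`, `2·step`, … centred at
the trace root (the nerve's exit from the ANC), default `step` = 10 μm.
Shells extend to the smallest multiple of `step` at or beyond the most
distant *node* (spheres are geometric, not geodesic). Counting is exact:
for an edge from `p` to `q`, crossings of the sphere of radius `r` are the
sign changes of `‖p + t(q−p) − c‖² − r²`, a quadratic in `t`, over the
segment. Conventions:

- a re-entrant edge whose two roots both lie strictly inside the segment
  contributes 2 (intersection counting, not visit counting);
- a tangential touch (double root) contributes 0;
- a non-root node lying exactly on a sphere contributes a single crossing
  iff the sign of distance-minus-radius just before it (on the parent
  edge) is nonzero and at least one child edge departs with the opposite
  sign; a root or leaf exactly on a sphere contributes 0. The
  at-least-one-child rule is this package's tie-break for multifurcations;
  it agrees with the limit of perturbed geometry in the generic case of a
  single child.

Zero-tests use a relative tolerance of 1e−9 on the squared-distance scale.
Profiles are computed in 3D (projection-plane Sholl is out of scope).

The independent oracle (`sholl_profile_dense`) resamples every edge at
0.01 μm, adds one sample at each edge's point of closest approach to the
centre (so dips narrower than the spacing still register), and counts sign
changes per shell; it shares no code with the quadratic solver. Analytic
and oracle counts agree on every shell for 100 random trees in the
acceptance suite.

Profile fitting is plain unweighted least squares of a degree-5 polynomial
(default) on the (radius, count) pairs, computed in a scaled domain for
conditioning and returned as ascending-power coefficients; fitting is
refused, not silently downgraded, when there are fewer than degree+1
shells. Radii (not counts) are normalized by the length of the nerve
flagged `reaches_skin` — anatomically the longest nerve — falling back to
the maximum cable length with a warning when no flag is present.

## Average trajectory

The exit direction of a nerve is the vector from its root to the centre of
its traced points. The default centre is the unweighted mean of all node
coordinates, root included, matching a point list pulled directly from a
tracer; an arc-length-weighted centroid (each edge's midpoint weighted by
its length) is provided because manual traces have uneven node density.
Vectors may be divided by the skin-reaching nerve length for comparison
across preparations. The vector is translation-invariant and
rotation-equivariant by construction.

## Angular coverage

Tips of the oral nerves decorating one sucker are centred on their
centroid, the proximal–distal coordinate is dropped (configurable axis;
the sucker circle lies in the transverse plane), and each planar vector is
normalized to the unit circle. The circle is then partitioned: between
adjacent tips of different groups a boundary sits at the circular
midpoint; arcs between same-group tips belong wholly to that group. This
equals assigning every angle to its nearest tip and guarantees the
per-group extents sum to 360° — consistent with coverage always being
reported as complementary percentages. A bare per-group angular span would
not have that property, which is why the partition definition is used.
Ties (differently-labelled tips at one angle) give zero-width arcs; with a
single group present that group covers 100% and a warning is issued; a tip
coincident with the centroid has no direction and is rejected by name.

Two properties of the statistic discovered during validation and worth
knowing:

- **Centroid sensitivity.** The tip centroid is a consistent estimator of
  the circle centre only when angular tip density is roughly uniform
  around the circle. If one group's tips are packed twice as densely as
  the other's, the centroid shifts toward the dense side and the recovered
  fractions are biased by several percentage points (measured ≈ −4 points
  for a 216°/144° split with equal group counts). Real suckers show
  radially symmetric decoration, the regime in which the estimator is
  unbiased; the generator therefore allocates tip counts proportional to
  arc width by default and keeps `allocation="equal"` available to
  demonstrate the bias.
- **Grid discretization.** The 36,000-angle nearest-tip grid cross-check
  accrues an error of up to one cell per group boundary; over many
  boundaries these accumulate beyond a single cell. The equivalence test
  therefore draws tip angles from the lattice 0.005° + k·0.02°, which
  places every midpoint boundary exactly halfway between grid points so
  the grid measures each arc exactly; agreement is then at float precision
  while the comparison threshold stays at one grid cell (0.01°).

## Segment and sucker morphometrics

Closed forms follow the measurement protocol: segments per sucker is the
mean of the anterior and posterior counts over a run of suckers divided by
the number of suckers (six by default); cell density is nuclei count over
patch area; cross-sectional area is width × height. Width summaries use
two-step averaging — anterior and posterior pooled within each (position,
territory) cell, then the "total" per position is the mean of the ExA and
InA cell means, *not* the pooled grand mean, so an unbalanced territory
cannot dominate. `sem` is the n−1 sample standard deviation over √n.

The factorial stage is a two-way ANOVA with interaction on a tidy table
(statsmodels OLS), using Type II sums of squares, which coincide with the
classical decomposition on the balanced designs used here but remain
sensible when cells are lost. *Side* is averaged over rather than entered
as a factor, following the measurement protocol's averaging order. The
interaction term requires a full, replicated design; otherwise the
additive model is fit with a warning. Tukey HSD comparisons run over the
levels of each main factor using the pooled residual mean square and
degrees of freedom of the fitted model (Tukey–Kramer for unequal n), with
p-values from the studentized range distribution; α = 0.05 throughout.
Calibration on 1,000 simulated null tables gives per-factor type-I error
inside [2.5%, 7.5%], and a 3σ territory offset at 24 replicates per cell
is detected in ≥ 99% of runs (both recomputed by the acceptance suite).

## Nuclei counting

Particle analysis on intensity images in [0, 1]: binarize at a fixed
global threshold (`pixels ≥ threshold`; Otsu optional, off by default
since the upstream protocol specifies none), label connected components
(8-connectivity by default, 4 available), drop components smaller than
`min_area` μm², and report count, centroids and areas in physical units
via the pixel size. Density over a rectangle counts components whose
centroid lies in the half-open rectangle [r0,r1)×[c0,c1), so tiling
rectangles never double-count. Counts are monotonically non-increasing in
`min_area` on any image, and in threshold on unimodal-blob images (the
targeted regime); on arbitrary noise a rising threshold can split
components and is not monotone — a property of connected components, not
of this implementation.

## Synthetic data

Generators are pure functions of their spec (seed included) and draw from
per-generator named streams, so adding a generator never perturbs existing
fixtures. Defaults encode the study conditions the package expects:
segment tables with base width 40 μm, 8 μm taper per position step, +5 μm
ExA−InA offset, 3 μm Gaussian noise, 24 replicates per cell split evenly
across sides, and 7.5 segments per sucker over six-sucker runs; tip sets
with a 216°/144° (60/40) arc split at radius 50 μm with 10% radial jitter;
random branching trees with 5–15 μm segments and ~30° directional drift;
blob images with σ = 3 px Gaussian nuclei placed ≥ 8σ apart by rejection
sampling. These are synthetic defaults informed by the measured structure
of the octopus arm, not data. The generators emulate the *statistical*
structure only: no tracing noise model, no anisotropic point densities
along real neurites, no uneven illumination or touching nuclei — so
passing tests certify the algorithms and their calibration, not robustness
to those real-data artefacts.

## Problem sizes

The shipped test and acceptance runs use 100 random trees for the Sholl
oracle, 100 tip sets of 30 (equivalence) and ~400 (recovery) tips, 1,000
null + 200 alternative ANOVA tables of 144 rows, and 50 blob images —
sizes chosen so each agreement rate or calibration band is measured with
comfortable margin while a full run stays around a minute.

## Known limitations

- Sholl is 3D-only; no geodesic (path-distance) variant or branch-order
  statistics.
- Coverage percentages are plane-dependent for strongly tilted tip
  clouds; the package projects along a declared axis and does not attempt
  to infer the sucker plane.
- No watershed splitting of touching nuclei; a merged pair counts once.
- Mixed-effects structure (multiple arms/animals) is out of scope; the
  ANOVA treats rows as exchangeable replicates.
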