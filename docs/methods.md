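# Methods

This note records the models, defaults and design choices behind `rodplan`,
and what the synthetic phantoms do and do not demonstrate.

## Clinical model

The toolkit plans a spatially fractionated external-beam **boost** of
30 Gy in 5 fractions to a cervix-uteri clinical target volume (CTV),
prescribed to the 90% coverage level (D90% = 30 Gy), delivered after a
uniform 45 Gy conventionally fractionated external-beam course. Heterogeneity
aims for the CTV are V45Gy ≥ 50–55% and V60Gy ≥ 30% (150% and 200% of the
prescription), mimicking the central hot regions of a brachytherapy boost.
Organ-at-risk (OAR) near-maximum (D2cm3) boost aims are bladder 23.75 Gy,
rectum 17.0 Gy, sigmoid 19.5 Gy, bowel 17.0 Gy with hard upper limits
27.5 / 19.45 / 21.65 / 19.45 Gy.

### EQD2 arithmetic

All scalar metrics can be converted to equivalent dose in 2 Gy fractions,

EQD2 = n·d·(1 + d/(α/β)) / (1 + 2/(α/β)),

with α/β = 10 Gy for target structures and 3 Gy for OARs, and summed with the
prior course. The prior is modelled as **25 × 1.8 Gy** by default: this is
the fractionation under which the shipped objective table is internally
consistent — 30 Gy/5 fx + 45 Gy/25 fx gives the CTV objective 40 + 44.25 =
84.25 Gy, and the OAR boost limits are exactly the inverse-EQD2 images of the
cumulative limits 80/65/70/65 Gy (e.g. bladder: 80 − 43.2 = 36.8 Gy EQD2 →
23.75 Gy over 5 fractions). A 2 Gy/fraction prior is available via
`PriorCourse(n_fractions=...)` but does not reproduce that table. Two
rounding quirks of the constraint table are kept as printed rather than
silently corrected: the sigmoid aim is quoted as 19.5 Gy where the exact
inverse is 19.449 Gy, and its aim therefore back-computes to a cumulative
70.11 Gy rather than 70.0. EQD2 is applied to scalar metrics only, not
voxel-wise.

## Synthetic phantoms (`rodplan.phantom`)

Phantoms replace patient CT contours; only the **relative** pelvic geometry
matters to the method. The CTV is a super-ellipsoid (exponent 2.2, semi-axis
ratios 1 : 0.8 : 1.6) bent anteriorly along z by a configurable angle
(default 20°, emulating uterine curvature and giving the spline rods
something to follow); its scale is solved so the voxelized volume matches the
requested value (default 51 cm³, the cohort median; the supported range is
roughly 30–90 cm³ on the fixed 130 × 150 × 145 mm stage). OARs are primitive
shapes at anatomical offsets with seeded jitter: bladder (ellipsoid,
anterior), rectum and sigmoid (capped cylinders, posterior), bowel bag (flat
ellipsoid, superior). A minimum CTV–OAR surface gap (default 4 mm) and
pairwise disjointness are enforced by carving. The default grid spacing is
**1.25 mm** so a 5 mm rod spans four voxels; 2.5 mm (the usual dose-grid
resolution) is available for fast runs and is used by most of the test suite.

Phantom OAR–CTV distances are free parameters, not calibrated to any cohort:
absolute OAR doses produced on phantoms are therefore illustrative, while
geometric properties (pitch, gaps, containment) and all closed-form
arithmetic are exact.

## Rod structures (`rodplan.rods`)

- **Axis convention.** The rod axis is +z rotated first by `angle_zx` about
  y, then by `angle_zy` about x; both angles must lie strictly inside
  (−90°, 90°).
- **Lattice anchoring.** The square lattice (pitch 15 mm) lives in the plane
  perpendicular to the axis and is anchored at the projection of the target
  centroid, plus a user offset; anchoring at the centroid makes rod placement
  translation-equivariant.
- **Selection.** With `max_rods` set (default 3), the most central rod is
  always kept and remaining slots go to the rods with the greatest
  within-target length, matching the clinical template of one central rod
  spanning the CTV plus shorter lateral rods.
- **Voxelization rule.** A voxel belongs to a rod iff its center lies inside
  the continuous tube; this is simple, testable and resolution-convergent,
  but means voxelized cross-sections can be up to one voxel slimmer than the
  nominal diameter at 1.25 mm spacing.
- **Bending rods** interpolate ≥ 2 seed points with a natural cubic spline
  (chord-length parameterisation), resample the curve uniformly in arc
  length at a quarter voxel, and sweep a sphere of the rod diameter; the
  tube is clipped to the target and self-overlap (curvature radius below the
  tube radius) is warned about, not forbidden.
- **Valley.** valley = target ∖ expand(rods, margin). The margin default is
  3 mm (configurable); expansion is Euclidean distance-transform dilation on
  voxel centers, so margins below the grid spacing are no-ops at that
  resolution.

## Surrogate optimizer (`rodplan.optimizer`)

The commercial arc-therapy engine the technique was designed for is out of
scope; the optimizer here is an explicit **surrogate** whose only job is to
produce smooth, constraint-shaped dose. Dose = nonnegative intensity field
convolved with an isotropic Gaussian (σ = 3 mm ≈ photon penumbra at depth),
which forbids unphysically sharp gradients and makes the 5 mm-rod/10 mm-gap
pattern genuinely hard — the same resolution argument that sets the rod
diameter at the MLC leaf width clinically. The intensity is fitted by
projected gradient descent (fixed budget, default 300 iterations; step
normalized to the gradient's max, 2 Gy per step; warm start: prescription
inside CTV + 5 mm) on quadratic penalties: CTV (and optionally PTV) coverage
below prescription, rod dose below `rod_min_gy` (default 60 Gy, the lower
end of the 60–80 Gy peak window), valley dose above 45 Gy (peak-and-valley
strategy only), each OAR's hottest-2 cm³ voxel set (recomputed every
iteration) above its hard limit, and a quadratic decay penalty outside
CTV + 20 mm. The descent is deterministic; non-convergence (no objective
decrease over the last 10% of iterations) warns and returns the best
iterate. `iterations=0` returns a zero dose — the warm start is part of the
first iteration.

Known surrogate limitations, stated plainly:

- There is **no dose bath**: a Gaussian σ = 3 mm falls off far faster than a
  real rotational delivery, so phantom OAR D2cm3 values are much lower than
  clinical ones, and the mitigation renormalisation consequently finds very
  large safe scales (the clinical analogue raises D90 by 10–15%; on phantoms
  the closed-form scale can be several-fold). The mitigation *logic* —
  closed-form optimal scale, binding OAR at equality — is exact regardless.
- Achieved CTV V45/V60 depend on the iteration budget and weights; the
  implemented checks are the qualitative orderings (peak-only V45 >
  peak-and-valley V45; uniform strategy V60 = 0; rod/valley mean-dose ratio
  > 1.2), not the clinical cohort's absolute percentages, which came from a
  full treatment planning system on patient anatomy.

## DVH metrics (`rodplan.dvh`)

Cumulative DVHs use a fixed **0.02 Gy** binning; the curve is the fraction of
structure volume receiving at least each bin edge (1.0 at 0 Gy, monotone,
0 one bin above the maximum). D-metrics interpolate linearly between bin
edges; bin width is specified, interpolation is a package choice. Two metric
routes coexist deliberately: binned-DVH metrics (curves, averages,
prescription normalisation) and exact voxel-sort quantiles (plan pass/fail
and the mitigation scale), which are strictly linear under global scaling —
the property that makes the closed-form mitigation scale exactly optimal.
The two agree within one bin width (property-tested). Prescription
normalisation is closed-form (D90 is linear in scale) refined by a second
pass to absorb re-binning error; D2cm3 uses absolute volume from voxel
counts, with no partial-volume weighting. Average DVHs report per-bin mean
with 1 SD and 1.95 SD bands (sample SD, n − 1), clipped to [0, 1].

## Mitigation strategies (`rodplan.evaluation`)

- **Strategy A** (renormalise): global scale s\* = min over OARs of
  (hard limit / current D2cm3); after scaling the binding OAR sits exactly at
  its limit and s\*(1 ± ε) flips feasibility at ε = 10⁻⁶. Only OAR
  constraints bind; CTV aims are not treated as ceilings.
- **Strategy B** (re-optimise): the optimizer reruns with the PTV2mm added as
  a coverage structure, then strategy A is applied. Reports are labeled
  "`<strategy> B`".

Cohort summaries report mean ± sample SD and [min, max] per metric.

## Problem sizes

Defaults target desk-scale runs: a 51 cm³ phantom at 1.25 mm spacing is a
104 × 120 × 116 grid, and one 300-iteration optimization takes on the order
of half a minute on a single core. The test suite exercises plan-level
behaviour at 2.5 mm spacing with 120–150 iterations, where a full
phantom-to-report pipeline takes a few seconds; the acceptance script runs
the two headline plans at the default 1.25 mm resolution.
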