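# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `pulstrans`. It is written for users who need to judge
what the package's validation does — and does not — establish.

## Data model and conventions

The unit system is millimetres for geometry and mL/s for flow throughout;
fitted slopes are converted to `p_pi` per metre (×1000) for reporting,
since per-millimetre slopes are numerically tiny. `order_index` is 0-based
and increases downstream; flow is signed positive in the direction of
increasing index. `orient_segment` enforces this by inspecting the
segment-median of the per-point mean flow: a negative median flips the
point order and negates tangents and traces. The median (rather than the
mean) makes the decision robust to a few noise-dominated points; an exactly
zero median is refused as ambiguous rather than guessed.

Cross-section tables are plain CSV with a fixed, documented header and one
flow column per cardiac phase. Floats are written with 12 significant
digits, which bounds round-trip error at ~1e-12 relative — far below any
physical effect of interest.

## Vessel reconnection

Centreline tools export vessels as unlinked segments. Reconnection is a
breadth-first search from a user-chosen root: every frontier terminal
searches for unconnected segment inlets within a radius of
`search_distance_voxels × voxel_size_mm` (default 8 voxels at 1 mm — the
scanned resolution of typical high-resolution intracranial 4D flow).
When several terminals compete for one inlet (kissing or crossing
vessels), the candidate whose terminal and inlet tangents have the largest
inner product wins; remaining ties break on smaller gap, then on smaller
parent id. The tie-break chain makes `build_tree` deterministic and
invariant to the order segments are presented in. Each segment accepts at
most one parent and connected segments are never revisited, so the result
is a rooted forest restricted to one tree — cycles cannot form by
construction.

Distance from the root inlet sums Euclidean steps between consecutive
centreline points and adds each traversed junction's straight-line gap.
Treating the junction bridge as straight ignores local curvature; the
shift-error simulation below quantifies why such distance errors are
benign when they are symmetric.

The search radius is per-run configurable because real anatomies
occasionally need a larger radius for specific junctions (e.g. basilar to
posterior cerebral gaps); excluded segments (communicating arteries) are
listed by id and never linked, keeping the three perfusion territories
separate.

## Quality score

Each cross-section's `Q` sums four dimensionless terms on a 5-point
stencil (half-width 2, truncated at segment ends): stencil-mean
circularity `r_min/r_max`, mean-flow conservation `1 − σ/μ`, area
conservation `1 − σ/μ`, and waveform conservation `1 − Δq/μ`, where `Δq`
averages the per-phase spread of the stencil's traces. Choices worth
stating explicitly:

* **Population standard deviation** (divide by n) — the stencil is a fixed
  window, not a sample from a population; this also keeps oracle tests
  exact.
* **No clamping** — a corrupted stencil can push a term negative and `Q`
  well below zero. That is intentional: the `Q ≥ 2.5` threshold is the
  mechanism that discards such points, and clamping would compress exactly
  the signal the threshold needs.
* **Stencil-mean circularity** (not the point value) — all four terms then
  share the same support, and a single eccentric outlier degrades its
  whole neighbourhood, which matches how segmentation failures cluster at
  bifurcations.
* **Truncation at ends** (not reflection or exclusion) — endpoints keep a
  score from the points that exist; endpoint unreliability is handled by
  the threshold, not by refusing to score.

`Q` is invariant to uniform rescaling of all flow traces and to consistent
geometric rescaling, so it measures data consistency, not vessel size or
flow magnitude.

## Transmission fit

Samples are all rooted cross-sections; those with `Q < 2.5` are discarded,
the rest weighted `w = (Q − 2.5)/1.5`, clamped to 1 above `Q = 4`
(impossible under the term bounds, clamped defensively). The weighted
least squares problem is a 2-parameter convex quadratic and is solved in
closed form from the normal equations; no iteration, no tolerance. The
weighted R² is `1 − SSres_w/SStot_w` with the total sum of squares about
the weighted mean — one of several conventions in circulation, so it is
stated here and pinned by an oracle test. Two sensitivity modes mirror the
natural robustness checks: `unweighted` (threshold only, unit weights) and
`unthresholded` (unit weights, nothing discarded).

Degenerate designs — fewer than two included samples, no distance spread,
zero total weight — raise errors rather than returning NaNs.

## Synthetic data generator

`SyntheticSpec`/`make_tree` build a bifurcating tree of gently curved
polyline segments: children leave the parent terminal at 35° around evenly
spread azimuths, radii shrink by 0.8 per generation from 2 mm, and mean
flow splits equally at branches from 5 mL/s at the root (a plausible
internal-carotid inflow). `make_flow_traces` assigns each point a raised
sinusoid over `S = 20` phases whose amplitude is solved so the *sampled*
trace's pulsatility equals the target `offset + slope·d` exactly (noise,
when requested, is added to the target before solving, so the realised
`p_pi` equals the noisy target to machine precision). Targets requiring
negative-flow excursions (`p_pi ≳ 2`) are refused.

What the generator does **not** emulate: measurement noise correlated
across phases, partial-volume effects, velocity-dependent SNR, vessel
taper within segments, anatomical loops (the circle of Willis is cut by
excluding communicating arteries in real use), and physiological
pulsatility oscillations along vessels. Passing tests therefore establish
algorithmic correctness — recovery of known slopes, exact connectivity,
threshold behaviour — not robustness to every artefact of real 4D flow.

### End corruption

`corrupt_for_quality` degrades the first and last 15% of each segment's
points (eccentric radii ×0.35, per-phase Gaussian trace jitter at 0.8 of
the local mean flow), emulating the segmentation failures that cluster at
vessel junctions. This drives endpoint `Q` below 2.5 while leaving deep
interiors intact, and gives the thresholded-vs-unthresholded comparison
its teeth: corrupted-end pulsatility is wildly wrong, and discarding it
demonstrably stabilises the slope.

## Junction shift-error simulation

Mis-connected kissing/crossing vessels shift all downstream distances by
the difference between true and assigned paths. The simulation draws an
independent shift per junction from Uniform(−8, +8) mm — the connectivity
search scale — clamps it so gaps stay nonnegative, adds the cumulative
shift to downstream distances, and refits the line with uniform weights
against the corrupted distances while pulsatility keeps its true-distance
values. Over 1000 cases with true slope −1 `p_pi`/m the fitted slope
distribution is symmetric and its mean stays within 1% of the truth
(−0.9947 ± 0.005 at the default seed).

Two structural points matter:

* The default junction gap equals the shift scale (8 mm), so the
  nonnegativity clamp never truncates a draw; a truncated draw would make
  the shift distribution asymmetric and genuinely bias the slope.
* Distance errors enter the *regressor*, so this is an errors-in-variables
  problem: the slope attenuates by roughly the ratio of cumulative shift
  variance to distance spread. The default geometry (depth 6, 90 points
  per segment at 1 mm) keeps that ratio near 0.5%, small enough that the
  symmetric-shift conclusion is what the experiment measures. The
  resulting tree (~0.67 m root-to-leaf) is a stylised geometry chosen for
  this variance ratio, deliberately longer than a real cerebral tree
  (~0.18 m); with realistic spans, ±8 mm junction errors would attenuate
  the slope by several percent, which is worth remembering when
  interpreting real-data fits with many mis-connections.

The tree geometry is a deterministic function of the spec seed, so the
experiment builds it once and repeats only the random draws per case, with
shift propagation vectorised over points; this is numerically identical to
regenerating the tree per case. Pulsatility is assigned directly from the
linear law (no waveform synthesis) — the waveform path is exercised by its
own tests.

## Problem sizes used in validation

The test suite uses trees of 7–127 segments (roughly 200–11 000
cross-sections), 1000 Monte-Carlo cases for the shift experiment, 200
replicates for noisy parameter recovery, 200 random trees for connectivity
recovery, and 50 replicates for the thresholding comparison. The whole
suite runs in well under a minute on one core.

## Known limitations

* The linear transmission form extrapolates poorly to deep vasculature;
  it is a first-order description over the imageable tree.
* The weighted-R² convention is package-defined; other tools may report a
  different weighted R² for the same fit.
* Vein exclusion by flow timing, dynamic search radii, and SNR- or
  partial-volume-aware quality terms are out of scope.
* Anatomical loci (C3/M1/A1/P1) are user-supplied indices; nothing is
  auto-detected.
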