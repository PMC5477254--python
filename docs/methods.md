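# Methods

## Problem setting

Fluorescent membrane labels in early embryos (the motivating system is the
*C. elegans* embryo imaged on a spinning-disk confocal) produce 3D time-lapse
recordings in which cell boundaries are thin bright shells over a dimmer
cytoplasm.  Segmenting every cell at every time point requires tuning image
processing parameters (filter widths, energy weights, thresholds), which is
the step this package automates: segmentation is run exhaustively over a
declared parameter grid, each candidate result is scored by an
image-consistency objective, candidates violating biological constraints are
discarded, and the feasible maximizer is kept.  The user tunes biological
constraints (easy to reason about) instead of image processing parameters.

## Stage 1 — embryonic region

Per recording, an initial 3D region is formed by summing the 4D stack over
time, keeping voxels above the mean of the summed stack, and retaining the
largest 26-connected component.  Per time point the membrane image is
Gaussian-smoothed, depth-adjusted (below), and segmented with a two-phase
piecewise-constant active contour evolved morphologically from the initial
region: per iteration the two phase means `c_in`, `c_out` are computed and
voxels in the one-voxel boundary band flip according to the sign of

    F = (I − c_in)² − (I − c_out)² + cb(t) · (1 − 2 · box_mean(u))

where `u` is the region indicator and the last term is a discrete
curvature/contraction force.  Restricting flips to the boundary band makes a
single iteration at most one morphological step and keeps the evolution a
contour motion.  After the final iteration holes are filled and the largest
component kept.  The evolution is deterministic.

The curve-length weight is brightness-adaptive,

    cb(t) = c · vars(t)^b,

with `vars(t)` the population variance of intensities inside the initial
region at time `t`.  Because a global intensity rescaling by `s` scales the
data term by `s²` and `cb` by `s^{2b}`, the whole evolution is invariant to
photobleaching-style dimming at `b = 1`; a fixed bias (`b = 0`)
over-contracts dim late frames.  This is tested directly: under strong
bleaching the adaptive run's min/max volume ratio dominates the fixed-bias
run's.

**Depth adjustment.**  Deeper focal planes are dimmer.  For each plane `z`
with in-contour mean `μ_z`, the plane is multiplied by `(μ̄ / μ_z)^strength`
where `μ̄` is the unweighted average of the per-plane means (chosen over the
voxel-weighted global mean so that two planes with means 10 and 20 equalize
to 15 irrespective of cross-section sizes; the correction is idempotent at
strength 1 either way).  `strength` ∈ [0, 1] is a grid axis: 0 is the
identity, 1 equalizes plane means.

**Selection.**  The objective is the mean membrane intensity under the
per-plane embryo edge (4-connected inner boundary on each focal plane;
vertical neighbours never contribute).  Constraints: (i) every seed-nucleus
voxel lies inside the mask at every time point — an equality constraint,
zero excluded voxels; (ii) min/max embryo volume over time ≥
`volume_ratio_min` (default 0.95), reflecting the near-constant volume of
early embryonic development.  The edge objective peaks when the contour
rides the outermost bright shell; a contour collapsed onto inner membranes
can score higher but is rejected by constraint (i).

## Stage 2 — cells and membranes

Seeds (nuclei labels) may come from the bundled DoG segmenter or be
supplied directly.  Per time point:

    S_dist = EDT(~seeds)           # distance to nearest seed voxel
    I_hyb  = I + α · S_dist        # distance-weighted hybrid image

The hybrid image is box-average filtered (window `avg_filter_size`) and
flooded by a marker-based watershed restricted to the stage-1 mask; there is
no background seed — restriction to the embryo mask replaces it, which
avoids basins escaping through dim surface membranes.  `α ≥ 0` penalizes
basin growth far from the seed: at `α = 0` a basin can flood through a
membrane gap deep into a neighbour; larger `α` restores an interface near
the equidistant surface.  Mislabelled voxels are empirically non-increasing
in `α` on the gap fixture, and the `α = 0` incursions (thousands of
contiguous voxels when the averaging filter is off) vanish at the selected
`α`.

**Watershed lines.**  The flood labels every mask voxel; single-voxel
membrane lines are then carved by marking, for each 6-adjacent pair of
differing labels, the voxel sitting higher on the flooded landscape
(deterministic tie-break by array order; seed voxels are never consumed).
This in-package line extraction replaces the line-producing mode of the
library watershed, which showed pathological runtime on distance-dominated
landscapes; the contract is unchanged — lines are one voxel thick (eroding
the membrane mask yields the empty set), and cells, membrane and exterior
partition the grid exactly.  The embryo's outer surface voxels are added to
the membrane mask, so the membrane set is "lines between cells plus the
embryo surface".  Stage 2's objective is the mean of the *original* image
(never the hybrid) over the membrane set; its only constraint — each
nucleus enclosed by its own cell — is enforced by construction and treated
as a segmentation failure if violated.

**Optimizer.**  Exhaustive lexicographic enumeration of each stage's grid;
ties broken by enumeration order; stage 2 searches only on stage 1's single
winner (sum, not product, of grid sizes).  Every candidate is logged with
its objective and per-constraint outcomes, feasible or not; if no candidate
is feasible the run aborts with a report naming the constraint that
eliminated each one.

## Synthetic recordings

The generator produces voxel-exact ground truth plus a degraded membrane
image.  Cells are nearest-centre (Voronoi) regions of sampled (or scripted)
centres, clipped to an ellipsoid; membrane voxels are those adjacent to a
label change (dilated for thicker membranes); seeds are balls of ⅓ the cell
inradius around centres, with labels stable over time.  Degradations, in
order: per-plane attenuation `depth_attenuation^(z_max − z)` (z = 0 is the
deepest plane), per-frame bleaching `bleach_rate^t`, additive Gaussian
noise, clipping at zero.  Membrane stretches whose local normal is within
30° of the z axis (computed from the two nearest centres, or the ellipsoid
gradient on the embryo surface) are deleted in contiguous Chebyshev-radius
patches until `gap_fraction` of them are gone — contiguous, because
independent voxel dropout leaves pinholes that an averaging filter closes,
which would not exercise watershed leakage.  Scripted divisions replace a
parent centre by two offset children with lineage-suffixed identities.

Default study conditions: a 64×64 plane × 24 slice grid over 5 time points,
ellipsoid semi-axes (10, 27, 29) voxels, 7 cells, membrane peak 120 /
cytoplasm 25 / background 4 counts, attenuation 0.97 per plane, bleaching
0.98 per frame, noise SD 2, 40% horizontal-membrane gap deletion, spacing
(0.5, 1.0, 1.0) μm at 15 s intervals.  The sizes keep a full grid search in
tens of seconds on one core while leaving cells large enough (~4,700 voxels)
for stable shape features.  What the phantom does *not* emulate: a PSF,
nuclear/cytoplasmic texture, cell motion, dim duplicate surface shells, or
mitotic shape change — so passing tests demonstrate the machinery
(selection, constraints, leakage control, feature accounting), not
performance on real microscopy.

## Shape features

Thirteen core features per cell and time point: Volume; PerimeterXY/YZ/ZX
(sum over planes of 4-connected cross-section boundary length, scaled by
in-plane spacing); CentroidX/Y/Z (physical units, image frame);
Width/Height/Depth (bounding-box extents along x/y/z); SurfaceArea;
Convexity (volume / voxelized convex-hull volume, hull on voxel centres);
Sphericity (`π^(1/3)(6V)^(2/3)/A`).  SurfaceArea is a marching-cubes mesh of
the mask padded and Gaussian-smoothed at σ = 0.7 voxel: meshing the raw
staircase overestimates smooth surfaces by 6–10%, while the smoothed mesh is
accurate to ~1% on a digitized ball of radius ≥ 12; small flat-faced
polyhedra are conversely underestimated — an accepted bias, since cells are
smooth.  A documented extended set (equivalent diameter, bounding-box
volume, extent, principal-axis lengths, elongation, flatness, compactness,
surface-to-volume ratio, convex surface area, max Feret diameter) is
available behind a flag.

## Evaluation

Cells are matched to a reference by greedy maximal voxel overlap (ties by
Jaccard, then smaller labels), so externally produced segmentations can be
evaluated too.  Deviation vs truth: per matched cell and feature,
`|truth − seg| / truth · 100`; per-feature means over cells; headline =
mean ± sample SD over the per-feature means (entry-level means are also
reported).  Zero-valued truth entries are excluded and counted.
Adjacent-time-point deviation applies the same formula to consecutive time
points of one segmentation per persistent identity; pairs spanning a
division contribute nothing.  Per-voxel distance maps give, for every voxel
of a segmented cell, the Euclidean distance to the nearest voxel of its
*matched* truth cell (never a neighbour), localizing where a segmentation
deviates.

On the synthetic fixture the residual deviations of the selected
segmentation concentrate on lateral watershed fronts rather than on
horizontal surfaces: with symmetric seeds a marker watershed self-corrects
inside a membrane gap, and the stage-1 mask pins the large horizontal bare
surfaces.  The horizontal-vs-vertical asymmetry therefore appears in the
controlled discontinuous-membrane scenario (tested) rather than on the full
phantom.

## Numerical conventions

Axis order (t, z, y, x), 0-based, z = 0 the deepest plane.  Physical spacing
lives in the config, not in TIFF tags.  Population (not sample) variance in
`cb(t)`.  The seed distance transform uses voxel units by default; physical
spacing behind `physical_distance` (α then has units of intensity per μm).
All randomness flows from one integer seed; segmentation itself is
deterministic, and repeated runs are byte-identical.  Degenerate inputs
fail loudly: constant images (no initial region), vanished contours, empty
seed frames, zero embryo volumes, and zero-denominator deviation entries
are errors or logged exclusions, never silent.

## Known limitations

Stage 2 currently floods each time point independently (per-time 3D, not 4D)
— consistent with per-time seeds, but temporal smoothness of membranes is
not enforced.  The exhaustive search is the only optimizer; `evaluate` is a
pure function so a surrogate-based search could be added.  Feature
deviations on the desk-scale phantom run several percent higher than they
would at full microscope resolution because single-voxel membrane lines are
a larger fraction of small cells.
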