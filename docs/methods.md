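# Methods

## Model and assumptions

The segmenter assumes exactly two things about a nucleus: it can be
separated from its surroundings by *some* intensity threshold, and its
binary shape is characteristic of its cell-cycle phase. Everything else —
absolute brightness, depth-dependent noise, temporal decay, nucleus size —
is deliberately not modelled, which is why the classifier features are
restricted to dimensionless shape descriptors of the binary mask and why
thresholds are chosen per object rather than per image.

Segmentation and classification are performed jointly. At each threshold
τ (ascending), 26-connected components are screened by a Boolean
pre-classifier and classified by a random forest; accepted candidates are
nodes of a forest-of-chains hierarchy in which a node's parent is the
accepted candidate at the highest lower threshold containing the majority
of its voxels. Because threshold masks are nested, containment is in
practice complete, and invalid intermediates (the whole embryo at low τ)
simply leave chains parentless. One object is reconstructed per leaf: its
branch (the chain up to, and excluding, the nearest split node) is
scanned from the high-threshold end for the longest run of consecutive
same-class nodes — ties go to the run nearer the high end — and within
that run the node with the highest posterior wins, ties to the higher
threshold. Excluding split ancestors from branches operationalises the
preference for high thresholds: two nuclei that merge at low τ can never
collectively resolve to their merged ancestor, which is why clean
separations are never merged.

### Pre-classifier

A candidate is valid iff (a) its calibrated volume lies inside the union
over phases of the volume intervals at t, and (b) each descriptor lies
inside the union over phases of the training ranges, independently per
descriptor ("union semantics": a candidate need not match a single phase
on every axis — the forest, not the screen, decides the phase).

Two range-calibration details matter in practice:

* **Window probing.** Training extraction returns the *lowest* threshold
  at which the clicked component's volume enters its phase interval, but
  segmentation re-encounters the same nucleus slightly eroded across its
  whole in-interval threshold window. Ranges computed from the extraction
  threshold alone systematically miss the eroded tail (flatness and
  compactness drift upward), so each training sample's descriptors are
  probed at up to 4 additional thresholds spread over its window and
  pooled into the ranges. The forest itself still trains on one feature
  vector per sample.
* **Margin.** Each per-phase range is widened by 0.25 of its span on both
  sides (configurable, stored in the model) because the min/max of a
  finite sample underestimates the population range. With the window
  probing in place this margin is a secondary guard; it matters most for
  phases trained with very few clicks.

### Inclusion model

Phases may be flagged `no_inclusion: [phases...]`. If a selected object
has an ancestor classified into a flagged phase and that ancestor
spatially contains (centroid-inside test) selected objects of the
forbidden phases, the ancestor — the whole nucleus — replaces them. When
a replacement fires, every selected object whose centroid lies inside the
ancestor is absorbed so the output stays voxel-disjoint. Centroid
containment was chosen over voxel-subset containment because fragments
at high thresholds are always nested subsets anyway; the centroid test is
cheaper and robust to one-voxel boundary effects.

## Descriptors

* **Surface.** S is the area of a marching-cubes iso-surface at level 0.5.
  Meshing the raw 0/1 mask overestimates a sphere's area by ~8%
  (stair-casing), which would cap compactness near 0.78; heavy smoothing
  shrinks convex surfaces instead. The mask is therefore Gaussian-smoothed
  with sigma = 0.65 in-plane voxels (scaled per axis to physical space)
  before meshing, which keeps digital balls across the radius range used
  here at compactness ≈ 1 and the r vs 2r scale drift within 2%. Objects
  thinner than the kernel fall back to the unsmoothed mask.
* **Ellipsoid fit.** Radii Rᵢ = √(5λᵢ) from the eigenvalues of the
  calibrated second-order central-moment matrix (exact for a solid
  uniform ellipsoid); degenerate objects get radii floored at half the
  smallest voxel spacing and are flagged.
* **Moment invariants.** Six invariants of the scale-normalised central
  moments up to order four: m1–m3 are the three invariants of the
  second-order matrix (trace, second elementary symmetric function,
  determinant); m4 and m5 are the squared norms of the third- and
  fourth-order moment tensors (with multinomial weights, making them
  rotation invariant); m6 is the double trace of the fourth-order tensor.
  All are translation invariant (central moments), scale invariant (the
  η normalisation) and rotation invariant/robust, verified by property
  tests (exact translation; < 5% under random rotation of digital
  ellipsoids ≥ 10 voxels in the smallest axis; < 2% between balls at r
  and 2r). m4 vanishes for centrally symmetric shapes, so tests compare
  it absolutely.
* **Feature set.** Sphericity is a deterministic monotone function of
  compactness, so the default classifier feature set is {compactness,
  elongation, flatness, ratio, m1..m6} — ten independent features; all
  eleven values are reported in the results tables.

Moments are computed over calibrated (µm) voxel-centre coordinates, so
anisotropic stacks yield physically meaningful shapes; a 2 µm ball
sampled at 0.25×0.25×0.5 µm scores elongation ≈ flatness ≈ 1.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| per-phase volume intervals | required | \[V_min, V_max\] µm³ at first and last frame; linearly interpolated between, clamped outside |
| `threshold.step` | 1 (8-bit); span/512 (16-bit) | threshold increment of the sweep |
| `training.box_vox` | 4·R_eq(max V_max)/dx, odd | side of the crop around each click |
| `training.step` | 1 | threshold increment during sample extraction |
| `filter.enabled` | false | adaptive 3D median pre-filter |
| `filter.max_radius_vox` | 12 | cap on the in-plane filter radius |
| n_trees | 200 | forest size |
| range_margin | 0.25 | pre-classifier range widening (fraction of span) |

The adaptive median filter derives its radius from the mean over phases
of the interval midpoints at t (a single scalar tracking nucleus size, as
the per-class derivation is under-determined), converts it to voxels via
R = (3V/4π)^(1/3), caps it at 12 in-plane voxels, and rescales the axial
radius by dx/dz so the ellipsoidal neighbourhood is physically isotropic.
Reflect padding avoids dark rims that would bias low thresholds. The
filter is optional and off in the synthetic experiments (the generator's
noise is mild and the sweep is intensity-adaptive anyway).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the algorithm relies
on: one thresholdable intensity level per nucleus, phase-specific shape
regimes, per-frame fluorescence decay (default 0.98), slow nucleus
shrinkage (radius ×0.99 per frame), signal-dependent noise (variance =
read² + gain·I, defaults 1.5² + 0.02·I on an 8-bit scale, optional depth
ramp), and cell division (daughters appear along the telophase axis,
spaced so a background gap separates them at their largest size).
Anaphase and telophase figures are rendered as two ground-truth instances
each, since each chromatin mass is a separately detectable object; their
separation axis stays in the image plane so the inter-mass gap is wide in
the finely sampled directions. Volume schedules emitted with a run
bracket the realised per-phase volumes by ±25%, following the shrink rate
between first and last frame.

It does **not** simulate a PSF, spectral crosstalk, chromatin texture
(beyond bright blobs inside prophase), nucleus movement, or segmentation-
relevant pathologies like overlapping nuclei in z. Passing tests on this
data therefore demonstrate the correctness and internal consistency of
the algorithm under its own assumptions — not performance on real
microscopy, where signal-to-noise, crowding and shape ambiguity are
harsher and detection scores should be expected below the clean-data
value of 1.

Default study conditions for the benchmark experiment
(`agita.benchmark.run_synthetic_benchmark`): 48×200×200 voxels at
0.25×0.25×0.5 µm, 10 frames, 22 mother cells (≈25–27 visible nuclei per
frame), 2 divisions, decay 0.98, low noise, simulation seed 42. The
experiment sweeps thresholds with step 3 — the method's accuracy is
insensitive to the step on clean data and a unit step triples the cost
for no benefit here.

## Numerical choices and tie-breaks

* Connectivity is 26-connected throughout; thresholding is `>= τ`.
* Threshold grids start at (image minimum + step), so adding a constant
  to the image shifts every selected threshold by that constant and
  leaves selected voxel sets unchanged (property-tested).
* Training extraction picks the component whose centroid is nearest the
  crop centre in calibrated coordinates, ties to the larger component.
* Run-length ties go to the high-threshold run; posterior ties within a
  run go to the higher threshold.
* A candidate whose voxel set is identical to its parent's reuses the
  parent's descriptors and classification (the component did not change).
* Output labels are assigned 1..N in centroid (z, y, x) order, making
  per-frame outputs byte-reproducible; frames are processed independently.
* Posterior = scikit-learn forest `predict_proba` (mean of per-tree leaf
  distributions; equal to the tree-vote fraction for fully grown trees).
* Degenerate evaluation inputs (no ground truth or no predictions) yield
  zero metrics with a warning instead of an exception.
* `evaluate.table_metrics` rounds recall and precision to table precision
  before forming F — the convention used when a printed F column derives
  from printed recall/precision columns; `detection_metrics` works at
  full precision.

## Known limitations

* The pre-classifier needs the training clicks to span each phase's shape
  variability; with very few samples per phase the (widened) ranges can
  still reject legitimate nuclei. Ten or more samples per phase is a
  practical lower bound.
* The hierarchy keeps one node per candidate per threshold; very deep
  16-bit sweeps at step 1 are memory- and time-hungry — increase the step
  or convert to 8-bit.
* Containment for the inclusion model is centroid-based; a pathological
  crescent-shaped ancestor could fail to contain a fragment's centroid.
* No temporal coupling: tracking, lineage reconstruction and
  classification smoothing across frames are out of scope.
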