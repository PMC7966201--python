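# Methods

## Problem and model

A point-based neuronavigation system relates two right-handed coordinate
frames: *image space* (the scan-derived virtual scene, in mm) and *physical
space* (the patient fixed on the operating table, in mm).  The relation is a
proper rigid motion `T(p) = R·p + t` with `R ∈ SO(3)`; scaling, shear and
reflection are excluded by construction — anatomy must never be mirrored, so
the determinant correction in the rigid fit is mandatory, not cosmetic.

Registration estimates `T` from N ≥ 3 paired anatomical landmarks
`(xᵢ, yᵢ)` by minimising `Σᵢ ‖R·xᵢ + t − yᵢ‖²`.  The solution is the
closed-form absolute-orientation estimate: centre both sets, take the SVD of
the 3×3 cross-covariance `H = Σ x̃ᵢ ỹᵢᵀ = U S Vᵀ`, set
`R = V diag(1, 1, det(VUᵀ)) Uᵀ` and `t = ȳ − R x̄`.  Fewer than three
landmarks, or a collinear constellation, leaves the pose underdetermined and
is rejected (`DegenerateConfigurationError`).  The collinearity gate is the
second-largest principal extent of the centred set exceeding 1e-6 mm:
coplanar sets are fine (they pin down the pose), a line is not.

When correspondence is unknown the ICP variant alternates nearest-neighbour
matching (ties to the lower index, for determinism) with the closed-form
fit.  The FRE is non-increasing across iterations; iteration stops when the
FRE change falls below `tol` (default 1e-6 mm, far below clinical relevance)
or after `max_iter` (default 100).  If the converged FRE is not below the
FRE at the initial transform, the result carries a `converged-to-start`
status and a warning rather than an exception.  In the emulated workflow the
operator records landmarks one at a time, so correspondence is in fact known
and the paired path is the default; ICP is kept for correspondence-free use.

### Error metrics

* **FLE** (fiducial localization error): the error in locating each landmark
  in either space; the driver of everything downstream.
* **FRE** (fiducial registration error): root-mean-square residual
  `sqrt(mean ‖T(xᵢ) − yᵢ‖²)` after the fit — the metric navigation systems
  report automatically.
* **TRE** (target registration error): `‖T(x_target) − y_target‖` at a
  point *not* used in fitting — what actually matters at the surgical
  target.

For N fiducials with i.i.d. isotropic per-axis FLE of standard deviation σ
applied in one space, `E[FRE²] = (1 − 2/N)·E[FLE²]` with `E[FLE²] = 3σ²`.
The Monte-Carlo machinery reproduces this law, and also demonstrates that
per-trial FRE and TRE are essentially uncorrelated: a low FRE on a given
registration does not certify a low TRE.

## Tracking and the lock/relock chain

A tracked rigid body (`MarkerArray`) is ≥3 uniquely identifiable markers
plus a `tip_offset` in its local frame: the probe's offset is the pointer
tip; the reference array's defaults to its marker centroid.  Marker identity
is known, so a pose is a paired fit of local marker geometry onto the
observed world positions; its RMS is a tracking-quality diagnostic (default
warning threshold 2 mm — the pose is still returned, because optical
tracking degrades under poor conditions rather than halting).

Patient tracking is pure transform chaining.  Locking stores the scene in
the array's frame, `lock = array_pose⁻¹ ∘ scene_to_world`; after the bed
(patient + head clamp + array, one rigid body) moves by M, a fresh
observation gives `array_pose' = M ∘ array_pose` and relocking yields
`scene_to_world' = array_pose' ∘ lock = M ∘ scene_to_world`.  Registration
residuals are therefore *exactly* invariant under bed movement (to
floating-point roundoff, asserted at 1e-9 mm); with noisy marker
observations the scene displacement error grows continuously with the noise
and vanishes with it.

## Synthetic phantom

No clinical data accompany the system, so accuracy is studied on a synthetic
head phantom.  The landmark template holds nine plausible head-surface
positions (medial/lateral canthi, nasal bridge, philtrum, both antihelices,
inion) in a frame with origin mid-head, x right, y anterior, z superior.
The coordinates are invented fixture geometry, not anatomy — only their
geometric relations (spread ~190 mm, non-collinear, roughly bilaterally
symmetric) matter to the mathematics.  Case-like subsets of 9, 8 or 7
landmarks are selected by label.

A phantom realisation applies a ground-truth motion to the template and
perturbs the physical copy with i.i.d. isotropic Gaussian FLE (default
σ = 2.0 mm — a realistic figure for anatomical landmarks, which localize
far worse than adhesive fiducials; anisotropic or image-side noise is out of
scope).  Interior targets (a frontal-lesion-like point and a deep midline
point) are mapped by the noiseless truth and held out of every fit.

What the generator does **not** emulate: operator-dependent, spatially
correlated landmark error; camera projection and lighting effects; display
drift and spatial-mapping instability of the headset.  Passing tests
therefore validate the computational chain (fitting, error propagation,
frame bookkeeping), not the end-to-end accuracy of any physical device.

Randomness: one `SeedSequence` per study, one spawned substream per trial,
so reports are bit-reproducible for a given seed and trials are independent.

## Study sizes and numerical choices

Monte-Carlo sizes used by the test suite and the acceptance script — 5000
trials for the FRE–FLE law (3-standard-error band), 2000 for the FRE–TRE
correlation, 500–1000 random motions for exactness sweeps — were chosen so
each statistical check resolves its effect with a comfortable margin while
the whole suite runs in seconds.

* Transform validity: `RᵀR = I` and `det R = +1` to 1e-9, enforced at
  construction; homogeneous 4×4 JSON serialization round-trips exactly.
* Exactness assertions use 1e-9 mm; oracle agreement uses 1e-6 mm (the
  nonlinear oracle's own convergence floor).
* Landmark CSV uses `repr` floats and pandas' round-trip parser, so
  write→read is lossless; the `.fcsv` dialect follows the 3D Slicer Markups
  column layout with `#` headers, and coordinates are taken as-is (no
  RAS/LPS conversion).
* STL files carry no units; millimetres are assumed, loudly.
* Meshes are loaded without vertex merging or repair so an identity
  transform is bit-exact.

## Known limitations

* Isotropic FLE only; the anisotropic case (and hence anisotropic-weighted
  fitting) is not implemented.
* ICP uses plain nearest neighbours with no outlier trimming; it is meant
  for the near-aligned regime of this workflow, not global registration.
* No claim links a particular σ to the clinical mean FRE; the clinical
  figure depends on unreleased geometry and operator behaviour, and the
  package's accuracy statements are property-based.
* The reference-array accuracy is characterised only through simulation;
  there is no quantitative hardware benchmark to compare against.
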