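# Methods

`panonav` simulates view-based route navigation: an agent stores panoramic
views while walking a straight training route through a procedurally
generated semi-arid habitat, is displaced sideways, and must recover the
route direction by rotational image matching alone.  The package's purpose
is to measure how the eye's azimuthal field of view (FOV), its angular
resolution, and the division of the visual field into independently matched
subfields affect that recovery.

## The world model

Worlds are collections of opaque black triangles on a white sky — the
minimal visual statistics of a semi-arid ant habitat, where the
object/sky contrast edge is the dominant navigational signal.

* **Tussocks** are three-dimensional clumps about 1 m tall (height drawn
  uniformly from 0.7–1.3 m, footprint 0.6–1.2 × height, random yaw), built
  from one of three facet templates (two- and three-plane vertical fans and
  a six-facet cone).  They are scattered area-uniformly at 0.08 / m² over a
  45 m arena, i.e. a mean nearest-neighbour spacing near 2 m: sparse enough
  that sky dominates every view, dense enough that each panorama carries a
  tussock skyline.
* **Trees** are large distal silhouettes: flat ("billboard") coplanar
  triangle fans facing the arena centre, 8–30 m tall, placed on a ring
  50–80 m from the centre — strictly outside the tested region (which
  extends to 38.5 m from the centre), so their two-dimensional treatment is
  geometrically justified.  A dedicated test confirms a billboard and a
  thinly extruded 3-D copy render indistinguishably from the arena.
* **Route corridors.** Tussocks are excluded from a corridor (half-width
  2 m) around the eight radiating route lines.  A tussock sitting on the
  route itself blinds the stored views around it, and its apparent *size*
  change under displacement cannot be compensated by rotating the view, so
  uncleared routes make even 0.5 m displacements fail for reasons unrelated
  to eye design.  The corridor parameters are configuration fields
  (`exclusion_radius`, `exclusion_routes`, `exclusion_length`).

Worlds regenerate bit-identically from a single seed; each object consumes
its own spawned random stream, so reproducibility does not depend on
insertion order.

The arena layout, densities, object templates and sizes are free parameters
of the generator (the habitat they emulate constrains only their scale).
The defaults above were chosen so that the generated scenes show the
canonical qualitative behaviour of this class of models — near-perfect
recovery on and very near the route, monotone degradation with
displacement, and better long-range recovery in worlds containing distal
trees — which is the validation the study itself applies to its worlds.

## Rendering and the eye

Views are equirectangular panoramas covering 360° of azimuth × 75° of
elevation above the horizon: 1024 azimuthal pixels (0.3515625°/pixel) by
213 rows at base specification.  Pixel values are the fraction of the
pixel's solid angle showing sky, estimated by a deterministic stratified
4×4 supersampling grid per pixel (so grey levels are exact multiples of
1/16; values 0 = object, 1 = sky).  There is no lighting, haze or distance
attenuation: a pure silhouette model.  The default eye height is 0.02 m
(ant scale); because the view starts at the horizon, the ground itself is
never imaged and eye height only scales apparent object elevations.

Rendering culls by projecting each triangle to a conservative
azimuth/elevation bounding box (using the monotonicity of azimuth along
great-circle arcs, a per-edge elevation bulge bound, and an explicit
zenith-containment test) and ray-casting only inside the box
(Möller–Trumbore, compiled with numba).  The box is only a culling device:
the image equals a brute-force all-rays render exactly, which a test
verifies ray for ray.  Because the supersample grid rotates with the view,
rendering at a heading shifted by a whole number of pixels equals a
circular column shift of the original image, bit for bit.

An **eye model** is an even azimuthal pixel count `px` for a full panorama
(even because the model targets bilaterian, mirror-symmetric eyes; minimum
2) and a FOV symmetric about the forward direction.  The pipeline is always
render → subsample → trim:

* subsampling box-averages the base panorama to `px` columns (exact pixel
  blocks when `px` divides 1024, area-weighted otherwise) and to
  `max(1, round(75°/resolution))` rows via an area-weighted vertical box
  filter over the 75° window, preserving mean intensity exactly;
* trimming keeps the central `max(2, 2·round(px·fov/720))` columns.  The
  even rounding keeps the field symmetric about the forward column
  boundary; the floor of two pixels lets the full factorial (down to 2
  pixels per 360°) produce a view for every FOV.

## Heading recovery

For a stored view *I* (width *w*, height *h*) and the current full
panorama *J*, the rotational image difference function is the mean absolute
pixel difference at each candidate rotation θ:

    d(I, J, θ) = Σ |I − J(θ)| / (w·h),

with candidate rotations the `px` integer pixel shifts of the panorama and
the FOV window sliding with the rotation.  Per stored view, m(I,J) =
min_θ d and h(I,J) = argmin_θ d; the *perfect memory* rule evaluates every
stored view and adopts the heading of the globally lowest minimum.  Ties
prefer the smallest rotation magnitude (straight ahead), then the earliest
stored view.  Because recovery searches all rotations, the direction the
test panorama happens to be rendered facing cancels exactly (tested).

Two evaluation paths give identical numbers: a direct vectorised sweep, and
for large problems a spectral path built on the exact identity
|a−b| = a + b − 2·min(a,b) with min(a,b) split into binary×value
cross-correlations (FFT, accumulated over rows) plus an exact sparse
boundary-grey term (compiled kernel).  Both match an independent
brute-force loop to 10⁻¹² on a thousand randomised toy problems.

**Signal strength** summarises match confidence: the familiarity of the
most familiar direction (the lowest per-direction rIDF value over the whole
memory) against the median familiarity across all directions.  The package
reports `median/min` (≥ 1, larger = stronger; +inf on a perfect match) so
the measure rises as error falls; the literal `min/median` orientation is
available via `ratio="min_over_median"`.  Both orientations carry the same
information; only the monotone sense differs.

**Sector matching** splits the trimmed field (default 300° at 5°/pixel,
the optics of well-studied desert ants) into 1–6 contiguous equal
subfields: even counts meet at the forward direction, odd counts centre the
middle subfield on it — both are automatic consequences of equally dividing
a field symmetric about the front.  Each subfield runs its own
perfect-memory search against the same-index subfields of every stored
view, over the full circle of candidate rotations; the final heading is the
unweighted circular (unit-vector) mean of the per-subfield headings.  A
single sector reproduces whole-field matching record for record.

## Experiment protocol

* Training route: straight, 20 m, from the world centre; 200 stored views
  at 0.1 m spacing (half-open sampling — start included, 20 m endpoint
  excluded — the only scheme consistent with 200 views), each facing along
  the route.
* Test grid: transects parallel to the route at displacements
  0.5, 1, 2, 3, 5, 8, 13, 21, 34 m on both sides, with 17 positions at 1 m
  spacing centred on the route's own span (2–18 m along-route): 306
  locations per route, 2448 per world with 8 routes at 45° steps.
* Eye grids: FOV 36°–360° in 10 steps × resolution 2–1024 azimuthal pixels
  in 10 doublings.
* Ground truth is the route direction; directional error is the absolute
  wrapped difference (0–180°; 90° is chance, verified by Monte Carlo).
* Aggregation: group means with 95% confidence intervals (normal
  approximation mean ± 1.96·SEM by default, percentile bootstrap as an
  option; groups of one record carry an undefined-CI flag).

### Desk-scale reference study

`panonav.experiment.reference_study` runs a reduced version of the protocol
sized for minutes on one CPU: one world per vegetation type, two routes
(0° and 90°), five transect positions per side, displacement distances
{0.5, 2, 8, 21} m for the full-resolution distance sweep, a coarse eye grid
(px ∈ {8, 64, 512} × FOV ∈ {72°, 216°, 360°}) over full 17-position
transects at 8 m, and the 1–6 subfield comparison in the trees-only world
at {8, 21} m — the displacements where whole-field error sits between its
near-route ceiling and the chance floor, which is where subfield matching
can show an effect.  All conditions share one
render cache per world, so each pose is ray-cast once at base resolution
and every eye condition is derived from the cached image.  These problem
sizes preserve the protocol's structure while shrinking replication, so
conclusions from it are qualitative orderings, not effect-size estimates.

## Numerical choices and degenerate inputs

* Exact binary classification of pixels (sky = 1.0, object = 0.0) is
  preserved through resampling by snapping values within 10⁻¹² of the
  bounds, keeping the spectral path's sparse grey set small.
* rIDF values are clipped at zero against FFT round-off; on-route
  self-matches recover d = 0 to ≈10⁻¹³ and the exact heading.
* An empty world renders all-white (valid); a flat rIDF yields signal
  strength 1 and the tie-break heading (straight ahead).
* A route leaving the arena, mismatched eye geometries, fewer than two
  rIDF directions, and sector counts outside 1–6 (or not dividing the FOV
  width) raise errors.

## What the generator does and does not emulate

The synthetic habitat reproduces the *geometry* that drives view-based
navigation — sparse near clutter, distal landmarks, object/sky contrast —
but none of the photometric structure of real scenes: no texture, colour,
UV/green channels, shadows, clouds, canopy transparency or wind motion, and
the retina is uniform with no optics beyond box averaging.  Passing tests
therefore show that the *algorithmic* trade-offs (FOV vs resolution vs
subfields) behave as described for silhouette-like input; they do not show
that a particular ant's visual system experiences the same trade-off
magnitudes in its real habitat.

## Known limitations

* Worlds are bounded; at the largest displacements (≥ 21 m) most scene
  content falls on one side of the agent.  Records carry the displacement
  so analyses can exclude those distances.
* The perfect-memory search is O(stored views × rotations × pixels); the
  spectral path makes the full-resolution eye tractable but memory-hungry
  (~0.7 GB of spectra per route at 1024 pixels).
* Sector counts above 6 and non-divisible sector widths are unsupported by
  design.
* With very coarse eyes (2–8 pixels) the rotation lattice itself limits
  accuracy (e.g. 45° steps at 8 pixels); reported errors include that
  quantisation, as they should.
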