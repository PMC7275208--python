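# Methods

## Problem and model

Preoperative TAVI planning requires five 3D points in a CT volume: the
basal attachment (hinge) points of the three aortic-valve leaflet cusps
(LCC, NCC, RCC) and the left/right coronary ostia (LCO, RCO). The hinge
points define the aortic annular plane (AAP); the perpendicular
distances from that plane to the ostia — the coronary heights — flag
the risk of coronary obstruction by the implanted device.

The detection model is multi-scale heatmap regression. A detector is
trained (or, here, emulated) to label spheres of radius r around each
landmark; three detectors with r ∈ {3, 5, 7} mm are run on the same
normalised volume and their per-class probability outputs averaged and
renormalised per voxel. The radius diversity trades localisation
sharpness (small spheres) against robustness (large spheres); averaging
lets the sharp models dominate near the landmark while the coarse
models suppress spurious responses.

Landmark extraction is deliberately simple and deterministic:
threshold at 0.5, cluster with a 1.1 mm Euclidean distance threshold,
keep the largest cluster, take the unweighted centroid of its > 0.9
voxels. All constants live in `RunConfig`.

## Coordinate conventions

World coordinates are RAS+ millimetres (NIfTI). Voxel indices are
0-based; the origin is the world position of the *center* of voxel
(0,0,0), making `voxel_to_world` / `world_to_voxel` an exact affine
pair. Sheared affines are rejected at load time; all geometry code
assumes an orthonormal direction matrix (which also makes world
distances separable over axes in spacing-scaled voxel coordinates — a
fact the mask and surrogate renderers exploit).

## Preprocessing

* **Resampling** to 1.0 mm isotropic with an order-3 spline (mirror
  boundary). Output shape is `ceil(extent / spacing)`: ceiling rather
  than rounding so no anatomy is cropped. HU values are not rescaled.
* **ROI crop** of 128³ voxels centered on a supplied world point; the
  protocol centers on the (ground-truth) landmark centroid when truth
  is available, which is how validation runs operate. Out-of-volume
  voxels are filled with −1024 HU (air). For genuinely unseen data an
  explicit `--roi-center` must be given — the tool does not guess one.
* **Normalisation** clips HU to [−1024, 2048] and maps linearly to
  [0, 1]. A fixed window keeps contrast-enhanced blood (~300–500 HU)
  and calcium (~700–1500 HU) separable and is identical across
  patients.
* **Augmentation** (`random_similarity_transform`) applies a seeded
  uniform ±3 % scale and ±3° per-axis rotation about the volume
  center, composing rotations as R = Rz·Ry·Rx, identically to image
  (cubic interpolation) and landmarks (analytic matrix). It is provided
  for training workflows and tested for image/landmark consistency.

## Detector backends

`DetectorBackend` is the contract a trained model must satisfy:
per-class probabilities of the input shape, summing to 1 per voxel,
tagged with the sphere radius it emulates. `SurrogateBackend`
implements it analytically: per class, an unnormalised Gaussian score
exp(−d²/2σ²) with σ = r/2 centered at the true landmark plus one draw
of isotropic Gaussian jitter (default sd 0.5 mm, independent per class
and per radius model, seeded), against a constant background score
0.05. The 0.5 mm jitter plays the role of a converged detector's
residual localisation error; σ = r/2 keeps the > 0.5 probability region
comfortably inside each training sphere. The surrogate depends only on
world geometry, so sliding-window and whole-volume prediction agree
exactly — a property the tests assert — and whole-volume prediction is
the default route. Sliding-window inference (64³ windows, stride 32,
last window shifted to the border, uniform averaging of overlaps) is
implemented for backends that are genuinely window-limited.

A trainable CNN backend is out of scope; the published training
hyperparameters are recorded in `TRAINED_BACKEND_DEFAULTS` as the
reference configuration for anyone adding one behind the contract.

## Localization details

`cluster_voxels` computes connected components of the ≤ 1.1 mm
neighbour graph (cKDTree pair query + sparse connected components).
This is exactly the single-linkage dendrogram cut at 1.1 mm — two
points share a cluster iff linked by a chain of steps ≤ 1.1 mm — but
runs in O(n log n); tests assert equality with scipy's
`linkage(method="single")` and, on unit grids, with 6-connected
component labelling. Single linkage is the only linkage for which the
1.1 mm threshold has its intended face-adjacency meaning on a 1 mm
grid.

Tie-breaks are fixed so the procedure is enumeration-order invariant:
equal-size largest clusters are resolved by highest peak probability,
then by lexicographically smallest voxel index. If the winning cluster
has no voxel above 0.9, the whole-cluster centroid is returned with a
`fallback` diagnostic flag (the high-confidence subset is empty only
under heavy jitter or degraded maps). A class with no voxel above 0.5
is a hard failure reported per class — never a silent zero point.

## Annular plane and heights

The plane normal is the normalised cross product of two hinge-triangle
edges, its sign chosen so the midpoint of the two ostia lies on the
positive side; heights are then positive for normal anatomy by
construction. Heights are signed perpendicular point-to-plane
distances, invariant under rigid motion (tested to 1e−9 over random
rotations). Hinge triangles with area ≤ 1e−6 mm² are rejected as
degenerate. Reported heights are rounded to 0.1 mm only at the
reporting boundary (CSV/CLI), never internally.

## Phantom generator

The phantom emulates contrast-enhanced aortic-root CT, not anatomy in
detail: a tubular lumen (radius = annulus radius + 2 mm, widened by
2 mm over the 15 mm sinus segment above the plane) of N(350, 30) HU in
N(40, 10) HU soft tissue; hinge points exactly on a circle of radius
U(10, 14) mm (annulus diameter 20–28 mm) in a plane tilted up to 20°,
at 120°-spaced angles jittered by U(−10, 10)°; ostia at radius
0.5–0.75 of the annulus radius and exact perpendicular heights
U(10, 20) mm — bracketing reported clinical medians near 16–17 mm;
Poisson(3) calcific blobs (U(700, 1500) HU, radius 1–2.5 mm) near the
hinge points; additive N(0, 20 HU) noise; optional 1.5 mm Gaussian
motion-like blur along one axis. Default grid 160³ at 0.7 mm so
isotropic resampling is genuinely exercised (anisotropic spacings are
supported and tested). All draws come from one generator seeded by the
spec, in a fixed order, so phantoms are bit-reproducible.

Cohorts assign 40 % of cases motion blur and 40 % doubled noise
(independent seeded permutations, exact counts), mirroring the artefact
mix reported for clinical TAVI cohorts. `generate_cohort` writes
NIfTI + JSON + manifest CSV, or returns the identical phantoms in
memory (`out_dir=None`); both routes share one resolved-spec iterator
and are tested equal. Validation runs use the in-memory route.

What passing on phantoms does *not* show: robustness to real detector
failure modes (multi-modal heatmaps, anatomical confusers, coronary
anomalies), to metallic artefacts, or to imperfect ROI centering. The
phantom validates the measurement chain, not a trained detector.

## Validation and statistics

`run_validation` runs the full chain per case (per-case seeds derived
from the master seed drive both the phantom and the surrogate jitter)
and reports median (LQ–UQ) per class and pooled, using
linear-interpolation (inclusive) quartiles — the convention is stated
because SPSS versions differ. Shapiro–Wilk normality p-values accompany
each row. Paired comparisons use the two-sided Wilcoxon signed-rank
test (zeros dropped; exact distribution for n ≤ 25 without ties,
normal approximation with continuity correction otherwise; all-zero
differences report p = 1 by convention). Height agreement reports
Pearson r², bias, and Bland–Altman limits bias ± 1.96·sd (sample sd,
n−1). The significance threshold 0.05 is recorded in report output.

With the default conditions (100 cases, 0.5 mm jitter, default
phantom), the pooled median landmark error is ≈ 0.6 mm and no landmark
errs by more than 4 mm; the acceptance script recomputes both numbers
from scratch at every run.

## Problem sizes and numerical choices

Unit tests use 96³ / 0.8 mm phantoms and 32³ oracle grids; the
end-to-end validation uses the full 160³ / 0.7 mm default at n = 100.
Probability maps are renormalised after every fusion step
(tolerance 1e−6). Gaussian scores below e⁻⁶⁰ are flushed to zero —
numerically indistinguishable from zero next to the 0.05 background
score, and avoiding denormal-range exp evaluations. Cubic-spline
resampling of probability volumes clips overshoot back to [0, 1].

## Known limitations

* The surrogate's unimodal, near-isotropic bumps make localization
  easier than real CNN heatmaps; accuracy numbers on phantoms are
  ceilings for the chain, not estimates of clinical accuracy.
* ROI selection for unseen patients is the user's responsibility
  (explicit center or whole-volume sliding window).
* No DICOM-series ingestion, gantry-tilt correction, or multi-phase
  (4D) handling; NIfTI only.
* Annulus perimeter/area/diameter sizing is not computed — only the
  plane and the two coronary heights.
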