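# Methods

## Camera model and calibration

All three cameras (left RGB, right RGB, thermal) use the pinhole model with
the 5-coefficient radial–tangential distortion `(k1, k2, p1, p2, k3)`.
Conventions: camera frames are right-handed with +z forward, +x right,
+y down; pixel (0, 0) is the top-left corner with pixel centers on integer
coordinates; `T_a_from_b` maps b-frame coordinates into frame a, and all
extrinsics are stored relative to the left (reference) camera.

Planar calibration follows the classical homography scheme: a normalized
DLT homography per view, closed-form intrinsics from the absolute-conic
constraints over ≥ 3 views, per-view poses from the decomposed homographies,
then a joint damped least-squares refinement (Levenberg–Marquardt via
`scipy.optimize.least_squares`, `ftol = xtol = gtol = 1e-15`) of intrinsics,
distortion and all board poses. Skew is held at zero by default (square
pixels); distortion starts at zero. On noiseless synthetic views the refined
solution reaches reprojection RMS ~1e-13 px and recovers generator
intrinsics to machine precision; the exactness is limited only by the
optimizer tolerances, hence the 1e-6 px acceptance bound.

The calibration target is a 9 × 9 grid of isolated 8 × 8 cm squares at
16 cm pitch (81 squares, 324 corners), centered on a 1.5 × 1.5 m board.
Isolated dark squares on a bright backing suit a multi-material
(heat-absorbent on heat-reflective) target visible to both RGB and thermal
cameras; a classical checkerboard is not. The inter-square gap is not
derivable from the square count and board size alone, so the 16 cm pitch
(8 cm gaps) is a configurable default. Corners carry stable integer ids
(`square_index * 4 + corner_index`, squares row-major from the top left),
so correspondence across cameras and views never relies on ordering
heuristics.

Rig extrinsics average per-view relative transforms
`T_cam2 ∘ T_cam1⁻¹` — rotations by the quaternion mean
(`scipy Rotation.mean`), translations arithmetically — and report the
per-view spread. A caveat quantified by the Monte-Carlo tests: board-pose
rotation errors couple with the board distance into the relative
translation, so millimeter-level extrinsics require calibration views from
the near end (3–5 m) of the tower's 3–10 m working range; re-estimating
intrinsics from the same noisy corners adds a correlated depth-scale error
on top. With 0.5 px corner noise and 10 near-range views the recovered
baseline is within 5 mm.

Distortion inversion is fixed-point iteration (cap 50, tolerance 1e-12,
verified by forward mapping); it round-trips to < 1e-6 px for normalized
radii ≤ 0.7. Triangulation returns the midpoint of the common perpendicular
of the two viewing rays and rejects ray pairs within 1e-8 rad of parallel.
First-order stereo error propagation σ_z ≈ z²·σ_d/(f·b) with
σ_d = √2·σ_px matches the Monte-Carlo depth spread within a few percent at
10 m depth.

## Registration validation and thermal fusion

Registration quality uses the three-step field procedure: triangulate board
corners from the RGB pair, re-project into the thermal camera, compare with
the corners observed in the thermal image. Residuals are
observed − predicted, so a thermal image shifted down by 2 px reports
`bias_v = +2`. RMS and per-axis bias are reported separately because a
systematic bias is removable; subtracting the reported bias from the
observations never increases the RMS (tested property).

Temperature attachment projects each 3D point into the thermal raster and
samples it bilinearly (thermal fields are smooth); nearest-neighbor lookup
is available for exactness tests against point-splat rasters, where bilinear
interpolation would mix edge pixels. Points behind the camera, outside the
raster, or occluded (z-buffer: nearest point per integer pixel bin wins)
receive NaN and are excluded from statistics, with excluded counts reported.
Plot temperature is the arithmetic mean of raw raster pixels whose centers
fall inside an image-space bounding box — the plot-level statistic used in
the field — with a 3D-mask leaf-only mean (`leaf_mean_temperature`)
provided separately and clearly labeled.

## Canopy traits

Heights are perpendicular distances to a RANSAC-fitted ground plane
(inlier threshold 2 cm, 500 iterations, least-squares refinement on
inliers, normal forced upward), so tilted fields are handled; the fit
rejects support below 10%.

Plant height is defined as the distance from the ground to the collar of
the topmost leaf. The annotated mode takes a user-supplied collar point —
the reference protocol, since "collar" has no algorithmic definition on a
raw cloud. The automatic proxy estimates the stem axis as the vertical line
through the 2D centroid of the lowest 20% height band and returns the
height of the topmost point within 3 cm of that axis. It is validated only
against synthetic ground truth, where it recovers ≥ 95% of collar heights
within 1 cm on noiseless plots; its reliability on real clouds depends on
stem visibility in the lowest height band.

Segmentation labels soil by excess-green index ExG = 2G − R − B below a
color threshold (default 20 on the 0–255 scale — adequate for the
controlled synthetic colors; real imagery needs a user-set threshold), then
splits green points by height above ground: weeds below the threshold
(default 0.3 m, reflecting the distinctly lower weed height mode in row
crops), crop above. `height_threshold="auto"` uses the Otsu split of the
green-point height histogram, accepted only when the two modes separate by
more than one pooled standard deviation, falling back to 0.3 m otherwise.
Points of a crop plant that hang below the threshold (stem bases, low
tips) are deliberately filtered out, exactly as the height-aware
segmentation intends.

Gap-fraction LAI drops the z coordinate of crop points (orthographic
re-projection), bins them into a 1 cm occupancy grid over the plot ROI (the
row-spacing × row-length rectangle in field coordinates), takes
P₀ = background cells / total cells and returns LAI = −2 ln(P₀). The
coefficient 2 is fixed, not configurable: it is the inverse nadir
extinction coefficient of the spherical leaf-angle special case of the
Beer–Lambert law, the canonical form of this estimator. Leaf-sum LAI is
Σ Sᵢ / A with leaf surfaces supplied either as scalar single-sided areas or
as triangulated patches (summed triangle areas); meshing leaves from raw
points is out of scope — surfaces arrive pre-segmented from the generator
or the user. Growth rate is the OLS slope of plot height against days
after planting.

## Synthetic scenes and what they do (not) show

The generator emulates the study conditions: a 1.7 m baseline rig
(RGB 1920 × 1200 at fx = 1200 px, thermal 640 × 480 at fx = 600 px —
representative of 8 mm lenses on the respective sensors), board poses 3–10 m
from the rig with tilts to 45°, rows at 76/114/152 cm spacing, 10 plants
per sampled plot at 23 cm in-row spacing, collar heights N(1.0 m, 0.05²)
clipped to ≥ 0.5 m, 10 leaves per plant of 60 × 8 cm, and weed tufts below
0.3 m. These defaults give a leaf-sum LAI of ≈ 2.7, a realistic mid-season
maize canopy, with substantial leaf overlap.

Leaves are developable ribbon strips: an arc-length-parameterized
centerline with parabolic droop (z = a·r − β·r² in the radial plane,
initial elevation 0–15°, droop 0.5–1.5 m⁻¹ capped so tips stay above
~0.25 m), swept along a constant horizontal ruling. Because the ruling is
constant, the single-sided area is exactly arc length × width — the
analytic LAI ground truth — and the sampled mesh converges to it (within
1% at 24 segments, ~1e-4 at 240; the radial extent for a requested arc
length inverts the closed-form parabola arc length by Brent's method). The
shallow initial elevation also makes the collar the topmost near-axis
point, which the automatic height proxy requires; steeply upward-pointing
young leaves would bias it high.

Every generator output is bit-reproducible from (parameters, seed); each
call owns one `numpy.random.default_rng`, no global state. The generator
does not emulate photorealistic color variation, SfM reconstruction noise,
wind deformation, occlusion-dependent point density, or radiometric thermal
effects (emissivity, atmosphere). Passing tests therefore demonstrate the
correctness of the geometry, the estimators and their documented error
behaviour — not robustness to real reconstruction artifacts.

Thermal rendering is a z-buffer point splat (nearest surface temperature
per pixel, soil temperature as background, optional Gaussian sensor noise).
Sensor logs are affine responses to a shared irradiance profile; lux
photodiodes emit lux such that the standard 0.0185 lux→PPFD sunlight
conversion reproduces their configured PPFD relation (default slope 0.9,
intercept 2 against the quantum reference — the relation an agreement
analysis should recover).

## Environmental statistics

Agreement between two series pairs readings by nearest timestamp within a
tolerance (default 60 s; unmatched readings are dropped, never
interpolated, and counted). RMSE and bias are computed against the y = x
line and the OLS fit of a on b is reported alongside, since both framings
are standard. Constant series cannot support a correlation and are flagged
degenerate (r = NaN), except the exact self-comparison where r = 1 by
convention. Plot aggregation reports mean/sd/n per (row, plot, level) in
deterministic sorted order and conserves totals exactly.

## Numerical choices and scale

Acceptance-level runs use 10 board views × 324 corners per camera, 1000
triangulation Monte-Carlo draws, 3 plot scenes (one per row spacing, 10
plants each) for trait recovery, 100 seeded scenes for the underestimation
rate, and n = 500 sensor samples — sizes at which every stochastic check is
stable across seeds while the whole suite runs in well under a minute per
component. Occupancy cells default to 1 cm; point densities to 4000 m⁻²
for canopy and soil alike, as a uniform surface-sampling model. Files
serialize floats at full precision (`repr`) and CSVs are parsed with
pandas' round-trip float parser, so write/read cycles and repeated seeded
runs are byte-identical.

## Known limitations

* The automatic collar proxy assumes a visible, near-vertical stem and
  shallow top-leaf elevation; it is a proxy, not a collar detector.
* Gap-fraction LAI saturates (P₀ → 0 diverges) on closed canopies and is
  reported as an error rather than a clipped value.
* The thermal point-splat renderer leaves background-valued holes wherever
  point density is below pixel density; bilinear temperature lookup near
  leaf edges mixes in background accordingly (use nearest-neighbor lookup
  for sparse clouds).
* Extrinsic accuracy degrades with board distance (rotation–translation
  coupling); calibrate near the low end of the tower's range.
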