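# Methods

## Pipeline model

The package models a rigid two-sensor rig: a high-resolution camera
producing a 5-channel reflectance stack (R, G, B, 635 nm, 880 nm) and a
time-of-flight (TOF) camera producing amplitude, depth, confidence and
per-pixel xyz rasters at 176 × 144 px over a 69° × 56° field of view and a
0.1–5.0 m working range. Because the mount is rigid, one planar transform
X₂ = R·X₁ + T relates 2-D pixel coordinates in the TOF frame (F₁) to the
colour/classification frame (F₂) for the life of the rig.

### Sequential masked SVM classification

Four binary SVMs are applied in the fixed order fruit → leaf →
stem/branch → background. Stage k is trained one-vs-rest on the full
training set; at inference each stage only sees pixels no earlier stage
claimed, and pixels left unclaimed by all four stages default to
background, so the labelling is total and the stage masks are disjoint by
construction.

Training samples are region means: labelled regions of interest are drawn
by stratified random sampling (40 regions per class by default) and each
contributes one sample — its per-channel mean reflectance. At inference
the feature is the raw 5-channel value of the pixel, min–max normalised
per channel with parameters frozen at training time. Training on region
means while classifying raw pixels is the simplest consistent reading of
the field protocol; region means denoise the training set while inference
must stay per-pixel. The kernel is RBF with C = 10, gamma = "scale" and
balanced class weights (each one-vs-rest problem is 1:3 imbalanced); no
kernel or regulariser is prescribed by the protocol, and these defaults
are not tuned per scene. No morphological post-processing is applied to
the classification map.

### RANSAC registration

The transform is estimated from N control-point matches contaminated by
outliers. Each iteration fits a minimal sample (2 pairs for
rigid/similarity, 3 for affine), scores the hypothesis by the inlier
fitness f₀ = Σᵢ 1[‖R·X₁ᵢ + T − X₂ᵢ‖ < ε] — the inequality is strict —
and the largest f₀ wins, ties broken by smaller mean inlier residual.
The winner is then re-fitted by least squares on its consensus set
(Umeyama for similarity, Kabsch for rigid, linear least squares for
affine); pass `refit=False` for the literal best-hypothesis transform.

The default model is **similarity** (rotation + uniform scale +
translation): mapping a 176 × 144 frame onto 2448 × 2050 requires scale
(~14×), so a pure rotation+translation cannot be meant literally. Rigid
and affine remain selectable. Defaults ε = 2.0 target-frame pixels and
max_iter = 1000 are package choices.

Warping uses inverse mapping with nearest-neighbour sampling for depth,
confidence and xyz — interpolating range values across fruit/background
borders would fabricate distances precisely where TOF multi-path already
corrupts them — with bilinear optionally available for amplitude. Target
pixels whose pre-image falls outside the TOF grid are no-data (NaN).

### Detection and localisation

Fruit candidates are connected components (8-connectivity by default) of
fruit-labelled pixels with area within configurable bounds (default
minimum 0.02% of the frame, no maximum, optional solidity bound). The
"requisites" a candidate must satisfy are not prescribed anywhere, so they
are configuration, not constants. Each candidate's position is the
registered xyz at its nearest-integer centroid pixel, matching the
single-point ("centre of the visible outer surface") ground-truth
convention; a no-data centroid falls back to the median xyz over the
blob's covered pixels, and a fully uncovered blob is marked invalid.

### Evaluation

Pixel metrics are fruit-vs-rest against a binary fruit mask: TP rate over
fruit-truth pixels, FP rate over non-fruit-truth pixels, precision
computed from the two rates as 100·TP/(TP+FP), and error rate = (missed
fruit + false fruit) / all pixels. The FP numerator is read as
non-fruit-truth pixels predicted fruit; this is the standard fruit-class
FP and the only reading under which the precision identity reproduces all
ten bundled per-scene precision cells. Scene aggregation is the
arithmetic mean of each rate; display rounding is 1 decimal for rates
≥ 10 and 2 below, matching the reference tables, with full precision kept
internally.

Manual ground-truth positions are measured as X/Y offsets (mm) from a
reference fruit's centre with Z already referenced to the TOF frontal
plane, so the coordinate transform is a pure planar shift: x = anchor_x ±
X/1000, y = anchor_y ± Y/1000, z = Z/1000 untouched. Axis signs default
to (+, +) and are configurable because the measurement-axis orientation
convention is not fixed. Detection–truth matching must be supplied
explicitly; `match_detections_to_truth` provides greedy nearest-neighbour
matching (5 cm gate) for synthetic runs.

## Synthetic scene generator

The generator emulates the field acquisition: a background foliage plane
at 1.0 m; stems as tilted bars slightly behind it (+3 cm); leaves as
random ellipses 2–12 cm in front; fruits as ellipses (eccentricity 0.75–1,
random orientation) with a spherical-cap depth protrusion of 4.5 cm toward
the camera — magnitudes consistent with the bundled ground-truth distances
(0.57–1.08 m). Reflectance is the class signature mean plus per-channel
Gaussian noise (default sd 0.02), clipped to [0, 1]. Default signatures
put fruit high in R/635 nm, leaves high in G/880 nm (chlorophyll red
absorption vs. NIR mesophyll reflection), stems dull, background dark; no
quantitative reflectance values exist for these classes at 635/880 nm, so
the defaults are plausibility-driven and live in configuration.

The TOF frame is produced by mapping each TOF pixel centre through the
true transform, sampling the high-resolution depth raster
nearest-neighbour, then adding Gaussian depth noise (default sd 1 cm,
typical of continuous-wave TOF at ~1 m), optional salt-type flying pixels
(default rate 0), and clipping to the working range with the clip count
reported. Confidence decays exponentially with the injected depth error,
so it is informative by construction. xyz rasters come from the depth via
a pinhole model with the 69° × 56° field of view; the real rig's projection
math is not public, so the pinhole is a package choice.

Two placement choices matter. Fruits are rejection-sampled to avoid
mutual overlap (the detector is connected-component based, so the default
scene keeps instances separable; overlap is still permitted after 200
failed attempts). Fruits are also kept inside the mapped TOF footprint by
default (`fruits_within_tof`): the field protocol ground-truths fruits
both sensors can see, and a fruit straddling the footprint edge is
localised through the median fallback, which on a spherical cap is
systematically biased toward the rim. Occlusion is modelled by drawing a
configured fraction of the leaves (default 25%) after the fruits.

What the generator does **not** emulate: texture and within-class spectral
variability (real leaves are not i.i.d. Gaussian around one spectrum),
specular highlights and shadows (named drivers of the lower vineyard
rates in the reference tables), multi-path range errors at object
borders, wind motion, and lens distortion. Passing tests therefore show
the pipeline's machinery is correct under its stated noise model, not
that field accuracy would match; the bundled reference tables are the
field baseline, and the synthetic rates (TP ≈ 100% at default noise) are
expected to exceed them.

## Problem sizes and numerical choices

Tests and the acceptance script run scenes at 410 × 512 (the full-frame
geometry scaled by ~4.8 with plant geometry scaled alike; the TOF grid,
depths and spectra are unchanged), 10–25 fruits per scene. The
localisation study pools ≥ 200 fruits across seeded scenes with occlusion
disabled and 1 cm depth noise: it verifies depth-noise propagation into
|e_z| against the half-normal mean √(2/π)·σ ≈ 0.80 cm, and occluded
fruits would shift blob centroids onto the steep rim of the depth profile
and measure centroid bias instead. Residual geometric bias from
cross-resolution sampling (a TOF pixel spans ~2.6 map pixels at this
scale) is ≈ 0.01 cm at the fruit apex, well inside the 3-standard-error
band used.

Degenerate inputs: RANSAC skips coincident (and, for affine, collinear)
minimal samples and raises only if every hypothesis was degenerate; an
empty match set scores f₀ = 0 with a warning; a training class whose
samples coincide with another's warns but trains; an empty ground-truth
fruit set yields NaN TP with a warning rather than an exception. Exact
float ties at the ε boundary are excluded (strict inequality), and the
scalar and vectorised residual paths use the same arithmetic expression so
the predicate is reproducible bit-for-bit.

Determinism: every stochastic step (scene rendering, region sampling,
stratified draws, RANSAC sampling, control-point noise) takes an explicit
seed and uses its own `numpy` Generator; fixed (config, seed) reproduces
scenes and pipeline outputs byte-identically, which is also what makes the
stage-resumable pipeline sound.
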