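# fruitsense

Detection and 3D localisation of fruits for harvesting robots, from a
multisensory rig that pairs a high-resolution colour/multispectral camera
with a low-resolution time-of-flight (TOF) range camera.

Harvesting robots need to know *which* pixels belong to fruit and *where*
each fruit sits in space. A colour camera alone struggles with both: fruit
and foliage colours overlap, and a single image carries no range. This
package implements the full sensing pipeline for the two-sensor answer:

1. **Pixel classification** — every pixel of a 5-channel reflectance stack
   (R, G, B plus narrow bands at 635 nm and 880 nm, where fruit and leaf
   spectra separate strongly) is labelled fruit / leaf / stem–branch /
   background by a *sequential masked one-vs-rest SVM chain*: the fruit SVM
   runs first and its positives are masked out, then leaves, then
   stems/branches, and anything left is background.
2. **Cross-sensor registration** — the TOF camera (176 × 144 px, 0.1–5 m
   range) and the colour camera (2448 × 2050 px) are rigidly mounted, so a
   single planar transform X₂ = R·X₁ + T maps TOF pixels into the
   classification map. It is estimated once by RANSAC over N control-point
   matches, scoring each hypothesis with the inlier fitness

       f₀(F₁, F₂, R, T) = Σᵢ 1[ ‖R·X₁ᵢ + T − X₂ᵢ‖ < ε ]

   and keeping the transform with the largest f₀.
3. **Detection and localisation** — connected components of fruit pixels
   that pass area requisites become candidates; each candidate's centroid
   indexes the registered per-pixel xyz rasters to give its position in
   metres in the TOF camera frame.
4. **Evaluation** — pixel-level TP rate, FP rate, precision
   (= 100·TP/(TP+FP)) and error rate against manual fruit masks, and
   per-axis mean absolute localisation errors |e_x|, |e_y|, |e_z| against
   manually measured fruit positions.

No public dataset exists for this rig, so the package ships a synthetic
scene generator (`fruitsense.scene_sim`) producing co-registered
multispectral frames, TOF rasters and complete ground truth — class label
maps, fruit instances, the true inter-sensor transform — so the whole
pipeline is testable end to end. Reference tables from a field trial of
this sensing approach (apple orchard and vineyard) are bundled in
`fruitsense.datasets` for the worked examples and regression tests.

## Worked example

```python
from fruitsense import (
    SceneConfig, generate_scene, sample_control_points,
    sample_regions_from_truth, extract_training_samples, train_chain,
    classify_pixels, ransac_register, apply_transform, extract_blobs,
    localize_fruits, detection_metrics, match_detections_to_truth,
    localization_errors,
)

# a 410x512 synthetic orchard scene with 10 fruits at default noise
cfg = SceneConfig.scaled(high_res=(410, 512), n_fruits=10)
frame, tof, truth = generate_scene(cfg, seed=42)

# 40 region-mean training samples per class, then the 4-stage SVM chain
regions = sample_regions_from_truth(truth.label_map.labels, seed=42)
train = extract_training_samples(frame, regions, per_class=40, seed=42)
chain = train_chain(train, seed=42)
cmap = classify_pixels(chain, frame)

# RANSAC registration from 100 control points with 30% outliers
matches = sample_control_points(truth, n=100, outlier_fraction=0.3,
                                noise_sd=0.5, seed=42)
result = ransac_register(matches, epsilon=2.0, max_iter=1000, seed=42)
registered = apply_transform(tof, result.transform, cmap.shape)

# fruit candidates, 3D positions, and the evaluation metrics
detections = localize_fruits(extract_blobs(cmap), registered)
report = detection_metrics(cmap, truth.label_map.class_mask("fruit"))
truth_pos = [fi.position for fi in truth.fruit_instances]
matching = match_detections_to_truth(detections, truth_pos)
errors = localization_errors(detections, truth_pos, matching)
```

Output:

```
pixel rates: TP 100.0%  FP 0.00%  precision 100.0%  error 0.00%
registration: 70/100 inliers, scale 2.620, rotation 1.51 deg
detections: 10 candidates, 10 matched to ground truth
mean |e| (cm): x 0.32  y 0.26  z 1.04
```

The classifier recovers the ground-truth labelling exactly at the default
(well-separated) spectral noise; RANSAC finds all 70 true inliers and the
similarity transform's scale/rotation; all 10 fruits are detected, and
with 1 cm simulated depth noise the z localisation error is of the order
of a centimetre while x/y (driven by TOF pixel discretisation) stay a few
millimetres.

The same flow is available from the shell:

```sh
fruitsense run --out runs/demo --seed 42      # full pipeline
fruitsense simulate --seed 1 --out scenes/s1  # individual stages:
fruitsense train --scene scenes/s1 --per-class 40 --seed 1 --out model.pkl
fruitsense classify --model model.pkl --scene scenes/s1 --out map.png
```

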