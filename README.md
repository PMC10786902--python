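# lidmetrics

Automated eyelid morphometry from standardized face photographs and
per-structure segmentation masks, for oculoplastic and orbital-disease
assessment (ptosis, thyroid eye disease, localized contour abnormalities).

Given binary masks of the **sclera**, **cornea**, **light reflex**, and a
**9.0 mm circular forehead marker**, the package computes, in millimetres:

- **MRD1 / MRD2** — margin–reflex distances: vertical distance from the
  corneal light reflex to the upper / lower eyelid margin;
- **upper / lower eyelid length** — curvilinear margin length between the
  medial and lateral canthi, using a *quadrant-corrected* digital
  perimeter (90° pixel corners become radius-½ quarter arcs and
  digitization staircases are reconstructed by run-midpoint chords, so a
  single pixel measures π and digitized circles converge to πd instead of
  the 27%-high raw pixel perimeter);
- **corneal boundary length**;
- a **360° radial contour profile** r(θ) of the palpebral fissure about
  the intercanthal line (0° toward the lateral canthus, 90° toward the
  upper lid), partitioned into k equal segments (k = 4 … 256; 24 segments
  = 15° intervals). Per-segment normative intervals mean ± 1.96·SD fitted
  on a normal cohort flag abnormal segments, and any subject with ≥ 1
  abnormal segment is flagged abnormal.

Segmentation itself is a pluggable backend contract: a ground-truth
oracle and a color-rule classifier ship for validation, and external mask
PNGs (e.g. from a semantic-segmentation network) plug in unchanged. A
synthetic scene generator provides photograph-like eye scenes with exact
analytic ground truth (parabolic lids through both canthi, configurable
MRDs, canthal tilt, raised-cosine contour bumps), so every stage is
validated against closed-form geometry. Method-comparison statistics
(ICC(2,1) with poor/fair/good/excellent bands, Bland–Altman mean
difference and 95% limits of agreement) round out the toolkit.

## Worked example

```python
import numpy as np
from lidmetrics.synthetic_scene import SceneParams, Bump, generate_scene
from lidmetrics.pipeline import process_scene

scene = generate_scene(SceneParams())          # normal eye, 0.1 mm/px
res = process_scene(scene, backend="oracle")
m = res.measurements
print(f"scale   {res.calibration.mm_per_px:.4f} mm/px")
print(f"MRD1    {m.mrd1_mm:.2f} mm   (truth {scene.truth.true_mrd1_mm:.2f})")
print(f"MRD2    {m.mrd2_mm:.2f} mm   (truth {scene.truth.true_mrd2_mm:.2f})")
print(f"upper   {m.upper_len_mm:.2f} mm  (truth {scene.truth.true_upper_len_mm:.2f})")
print(f"lower   {m.lower_len_mm:.2f} mm  (truth {scene.truth.true_lower_len_mm:.2f})")

bumped = generate_scene(SceneParams(bumps=(Bump(90.0, 20.0, 2.0),)))
delta = (process_scene(bumped, "oracle").profile.distances_mm[90]
         - res.profile.distances_mm[90])
print(f"profile bump at 90 deg: {delta:.2f} mm")
```

prints

```
scale   0.0999 mm/px
MRD1    3.10 mm   (truth 3.10)
MRD2    5.79 mm   (truth 5.80)
upper   28.78 mm  (truth 28.89)
lower   30.98 mm  (truth 30.93)
profile bump at 90 deg: 2.00 mm
```

— the marker recovers the true 0.1 mm/px scale to 0.1%, MRDs are exact to
a hundredth of a millimetre, quadrant-corrected lengths land within 0.4%
of the analytic arc lengths, and a planted 2 mm contour bump is recovered
at its degree.

The same flow from the shell:

```sh
lidmetrics synth --n-normal 100 --n-abnormal 20 --seed 7 --out scenes/
lidmetrics measure --scenes scenes/ --backend oracle --out results/
lidmetrics contour --scenes scenes/ --out results/
lidmetrics normative --profiles results/profiles.csv --k 24 --out model.json
lidmetrics verify --profiles results/profiles.csv --ks 4,8,16,24,32,64,128,256
lidmetrics agree --a auto.csv --b reference.csv
```

`lidmetrics run --config config.yaml` executes the whole pipeline
(fail-soft per subject) and writes a manifest with checksums of every
artifact.

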