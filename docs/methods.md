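# Methods

## Problem and measurement model

`lidmetrics` measures the periocular morphometry used in oculoplastic
assessment from standardized face photographs and per-structure binary
segmentation masks:

- **MRD1 / MRD2** — the vertical distances from the corneal light reflex
  (the flash reflection, taken as the centroid of the reflex mask) to the
  upper and lower eyelid margins;
- **upper / lower eyelid length** — the curvilinear length of each margin
  between the medial and lateral canthi;
- **corneal boundary length** — the perimeter of the visible corneal
  segment;
- a **360-degree radial contour profile** of the palpebral fissure about an
  intercanthal reference frame, from which localized contour abnormalities
  are detected against a normative cohort.

All measurement happens in original-image coordinates. Physical scale comes
from a circular forehead marker of known diameter (9.0 mm by default): the
marker mask's equivalent-circle diameter `2*sqrt(area/pi)` gives mm per
pixel. The equivalent-circle diameter is preferred over a caliper (Feret)
diameter because it is robust to one-pixel boundary noise.

The geometric substrate is the **crack boundary**: pixel `(r, c)` occupies
the unit square `[c, c+1) x [r, r+1)`, and region boundaries are traced on
the corner lattice between foreground and background pixels. The palpebral
fissure is the filled union of the sclera and cornea masks; its boundary is
cut at the two canthi — the horizontal endpoints of the sclera mask, ties
broken by the vertically median pixel of the extreme column — into the
upper margin (the sub-chain containing the topmost boundary vertex) and the
lower margin.

## Quadrant-corrected length

A digitized curve's crack boundary is an axis-aligned staircase whose raw
edge count systematically overestimates curved lengths: a digitized disk of
radius R has crack perimeter 8R rather than 2πR, and a 45° line costs 2 px
per √2 of true length. Pixel-perimeter eyelid lengths would therefore run
~25% high. The package's *staircase-aware quadrant correction* parses the
chain into maximal straight runs separated by 90° turns and corrects each
turn by its local context:

- a **hard corner** — an isolated turn, or one whose neighbouring turns
  rotate the same way (a genuine right angle of the underlying shape) —
  exchanges its two adjacent half-edges (total length 1) for a
  quarter-circle arc of radius 1/2 (length π/4);
- a **staircase turn** — one adjacent to an opposite-direction turn, the
  signature of a digitized oblique or gently curving edge — exchanges the
  two half-runs meeting at it (lengths a/2 and b/2) for their straight
  chord √(a²+b²)/2, which amounts to measuring the run-midpoint polygon of
  the staircase.

Both corrections only shorten, so the corrected length never exceeds the
crack length. Anchor values: a single pixel measures π (its inscribed
diameter-1 circle); an m×n rectangle measures 2(m+n) − 4 + π (rounded
corners); a long diagonal staircase converges to √2/2 per edge. Measured
accuracy on Gauss-digitized disks: +0.77% / +0.66% / +0.51% of πd at
R = 50/100/200 px, decreasing with radius; on an eyelid-shaped lens
(28 mm × 9 mm at 0.1 mm/px) the error is ≈ −0.25%.

A simpler rule that corrects corners only (fixed radius-½ arcs at every or
only convex turns) was evaluated and rejected: any corner-local correction
can remove at most 0.215 px per corner, and a digitized disk has ≈ 4.8R
corners against a needed 8R − 2πR ≈ 1.72R of shortening, leaving a ≥ +11%
systematic error — inconsistent with automated eyelid lengths running only
a few percent above manual curvilinear tracing. The run-midpoint chord term
is what restores convergence on oblique digitized curves.

MRD1/MRD2 are read off where the margin chains cross the reflex column
(linear interpolation along the chain). A reflex covered by the upper lid
(negative MRD1) is outside the method's measurement range and raises an
error rather than returning a signed value. Vertical means the image column
axis; the acquisition protocol assumes an upright head, and no head-pose
correction is applied.

## Intercanthal reference frame and contour profile

The reference frame's x-axis points from the medial toward the lateral
canthus; because the lateral canthus normally sits higher, this line is
inclined and the frame is effectively rotated so it becomes horizontal.
Degrees run 0° → lateral canthus, 90° → upper lid. The origin is, by
default, the foot of the perpendicular dropped from the reflex centre onto
the intercanthal line (`origin="reflex_foot"`); the intercanthal midpoint
is available as `origin="intercanthal_midpoint"`. The two conventions
coincide for a centred reflex and differ by a few degrees of profile phase
otherwise.

The profile casts 360 rays (1° steps) from the origin and records the
distance to the nearest intersection with the combined margin polyline, in
mm. For a boundary star-shaped about the origin (every fissure considered
here) the nearest intersection is unique.

**Quantization.** Rasterization localizes the margin to ~0.5 px normal to
the curve. A ray meeting the margin at incidence angle ψ therefore carries
~0.5/sin ψ px of radial uncertainty; rays near the canthi are the grazing,
least-certain samples (sin ψ ≈ 0.4 for a normal fissure). The
rotation-equivariance check admits (0.5 + 1/sin ψ) px × scale per degree,
with sin ψ computed from the analytic profile and floored at 0.05.

## Partitions and normative detection

The circle is divided into k equal segments (k ∈ {4, 8, 16, 24, 32, 64,
128, 256}; intervals 90.0°, 45.0°, 22.5°, 15.0°, 11.25°, 5.625°, 2.8125°,
1.40625°, conventionally reported to one decimal with halves away from
zero: 11.3, 5.6, 2.8, 1.4). k = 4 is the base construction: the
intercanthal line and its orthogonal through the reflex. A segment's value
is the arithmetic mean of its member degrees' distances (per-degree
flagging is k = 360).

A normative model fitted on N ≥ 2 labelled normals stores per-segment mean
and SD (n−1 denominator); a segment is abnormal when its value falls
outside mean ± z·SD with z = 1.959964 (two-sided 95% normal; an empirical
2.5–97.5 percentile interval is available via `method="percentile"`), and
any subject with ≥ 1 abnormal segment is an abnormal subject. Profiles are
compared in raw mm without per-subject size normalization — a deliberate
mirror of clinical practice, with the caveat that globally large or small
eyes inflate every segment's SD.

**Detection floor.** A raised-cosine bump of width w and amplitude A
contributes mass A·w/4 to the profile, i.e. displaces a fully containing
segment's mean by A·w/(4·interval) (≈ A/3 for w = 10° at k = 24). Flagging
requires that displacement to exceed ≈ 2 cohort SDs plus the subject's own
normal-range deviation, so reliable ("always flagged") detection needs a
~10 SD mean displacement. Sensitivity grows with k until the interval
shrinks to the bump width, which is why the sweep on bump-type
abnormalities is non-decreasing in k; specificity is computed empirically
(normals fitted and then flagged against their own model produce ~5%
abnormal segments per subject at z = 1.96, hence a non-trivial
subject-level false-positive rate at fine k — reporting it, rather than
defining it away as zero, is a deliberate choice).

## Synthetic scenes as ground-truth oracle

Real photographs and a trained segmentation network are out of scope; the
generator supplies photograph-like scenes whose geometry is analytic, so
every measured quantity has an exact reference:

- eyelid margins are parabolas through both canthi with apices `mrd1_mm`
  above and `mrd2_mm` below the reflex along the image vertical — smooth,
  eyelid-like, with closed-form vertical intersections and numerically
  exact arc length (20 001-point quadrature, relative error < 1e-8);
- canthal tilt elevates the lateral canthus; an optional rigid scene
  rotation tests rotation equivariance without changing intrinsic truth;
- abnormalities are raised-cosine radial bumps about the reference origin
  (degree-addressable, differentiable, localized);
- the cornea is a disc about the reflex centre clipped to the fissure; the
  sclera is the fissure minus that disc; the reflex a small concentric
  disc; the marker a separate disc, with an exact no-overlap guard;
- masks are exact rasterizations (pixel centre in shape); truth is always
  computed from the analytic curves, never from rasters;
- rendering uses flat per-structure colors plus optional Gaussian noise,
  sufficient for the rule-based color backend to segment by
  nearest-reference-color classification (IoU ≥ 0.999 per class on clean
  scenes).

Default scene: 1200 × 797 px at 0.1 mm/px, MRD1 3.1 mm, MRD2 5.8 mm,
fissure width 28 mm, canthal tilt 4°, corneal radius 5.75 mm, reflex radius
0.5 mm, 9.0 mm marker — a normal adult eye under a standardized portrait
protocol. Cohort variation defaults are Gaussian per-subject jitters (MRD1
± 0.8, MRD2 ± 1.1, width ± 1.5 mm, tilt ± 2°), truncated to keep the reflex
visible and the fissure open; these match a normal clinical population's
spread. Abnormal subjects receive one bump of width 10° and amplitude
3–6 mm (a severe localized deformation), centred uniformly on the lid arcs
away from the canthi.

What the generator does **not** emulate: eyelash/brow/skin texture,
specular gradients, partial reflex occlusion, head-pose and perspective
distortion, and inter-structure color ambiguity. Passing tests therefore
validate the measurement geometry and detection statistics, not
segmentation robustness on clinical photographs — the segmentation stage
is a pluggable contract (`oracle`, `color`, `external` mask files; a
trained-network adapter would slot in behind the same interface).

## Pipeline and numerical choices

- Photograph splitting: left/right halves `[0, W/2)`, `[W/2, W)`; marker
  crop `[W/4, 3W/4)`. An unmirrored photograph shows the subject's left eye
  in the right half, which fixes the medial/lateral labelling
  (configurable per eye side).
- Fixed-input backends receive a 512 × 512 zero-padded resize (content
  anchored top-left, padding right/bottom, bilinear for images); masks
  return to original coordinates by nearest-neighbour rescaling so they
  stay binary. Backends that can segment at native resolution (oracle,
  color, external files) skip the round trip.
- Mask cleanup: specks below max(20 px, 0.5% of foreground) are dropped
  for all classes; single-object classes (cornea, reflex, marker) keep
  only their largest 8-connected component. The sclera is exempt from the
  largest-component rule because it legitimately splits into nasal and
  temporal lobes whenever the cornea touches both lid margins (the normal
  configuration: corneal radius 5.75 mm > MRD1).
- Canthus snapping: a detected canthus pixel must lie within 2 px of the
  fissure boundary; degenerate one-pixel-tall fissures are rejected.
- Cohort batch processing is fail-soft: a subject whose reflex is missing
  (the paper's exclusion criterion) or whose geometry breaks a stage is
  recorded as failed and skipped.
- Determinism: a master seed derives per-scene child seeds; reruns are
  bit-identical for masks, truth, and measurements.

## Problem sizes

The validation suites use desk-scale cohorts chosen to estimate their
quantities stably: 50 scenes for parameter recovery (wide-open fissures,
MRD1 ≈ 7 mm / MRD2 ≈ 8 mm, so the full corneal disc is visible and 2πr is
its analytic boundary length), 100 normals + 20 abnormals for the
detection sweep, 60 homogeneous normals for the strong-bump flagging
check, and n = 300–2000 draws for the statistical reference behaviours.
`scripts/acceptance.py` re-runs the same computations at 30/100+20 scenes.

## Known limitations

- The corner rule's accuracy is quantization-limited: ~0.5–0.8% on discs
  at clinically relevant radii, comfortably inside the 2–3% tolerances
  used for length recovery, but not multigrid-exact.
- Profile samples near 0°/180° are grazing-incidence and carry a few-fold
  larger radial uncertainty than mid-lid samples.
- The normative model assumes per-segment Gaussian spread; the percentile
  option exists but needs larger cohorts.
- Negative MRD1 (reflex covered by the upper lid) is detected and refused,
  not measured.
- ICC(2,1) via `pingouin` requires non-degenerate variance; exact
  perfect agreement is special-cased to 1.
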