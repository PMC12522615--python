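# Methods

## Problem and scope

`periopano` automates the radiographic part of periodontitis assessment
under the AAP/EFP 2017 classification. Its input is not raw pixels but
polygon segmentations of a panoramic radiograph — one bone-level outline,
two cemento-enamel-junction (CEJ) curves, and up to 32 tooth contours keyed
by FDI code — plus a patient record (age, cigarettes/day, diabetes status
with HbA1c). In a clinical deployment those polygons would come from trained
segmentation networks; here a synthetic scene generator stands in for them
so that every downstream step can be tested against exact ground truth. The
package deliberately does not train or ship any neural model.

## Radiographic bone loss (RBL) geometry

For each tooth polygon a central axis is computed as the principal (major)
axis of the second central moments of the filled polygon, through its
centroid. The moments are evaluated exactly with Green's-theorem shoelace
sums, so the axis is rotation-equivariant and free of rasterization error.
The two intersections of the axis line with the polygon boundary are the
axis endpoints; jaw orientation picks the apex (maxillary teeth, FDI
quadrants 1–2: apex is the smaller-y endpoint; mandibular, quadrants 3–4:
larger y, with image y increasing downward). Shapes whose moment eigenvalue
ratio is below 1.05 are rejected as axis-ambiguous rather than silently
measured.

Along the axis, parameterized t = 0 at the crown endpoint and t = 1 at the
apex:

- the **CEJ point** is the most coronal (smallest-t) intersection with the
  jaw's CEJ contour, treating the contour as a thin closed band entered from
  the crown side;
- the **alveolar-crest point** is the most coronal bone-contour intersection
  at or apical to the CEJ (the crest is by definition the most coronal bone
  along the root);
- **Distance 1** = CEJ → crest, **Distance 2** = CEJ → apex endpoint, and
  RBL(%) = 100 · D1 / D2, clamped to [0, 100].

Pathological geometry degrades gracefully: bone coronal to the CEJ clamps
D1 to 0, bone apical to the apex clamps RBL to 100, and both attach a note
to the measurement; a missing CEJ or bone intersection marks the tooth
unmeasurable without failing the scene. Because RBL is a ratio of collinear
pixel distances, no millimeter calibration is needed and the quantity is
invariant to rigid motion and uniform scale (tested properties).

Numerical choices: edge–line intersections use a half-open vertex rule plus
deduplication by t (relative tolerance 1e−9) so tangential vertex touches
count once; axis-parameter comparisons use the same tolerance; unit vectors
are validated to 1e−9.

## Staging and grading rules

Per tooth, RBL < 15% → Stage I, 15–33% → Stage II, > 33% → Stage III_IV;
both boundary values belong to Stage II, following the printed ranges. The
most severe tooth sets the patient stage (ties to the lowest FDI code).
Stage III vs IV requires clinical criteria the radiograph cannot provide, so
the combined III_IV token is reported with a free-text clinician-override
slot instead of guessing.

The primary grade is the worst-site bone-loss% / age ratio: < 0.25 → A,
0.25–1.0 → B (boundaries inclusive), > 1.0 → C. Risk modifiers only ever
upgrade: any smoking below 10 cigarettes/day, or diabetes with
HbA1c < 7.0%, implies at least Grade B; smoking at ≥ 10/day, or diabetes
with HbA1c ≥ 7.0%, forces Grade C. Exactly 10 cigarettes/day triggers the
Grade C modifier (the tabulated ≥ 10 convention); the threshold is an
overridable function argument. HbA1c in a non-diabetic record is ignored.
Grading uses the maximum RBL over measurable teeth, including teeth clamped
at 100% for bone loss past the apex — the worst site is exactly what the
staging convention already trusts.

## Augmentation

Training augmentation emits five variants per image. Each variant first
receives additive Gaussian noise with intensity drawn uniformly from 0–5%
of the 8-bit dynamic range, then k transforms (k uniform on {0..4}, chosen
without replacement and applied in a fixed canonical order for
reproducibility) from: checkerboard alpha blending against a
contrast/brightness-perturbed copy, affine rotation (±10°), gamma contrast
(0.5–1.75), brightness shift (±30), salt-and-pepper (3% of pixels), and
motion blur (10×10 line kernel, angle ±45°). Rotation is the only transform
that moves annotations: polygons are mapped with the exact closed-form
rotation about the image center that also defines the image warp (inverse
bilinear resampling), then clipped to the frame. Pixel values are clipped to
[0, 255] after every photometric step.

Validation augmentation reuses the pipeline at reduced intensity. A literal
multiplication of the printed parameter ranges would make gamma diverge from
identity as the scale shrinks, so the scale instead multiplies each
parameter's deviation from its identity value (noise 0, angle 0, gamma 1,
shift 0, salt-pepper fraction 0) and blends the motion-blurred image by the
scale. Scale 1 reproduces the training distribution exactly; scale 0 yields
bit-identical copies of the input. The default validation scale is 0.5.

## Evaluation

Segmentation agreement is measured on pixel masks rasterized from the
polygons at native resolution with a pixel-center-inside (boundary
inclusive) rule. Seven metrics are computed from pooled confusion counts:
precision, recall, specificity, F1, accuracy, Dice and Jaccard; F1 equals
Dice algebraically in the binary-mask case and is reported from the same
expression. Bone and CEJ are single binary masks per scene (both CEJ bands
unioned); the 32-class tooth task is micro-averaged over per-FDI
one-vs-rest confusions, so a correctly outlined tooth with the wrong FDI
label is punished as both a false positive and a false negative.

Uncertainty comes from an image-level bootstrap: 1,000 resamples of the
image set with replacement, one pooled confusion matrix and metric set per
resample, percentile 2.5/97.5 bounds per metric. Percentile (not BCa)
intervals are used; a replicate with an empty denominator yields NaN and is
excluded from the interval with a warning rather than coerced to zero. The
stage-distribution balance check is a Pearson chi-square goodness-of-fit
against uniform (Σ(o−e)²/e, df = k−1) via `scipy.stats.chisquare`.

## Synthetic scene generator

The generator exists to give exact ground truth, not realism. Teeth are
tapered hexagons (crown wider than the root, flat apex edge) placed along
two parabolic arches in an 800×440 frame — maxillary crowns down, mandibular
crowns up. Defaults: 8 teeth per jaw, tooth width 26–34 px, crown 40–55 px,
root 90–120 px, individual tilt ±6°, arch curvature 3e−4 px⁻¹, loss
fractions uniform on [0.05, 0.6] unless a per-tooth mapping is given. The
shape is mirror-symmetric about its long axis, so the principal-moment axis
coincides with the construction axis; the CEJ band's coronal edge and the
bone polyline pass exactly through the per-tooth CEJ and crest points on
that axis. Measured RBL therefore recovers the configured fraction to
floating-point precision for any tilt in range — the 2-percentage-point
recovery tolerance in the tests is slack for future geometry changes, not a
property of the current construction.

The single bone contour is the inter-arch polygon whose upper boundary is
the maxillary bone-level polyline and lower boundary the mandibular one;
the most-coronal-hit selection rule makes measurement agnostic to whether
the polygon represents bone or the bone-free gap. Rendering is flat gray
levels (jawbone 170, inter-arch 70, teeth 225) plus Gaussian noise
(σ = 3), drawn after all geometry so fixed seeds give bit-identical images.
Patient records are sampled purely to exercise the grading path (age
uniform 25–75, smoker probability 0.3 with 1–20 cigarettes/day, diabetes
probability 0.15 with HbA1c uniform 5.5–9.5) and carry no epidemiological
claim.

Dataset generation can target a worst-tooth stage mix (e.g. 37/32/31%):
images are apportioned to stages by largest remainder, and each image's
worst loss fraction is drawn from a band kept clear of the 15%/33%
breakpoints (I: 0.04–0.14, II: 0.16–0.32, III_IV: 0.35–0.75) with all other
teeth below it. `corrupt_scene` produces controlled "predicted"
segmentations: coronal bone dilation (understates RBL — the understaging
failure mode), dropped CEJ bands (unmeasurable teeth), or vertex jitter.

What passing tests on this generator do **not** show: robustness to real
radiographic appearance (overlapping anatomy, restorations, exposure
variation), to imperfect network polygons beyond the scripted corruptions,
or to anatomically curved roots whose central axis is not straight.

## Problem sizes and limitations

The test suite and the reproduction script run at desk scale by design:
20-scene recovery suites, 1,000 bootstrap iterations, 1,000 random
confusion matrices, and 500-item split manifests. Known limitations: a
single mid-axis measurement per tooth (no mesial/distal sites), no
furcation/probing-depth/vertical-defect complexity factors, no direct
(longitudinal) grading evidence, and no DICOM ingestion — inputs are
LabelMe-style JSON with PNG/JPEG rasters.
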