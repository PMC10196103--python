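# Methods

This note describes the models and procedures implemented in `cranioqst`,
the choices made where the underlying clinical method left the design
open, and what the synthetic phantoms can and cannot demonstrate.

## Problem setting

Craniopharyngiomas (CPs) are benign but locally aggressive tumors of the
sellar/suprasellar region. Their site of origin — infrasellar/
subdiaphragmatic (**Q**), subarachnoidal along the pituitary stalk (**S**),
or pars tuberalis (**T**) — determines growth pattern, the preferred
surgical approach and prognosis, but is normally confirmed only
intraoperatively. The pipeline infers the type preoperatively from
sagittal contrast-enhanced T1 MRI in four stages: multi-tissue
segmentation, geometric feature extraction, and two parallel classifiers
(a points-based clinical scale and a learned fusion network).

## Coordinate conventions and label schema

All volumes are held in a canonical orientation: axis 0 is the sagittal
stack (left-right), axis 1 points posterior→anterior, axis 2
inferior→superior. Seven integer labels cover background, tumor,
pituitary (gland + stalk merged — the stalk is too thin to delineate
separately at this resolution), sphenoid sinus (air + bony wall), brain,
suprasellar cistern and lateral ventricles. The default grid is strongly
anisotropic — 6 mm slices, 0.45 mm in-plane — which is why all learning
is 2D per slice. NIfTI input is assumed already reoriented; the reader
validates labels and preserves header spacing (to float32 precision,
the NIfTI zoom width).

## Synthetic phantoms

No patient data ships with the package; every stage is exercised on
parametric phantoms. Anatomy is built from simple solids in physical mm
(field of view ≈ 60 × 72 × 79 mm): a sphenoid-sinus block whose
superior-anterior corner defines the tuberculum-sellae landmark, a large
brain ellipsoid, paired-ventricle and cistern ellipsoids, a pituitary
ellipsoid of requested volume, and a tumor built as a stack of per-level
ellipses whose half-extents follow a tent profile — the peak position
sets where the tumor is widest (inferior peak = "positive pyramid",
superior = inverted pyramid). Vertical and antero-posterior placement are
solved numerically so that requested fractions of tumor volume fall below
the tuberculum plane (intrasellar) and anterior to it. Overlapping solids
resolve by a fixed priority (tumor > pituitary > cistern > ventricle >
sinus > brain), which naturally produces the clinically expected
absences: a Q-type gland of 0.01 cm³ vanishes below voxel resolution, and
the cistern is effaced where the tumor grows through it. Intensities are
fixed per-class means plus i.i.d. Gaussian noise (default SD 0.05 against
class contrasts of 0.05–0.9).

Archetype parameter sets place each type firmly on its side of every
scale cutoff (e.g. Q: AP 3.0 cm, SI 4.2 cm, intrasellar fraction 0.28,
gland 0.01 cm³; S: AP 4.2 / SI 3.0 cm → aspect 1.4, widest level 0.25,
no dilatation; T: dilation factor 2.5, widest level 0.75, posterior
offset −20 mm, intrasellar fraction 0.03). Cohort generation jitters
extents by ±0.2 cm, fractions by a few hundredths and the gland volume by
±30% — bounded so jittered samples stay on the correct side of the
cutoffs up to voxelization noise. The default type mixture equals the
reference cohort prevalences (Q 21.8%, S 16.5%, T 61.7% of 133).

What the phantoms do **not** model: MRI physics (bias fields, partial
volume beyond voxelization, acquisition artifacts), anatomical
variability beyond parameter jitter, deformation of surrounding tissue,
and irregular/cystic tumor margins. Passing tests therefore demonstrate
the correctness and internal consistency of the pipeline — not clinical
performance on patients.

## Feature extraction

34 features per case, in a fixed documented order: per-tissue
bounding-box extents along the three axes (18; inclusive extent, i.e.
`(max−min+1)·spacing`, so a single voxel spans one edge), per-tissue
volumes (6; voxel count × voxel volume), tumor centroid offset from the
brain centroid normalized by brain extent (3), offset from the tuberculum
landmark normalized by tumor extent (3), the relative SI level of the
maximal transverse diameter (1), intrasellar and anterior tumor volumes
(2), and the AP/SI aspect ratio (1).

Open choices, resolved as follows:

* **Tuberculum surrogate** — the most superior sphenoid-sinus voxel
  (ties: most anterior, then lowest slice index). The pituitary fossa is
  the half-space strictly inferior to it and "anterior" strictly anterior
  to it; a single landmark-plane rule is reproducible and testable.
* **Transverse diameter** — the AP extent per SI level (sagittal
  assessment ties transverse growth to the AP direction); configurable
  conceptually but fixed here.
* **Diameters** — axis-aligned bounding boxes in 3D, not principal-axis
  or in-plane 2D measurements: simplest deterministic choice.
* **Position features** — the LR components are reported as magnitudes,
  since laterality carries no diagnostic meaning for midline sellar
  anatomy; this also makes all 34 features invariant to a left-right
  mirror of the slice stack.
* **Missing tissue** — absent structures report zero extents/volume plus
  an explicit per-entry missing flag rather than silent zeros: the
  absence of the pituitary is itself diagnostic (Q) and must remain
  distinguishable from a tiny-but-present gland.

## Clinical scale

Nine findings are binarized and award fixed points per type (each type's
total ranging 0–16); the diagnosis is the argmax with tie priority
T > S > Q. The five numeric cutoffs (AP < 3.5 cm, SI > 3.5 cm, fossa
volume < 2.1 cm³, anterior volume > 0.8 cm³, aspect > 1.1) are strict
inequalities as printed; boundary values score nothing. Three findings
are qualitative in origin and get operational defaults here, stated as
configurable calibration:

* *pituitary clearly seen* ⇔ gland volume ≥ 0.1 cm³ — reference cohorts
  separate Q glands (≈0.01 cm³) from S/T glands (≈0.45–0.49 cm³) by an
  order of magnitude, so the midpoint decade is safe;
* *ventricular dilatation* ⇔ ventricle/brain volume ratio ≥ 2%;
* *anterior/posterior* ⇔ normalized brain-relative AP offset outside a
  ±0.05 dead zone, so a centred tumor awards neither Q/S (anterior) nor
  T (posterior) points.

An indeterminate item contributes 0 to every type. The Q(3) and S(2)
anterior awards are read independently: one anterior tumor scores both
columns. A generic maximum-AUC cutoff finder (scanning midpoints of
sorted distinct values in both directions, ties to the lower threshold)
is provided for re-calibrating any cutoff on data.

## Segmentation network

A 2D encoder–decoder (U-Net family) with two distinctive elements:

* **Feature-swapping layer.** Encoder feature maps at different
  resolutions are exchanged before decoding: for each configured level
  pair (i, j), level i is resampled to level j's grid (strided
  subsampling downward, bilinear upsampling upward), projected by a 1×1
  convolution and added, and vice versa. All contributions are computed
  from the input pyramid, so the exchange is order-independent, and an
  empty pair list is exactly the identity (this is asserted bit-for-bit
  against the plain backbone). The merge operator (resample + 1×1
  projection + addition) preserves every level's shape and admits the
  identity test; the mechanism counteracts the loss of small-structure
  localization (pituitary, cistern) caused by downsampling.
* **Deep supervision.** Auxiliary 1×1 heads at intermediate decoder
  resolutions are trained against nearest-downsampled labels with
  weights halving per coarser level and normalized to sum 1.

Loss: equally weighted softmax cross-entropy and multi-class soft Dice
(the Dice term counters the volume imbalance between brain and the small
tissues). Optimizer Adam, lr 3·10⁻³, batch 8; slices are z-scored
individually. The desk-scale default (depth 3, width 8, 64×64 slices,
30 epochs on 200 slices) trains in ~5 minutes on one CPU; depth/width
scale up freely. Everything — layers, backprop, Adam — is implemented on
NumPy in `cranioqst.nn`, sized for exactly these configurations.

## Fusion classifier

Per case, the sagittal slice with the largest tumor area (ties: lowest
index) is stacked with the 7-channel one-hot segmentation of that slice
(background channel included — 8 input channels total; stacked channels
rather than separate branches, a documented choice). A small residual CNN
pools this to 32 "depth" features, concatenated with the 34 clinical
features (z-scored per training fold; missing entries imputed to the fold
mean, i.e. zero after standardization) into a 66-dimensional vector
classified by a two-layer discriminator with 3-class cross-entropy.
Training uses stratified 5-fold cross-validation; aggregated held-out
predictions are scored by one-vs-rest sensitivity/specificity/Youden/
accuracy plus overall accuracy. The image branch is desk-scale by
design — the component under test is the fusion, not backbone capacity —
and widths are configurable.

## Evaluation conventions

* Dice of two empty masks is 1.0 (configurable): a class legitimately
  absent from both reference and prediction — the cistern can be fully
  effaced — should not be penalized. Mean Dice averages labels 1–6;
  background is excluded.
* Cross-validation folds are stratified by type by default; fold sizes
  differ by at most one.
* All randomness (phantom sampling, weight init, batch order) flows from
  explicit integer seeds; repeated runs are bit-identical.

## Problem sizes used in the shipped checks

The acceptance checks run: the exhaustive 1,152-state scale enumeration;
600 jittered phantoms (200 per type, default 0.45 mm grid) for scale
recovery; 20 training + 5 held-out phantoms (200 slices, 64×64 coarse
grid) for segmentation; and a 150-phantom equal-mixture cohort for the
5-fold fusion CV. These sizes keep a full run in the tens of minutes on
a single CPU while leaving each result far from its threshold.

## Known limitations

* The phantom's geometric regularity makes both segmentation and
  classification far easier than on clinical data; the quantitative
  results here bound implementation correctness, not clinical accuracy.
* The tuberculum surrogate assumes a reasonably intact sinus roof; heavy
  erosion of the sella would displace the landmark and with it the
  intrasellar/anterior volume features.
* The scale's three operational cutoffs (0.1 cm³, 2%, ±0.05) are
  package calibration, not part of the published point table.
* 2D slice-wise segmentation ignores through-plane context by design
  (6 mm slices); no 3D convolutions are provided.
* The hypothalamus is not part of the label schema.
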