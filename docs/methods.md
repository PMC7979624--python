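# Methods

`bodycomp` implements a fully automated 3D body-composition pipeline for
abdominal CT: semantic segmentation of the volume into five body regions
with 3D U-Net variants, followed by Hounsfield-unit (HU) threshold
subclassification of adipose and muscular tissue inside those regions, and
per-slice volumetry with agreement statistics.  This note records the model,
its assumptions, the parameters that matter, and the design choices made
where the design was genuinely open.

## Problem and model

Body tissue composition (subcutaneous adipose tissue, SAT; visceral adipose
tissue, VAT; skeletal muscle) is a biomarker conventionally measured on a
single slice at the L3 vertebra.  The pipeline instead measures it across
the whole abdomen.  Tissue identity alone is not enough: adipose tissue at
−190…−30 HU looks the same everywhere, so whether a fat voxel is *visceral*
or *subcutaneous* is decided by which semantic region contains it.  The
region segmentation therefore carries the anatomical knowledge, and tissue
assignment is a logical conjunction:

* HU ∈ [−190, −30] ∧ region = abdominal cavity → VAT
* HU ∈ [−190, −30] ∧ region = subcutaneous tissue → SAT
* HU ∈ [−29, 150] ∧ region = muscle → muscle
* anything else → unassigned

Both threshold ranges are inclusive; the printed bounds −30/−29 are adjacent
integers, so the integer-HU partition is unambiguous.  Volumes are voxel
count × voxel volume, reported in mL per axial slice and in total, always at
the native CT resolution (volumetry must not inherit the 2× training
downscale).

Region codes: 0 background, 1 muscle, 2 bones, 3 subcutaneous tissue,
4 abdominal cavity, 5 thoracic cavity, 255 ignore.  The ignore code marks
unannotated voxels (the annotation protocol labels only every fifth axial
slice); 255 was chosen because it is far outside the class range and
survives uint8 storage.

## Network architectures

Two families share one skeleton: an encoder of `depth` (default 4) 2×2×2
max-pooling stages, a decoder of `depth` upsampling stages with skip
connections, and a biased 1×1×1 classification head with per-voxel softmax
over 6 classes.  Feature width at level *d* is `n_f · 2^d`, so with depth 4
and n_f ∈ {16, 32, 64} the bottleneck runs at 256/512/1024 features.  All
interior convolutions are bias-free and followed by instance normalization
and ReLU — batch size is a single volume crop, so batch statistics are
unavailable and instance norm is the appropriate choice.  Upsampling is
trilinear interpolation followed by a bias-free 1×1×1 channel projection;
transposed convolutions are avoided because of checkerboard artifacts.

**U-Net 3D**: each level block is two successive 3×3×3 conv + norm + ReLU
units; skips are identities; decoder blocks fuse `concat(upsampled, skip)`.

**Multi-resolution U-Net 3D**: each block chains three 3×3×3 convolutions
of widths `int(W/6), int(W/3), int(W/2)` (approximating receptive fields of
3, 5 and 7), concatenates their outputs and adds a 1×1×1-projected residual
shortcut; each skip is a *residual path* of `depth − level` conv/shortcut
units.  `W = α · n_f · 2^d` with width multiplier α.

### Parameter accounting and the choice of α

The published configurations come with printed trainable-parameter budgets
(5.34/21.36/85.43 M for U-Net 3D at n_f = 16/32/64; 5.82/21.24/85.10 M for
the multi-resolution variant).  These budgets pin down micro-structure that
prose leaves open.  An exhaustive structural search over block variants
showed:

* The U-Net budgets reproduce **exactly** (5,342,454 / 21,361,126 /
  85,427,142 parameters) only when the upsampling projection is 1×1×1 and
  the two 3×3×3 convolutions sit after the skip concatenation — the
  reconstruction adopted here.
* The multi-resolution budgets at n_f = 32 and 64 reproduce exactly
  (21,235,301 / 85,101,671) with the faithful block topology above and
  **α = 1.95** (any α in [1.9495, 1.951] gives identical integer widths);
  the conventional α = 1.67 misses both by ~1.5–2%.  α therefore defaults
  to 1.95, calibrated once against the published budgets.
* The printed 5.82 M at n_f = 16 is unreachable by *any* architecture whose
  channel counts scale with n_f: the printed 16→32 ratio is 3.65, but
  channel scaling forces a ratio ≥ 4 (integer truncation only pushes it
  higher).  Our reconstruction gives 5.28 M, consistent with a digit
  transposition in the printed table; the discrepancy is reported, not
  hidden, and the corresponding acceptance assertion is expected to fail.

Weight initialization is He-normal (fan-in) from a seeded generator;
activation is ReLU throughout.  `count_parameters` is cross-checked in the
tests against an independent per-layer analytic oracle (bias-free conv:
k³·c_in·c_out; biased conv adds c_out; instance norm: 2c).

### The numpy network engine

The networks are built on a self-contained reverse-mode autodiff engine
(`bodycomp.nn`): a dynamic tape over float32 numpy arrays with exactly the
primitives the architectures need (3D convolution via im2col + BLAS,
instance norm, ReLU, 2×2×2 max-pool, separable factor-2 trilinear
upsampling, concatenation, softmax).  Every adjoint is hand-derived and
verified against central finite differences in the test suite; the
upsampling adjoint additionally satisfies the inner-product identity
⟨Ax, g⟩ = ⟨x, Aᵀg⟩ to float32 precision.  The convolution input gradient is
computed as a correlation of the output gradient with the flipped kernels,
so both directions run through the same im2col/matmul path.

## Preprocessing

HU values are mapped through one or more windows `v ↦ clip((v−lo)/(hi−lo),
0, 1)`, stacked as channels, and recentred to [−1, 1].  The default is the
multi-window configuration — full 12-bit range [−1024, 3071], abdomen
window [−150, 250], liver window [−95, 155] — which dominated the ablation
over window choices; the four single-window ablation variants are
selectable by config alone (`ABLATION_WINDOW_CONFIGS`).  In-plane axes are
downscaled by factor 2 (block mean for intensities — deterministic and
antialiased; top-left nearest-neighbour for labels — class codes are never
interpolated, and an ignore voxel at the sampled position propagates).  The
z axis keeps its native 5 mm slice thickness.  Crops are taken at native
resolution and then downscaled, reconciling the crop size 32×256×256 with
the network input of 128×128 in-plane.

## Training

AdamW with β₁ = 0.9, β₂ = 0.999, eps = 1e-7, decoupled weight decay 1e-4;
the learning rate decays exponentially, `lr0 · 0.95^⌊epoch/50⌋`.  Batch
size is one crop.  Augmentation applies, in order: anisotropic in-plane
scaling with factors drawn independently for y and x from U(0.8, 1.2)
(linear interpolation for HU, nearest for labels), x-axis mirroring with
probability 0.5 (unstated in the source material; 0.5 is the conventional
choice), and random cropping.  Scaling precedes cropping, matching the
stated operation order.  Crops are unconstrained — ignore voxels contribute
no loss, so crops landing on unannotated slabs simply yield small gradient
steps.  An *epoch* is one random crop per training volume (the sampling
scheme was open; this keeps epochs comparable across dataset sizes).

The loss is `L_SV = 0.5·L_XCE + 0.5·L_Dice`, softmax cross-entropy plus a
generalized Sørensen Dice loss over the five foreground classes only
(excluding background weights the foreground up, the standard remedy for
class imbalance).  Ignore-labelled voxels are excluded from every sum and
receive exactly zero gradient.  The Dice smoothing constant is ε = 1e-5:
small enough not to bias scores on ≥10³-voxel regions, large enough to
stabilize empty classes.  A foreground class absent from both prediction
mass and truth contributes ε/ε = 1 (no penalty) — a direct consequence of
the stated formula, kept as-is.

Cross-validation is fivefold: a seeded shuffled partition into near-equal
folds (40 volumes → 32 train / 8 validation per run).  Model selection
monitors mean foreground Dice on full validation volumes through the
sliding-window inference path — not on crops — and keeps the best-scoring
weights; the kept checkpoint is by construction never worse than any logged
validation epoch.

## Inference

Full volumes are processed in overlapping windows of 32 axial slices with
75% overlap (stride 8); the final window is end-aligned so the last slice
is always covered, and volumes thinner than one window are padded with air.
Overlapping predictions are blended per voxel as Σw·p/Σw with a triangular
center-weighted profile w_z = 1 + min(z, 31−z) — the simplest monotone-to-
center choice; uniform and Gaussian profiles are available by config.
In-plane, inference runs at the training resolution (factor-2 downscale of
the full field of view) and class probabilities are upsampled back to the
native grid before the argmax, so volumetry happens on native-resolution
labels.  Whether the original system ran inference at native or downscaled
in-plane resolution is not decidable from its description; both are
supported, downscaled-with-upsampled-probabilities is the default.  The
five fold models form an ensemble by unweighted probability averaging;
argmax ties break toward the lowest class index.

## The phantom generator

Real training data for this problem is clinical and not redistributable, so
the package ships a synthetic phantom generator that emulates the *structure*
of the task: concentric axial anatomy (air background, elliptical body with
a subcutaneous fat ring, muscle wall, spine and rib bone sites, interior
cavity), a thoracic cavity dominated by two low-attenuation lung fields on
the cranial quarter of slices, and an abdominal cavity filled with
soft-tissue organs and visceral fat blobs, lined by a thin pre/retro-
peritoneal fat plane along the inside of the muscle wall.  That fat plane
matters: muscle (N(45, 15) HU) and visceral soft tissue (N(40, 20) HU)
overlap almost completely in attenuation, so without the interface fat a
segmenter cannot see the wall's inner boundary and regresses its thickness
toward the cohort mean — exactly as in real CT, where this boundary is
readable only because of fascial fat planes.  Per-voxel HU is sampled from
textbook tissue priors — fat N(−100, 20), muscle N(45, 15), bone
N(400, 150), soft tissue N(40, 20), lung N(−800, 50) — each clipped to its
legal HU range so threshold classification of a truth-labelled voxel
recovers the intended tissue deterministically.  Two deliberate impurities
make the conjunction rule non-trivial: ~5% connective-tissue speckle inside
the fat ring (not SAT) and ~3% fat streaks inside the muscle wall (assigned
to no tissue, since fat-range HU in the muscle region is unassigned by
design).  Bowel-gas pockets are available behind a config switch but
default off: at the phantom's coarse grid an air pocket is locally
indistinguishable from lung, and the sparse annotation provides too little
context to disambiguate them.

Each phantom draws its own body scale, ring-thickness multipliers and
visceral-fat load, emulating the wide inter-patient spread of habitus that
real per-slice agreement statistics pool over; the annotation grid keeps
its every-fifth-slice stride but starts at a random offset, as it would
when an annotator labels a scan of arbitrary extent.  With 20 slices and a
thoracic fraction of 0.25 every phantom contains exactly one annotated
thoracic slice, whose position varies across phantoms.

Ground truth is exact by construction: the generator enumerates, per slice,
the voxels in each tissue/region conjunction after HU synthesis, and this
enumeration is the oracle for the volumetry tests.

What the phantoms do **not** emulate: realistic organ shapes, partial-volume
mixing at tissue boundaries, contrast agent, beam-hardening or metal
artifacts, scanner noise texture, or anatomical variability beyond ellipse
taper and random blob placement.  Passing the phantom study therefore shows
that the implementation learns and quantifies the stated task end to end;
it does not certify clinical performance, and the published cohort scores
(mean Dice 0.9553, ICC ≥ 0.99) are not reproducible without that cohort.

## The scaled phantom study

The default `RunConfig` defines the study the tests and the acceptance
script run: multi-resolution U-Net with n_f = 4, depth 2 (17,369
parameters), 20×64×64 phantoms at (5.0, 6.25, 6.25) mm spacing, 10 training
volumes under fivefold cross-validation (8/2 per fold, mirroring the 32/8
protocol at quarter scale), 3 held-out test volumes segmented by the 5-fold
ensemble.  Crops are 8×64×64 and inference windows 8 slices at 75% overlap.
Unlike the full-scale configuration, the study runs at native in-plane
resolution (`downscale_factor=1`): a 64² phantom has no 512-grid excess to
downscale away, and the downscale/upsample cycle would erode the thin
tissue rings whose volumes the study measures.  The optimizer uses
lr0 = 2e-3 for 100 epochs (validation every 20): the published 1e-4 belongs
to the full-scale models and remains the `OptimizerConfig` default, but a
17k-parameter network on concentric geometry converges an order of
magnitude faster; the whole fivefold study takes roughly 10–15 minutes on
one CPU core.  Volumetry agreement (ICC(2,1), Bland–Altman) is computed per
tissue over the annotated slices of the test phantoms, pooled across
volumes — the same pooling across subjects that cohort per-slice agreement
statistics use.

## Numerical and degenerate-input choices

* HU grids are int16 and clipped (idempotently) to the 12-bit range
  [−1024, 3071]; everything after windowing runs in float32.
* A DICOM series with varying in-plane spacing, mixed orientation, a
  non-monotone slice gap, or a non-CT modality is rejected with a hard
  error naming the offending file — silent resampling would corrupt
  volumetry.
* ICC defaults to ICC(2,1) (two-way random effects, absolute agreement,
  single measurement): method-vs-truth agreement must penalize bias.  The
  form is configurable; computation is delegated to `pingouin`, with a
  hand-ANOVA oracle in the tests.  ICC on two constant identical series is
  undefined and raises.
* Hard Dice between label maps is 2|P∩T|/(|P|+|T|) over annotated voxels,
  defined as 1.0 when both masks are empty.  Reported averages weight
  volumes equally (macro-average).
* An all-ignore crop yields cross-entropy 0 with a warning and a Dice term
  of 0 (every class ratio is ε/ε); training simply takes no gradient step.
* Ties in the argmax resolve to the lowest class index, so a fully uniform
  probability field decodes as background.

## Known limitations

* VAT includes fat inside organs (no organ masking); artifact detection and
  thin-slice (<5 mm) support are out of scope.
* The engine is CPU-bound numpy; full-scale configurations (n_f ≥ 16 at
  512² in-plane) are buildable and countable but not practically trainable
  with it.
* DICOM support covers axial CT series with per-file rescale tags; PDF/PACS
  report export is intentionally excluded (CSV/JSON/PNG instead).
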