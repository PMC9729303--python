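# Methods

This note documents the models, the synthetic data, the numerical choices
and the known limitations of `capstrack`.

## Problem setting and conventions

The tracker observes grayscale B-mode frames of a magnetic sampling capsule
(8 mm diameter × 14.5 mm length) inside layered GI-wall tissue. Its outputs
are the mechanism state — closed, open (sampling cavity exposed) or
lost-in-FOV — and, for closed capsules, the in-plane 2D pose
(x, y, θ).

Coordinates: origin at the top-left pixel centre, x rightward along
columns, y downward along rows, 0-based. Orientation θ is the angle of the
capsule's long axis with respect to horizontal, measured counter-clockwise
*as displayed* (from +x toward the top of the screen) and folded into
[0, 180) — the capsule is symmetric end-to-end, so orientation is
180°-periodic. This convention is the one under which the standard
image-rotation matrix used for augmentation *adds* its angle to θ, so image
warps and label updates stay exactly consistent (the alternative,
measuring toward +y, would flip the sign of the rotation update).

Pixel poses convert to millimetres by multiplying with the probe scale
factor (mm/px). The scale factor is acquisition metadata: it is a required
input everywhere, never a constant.

## Label transforms

* `corners_to_pose`: centroid = mean of the four annotated corners; θ =
  angle of the line joining the midpoints of the two short edges. The long
  and short edge pairs must differ in mean length by a factor ≥ 1.05,
  otherwise the annotation is ambiguous and rejected (the capsule's
  aspect ratio is 14.5/8 ≈ 1.8, so real annotations pass easily).
* `resize_pose_update` for a w×h → S×S resize: x′ = S·x/w, y′ = S·y/h, and
  tan θ′ = (w/h)·tan θ, implemented by mapping the unit direction vector
  through the anisotropic scaling (atan2 branch handling; θ ∈ {0°, 90°}
  maps exactly to itself).
* Rotation by δ about the image centre uses the affine matrix
  [[α, β, (1−α)c_x − β c_y], [−β, α, β c_x + (1−α)c_y]] with α = c·cos δ,
  β = c·sin δ: θ′ = (θ + δ) mod 180 and the centroid/corners map through
  the same matrix. Shifts add (t_x, t_y) to the centroid and leave θ
  unchanged. Border cropping by margin M subtracts M from both centroid
  coordinates.
* Angular distances are computed 180°-periodically:
  d(a, b) = min(|a−b|, 180−|a−b|) ∈ [0, 90].

## Synthetic phantom generator

The generator is an *appearance* model of ex-vivo GI ultrasound, not a wave
simulation. A frame is built as:

1. **Tissue template**: ~5 horizontal layers with sinusoidally perturbed
   boundaries, alternating anechoic (0.12) and echogenic (0.45) reflectivity
   with ±20 % per-layer variation — the alternating bright/dark banding of
   the GI wall.
2. **Capsule echo**: a stadium (rectangle with semicircular caps) of the
   capsule's physical size divided by the scale factor, at reflectivity
   sampled from `capsule_contrast` (default 0.65–0.95; contrast varies
   frame to frame as it does with gain/TGC changes). Open state: the same
   stadium with a central band removed along the long axis (gap 10–40 % of
   the length — the cavity opening is not quantified anywhere, so the range
   is a design choice); the pose label of an open capsule is the
   centroid/orientation of the joint footprint and exists only for
   generator self-checks. Lost state: background only, or (with
   probability 0.5) a small irregular fragment, plus optional
   capsule-like distractor arcs so hard negatives for the state classifier
   exist.
3. **Shadow**: with probability 0.15 a dark vertical band (×0.35) emulating
   occlusion.
4. **Speckle**: multiplicative Rayleigh envelope (scale √(2/π), unit mean)
   smoothed by a small Gaussian PSF (σ 0.7 px) for spatial correlation,
   then log compression `log1p(5 I)/log1p(5)` to 8 bits.

Ground truth is exact: the binary capsule mask, the pose, and the
four-corner annotation of the oriented bounding rectangle. The generator's
self-check is that the image-moment pose of the mask (centroid from first
moments, orientation from the principal axis of the central second moments)
matches the stored label within 1 px / 2° — at 64 px frames the
discretisation of a 29-px capsule dominates this tolerance; at 224 px
frames soft (coverage-weighted) moments agree within ~0.3 px / 0.4°.

Determinism: the full dataset is a pure function of (config, seed); each
frame's randomness derives from `SeedSequence([seed, index])`.

Presets: `PhantomConfig()` renders 256×256 at 0.25 mm/px.
`PhantomConfig.tiny()` renders 64×64 at 0.5 mm/px (capsule ≈ 29×16 px) for
desk-scale runs; `tiny(easy=True)` additionally raises the capsule
reflectivity to 0.85–1.0, removes occlusions and damps the speckle
fluctuation to 60 % — the *easy high-contrast* condition used for
parameter-recovery runs, where a failure should indicate a pipeline defect
rather than an under-sized training set.

**What the phantom does not emulate**: trapezoidal wide-view geometry,
depth-dependent resolution and attenuation, refraction/reverberation
artefacts, air pockets, real anatomy, and the view-angle dependence of the
open cavity (the real protocol discards open frames where the cavity is not
visible; the generator has no notion of that). Passing tests on phantoms
therefore validates the *pipeline* — label algebra, training mechanics,
metric definitions — not clinical performance.

## Network

Backbone: pre-activation residual blocks, out = conv(relu(bn(…))) + input,
so the residual contract is exact — zeroing the inner transform makes a
non-projection block the identity, which the tests exploit by weight
surgery. Two variants:

* `tiny` — 1-channel input (64×64), stem 3×3 stride-2 conv, three
  stride-2 blocks with channels (16, 32, 64), ≈ 80 k parameters. This is
  the backbone used in all tests, trained from random (He) initialisation.
* `resnet50` — 3-channel input (grayscale replicated), 7×7 stride-2 stem
  plus four bottleneck stages (3, 4, 6, 3 units). Pretrained weights are an
  explicit opt-in from a local checkpoint path; nothing is downloaded, and
  no test exercises this variant's training.

Channel attention: hidden width max(1, C/r) with reduction r = 16 by
default (r is configurable; the tiny recipes keep 16), shared between the
average- and max-pooled paths, no biases by default (so zero weights give
the clean gate σ(0) = 0.5 everywhere). Note one subtlety: the hidden layer
is rectified, so an "identity-weight" MLP is *not* a pass-through for
negative pooled values — the closed-form test values account for the ReLU.
Insertion point: after the last block for pose tasks, after the penultimate
block for the state task (configurable).

Heads: GAP → dropout (0.5 default) → fully connected to 3 (state, softmax),
180 (orientation, softmax over integer-degree bins; continuous labels are
rounded to the nearest bin mod 180) or 2 (centroid, linear) outputs. The FC
acts directly on the pooled features; no intermediate width.

Inference is hierarchical: orientation and centroid run if and only if the
state model says *closed*; otherwise the result carries no pose.

The whole network stack (conv via im2col, batch norm, Adam, dropout,
backprop) is a compact float32 numpy implementation inside the package
(`capstrack.nn`), chosen for determinism and transparency at desk scale.
Frozen layers are a parameter-level contract: the optimizer skips
non-trainable parameters, and a frozen batch-norm layer uses (and never
updates) its running statistics.

## Training

Two stages: (1) backbone frozen, attention + head trained, LR 1e-4;
(2) backbone unfrozen except blocks 1..i (`ft_depth`, the stem belongs to
block 1), LR 1e-5. Batch size 32, Adam, dropout 0.5, 7:2:1
train/val/test split — these defaults are the full-scale reference values
(full-scale total epochs: 65 state / 102 centroid / 60 orientation).
Early stopping monitors the validation set with patience 10 and the
best-validation weights are restored per stage. The monitored quantity is
configurable (`loss` or a task metric — error rate, mean wrapped
orientation error, mean pixel error) because the reference procedure does
not specify it; the default is loss.

Centroid loss: L = (1/2N) Σ‖y − t‖² by default (the mean-squared-error
reading); a literal mode with the unsquared norm is selectable, since the
printed formula and its "MSE" label disagree. Cross-entropy clamps
probabilities at 1e-12 inside the log.

Splitting uses largest-remainder rounding, optional stratification by
state (used for the state dataset only), and a leakage guard that confines
all augmented variants of one base frame to a single split (on by
default).

Orientation targets may be softened by a circular Gaussian over the 180
bins (`label_smoothing_sigma`, default 0 = one-hot). Smoothing shares
evidence between neighbouring degree bins, which matters when training
from scratch on hundreds rather than tens of thousands of frames.

After centroid training the linear output head is recalibrated on the
validation split: squared-error training with limited capacity shrinks
coordinate predictions toward the workspace mean (regression to the
mean; the fitted correction slopes are ≈ 1.2), so a per-axis affine map
y ≈ a·ŷ + c is fitted by least squares on validation predictions and
folded exactly into the FC weights — the head stays linear and the
architecture is unchanged. On the desk-scale runs this cuts the mean
position error roughly from 3 px to 1.7 px.

### Desk-scale recipe (`TrainConfig.tiny_preset`)

The tiny backbone trains from random initialisation, so the transfer-
learning stage structure degenerates: stage 1 (2 epochs) only settles the
head, and stage 2 trains everything (`ft_depth` 0). Task specifics: state
12 epochs at LR 2e-3; centroid 30 at 1e-3 (batch 16); orientation 28 at 1e-3 with
σ = 4° label smoothing, dropout 0.3, weight decay 1e-4 (decoupled, weight
matrices only) and a wider final block (channels 16, 32, 96 — angular
discrimination needs more pooled features than the other tasks). Early
stopping monitors the validation task metric (patience 12–15).

Both pose models train on augmentation expansions of their base set
(the full 0.5–5° rotation ladder plus small-shift variants, 5-px crop) —
mirroring the reference pipeline, which always trains on the augmented
pose dataset. This matters for different reasons per task: the 180-way
orientation classifier otherwise overfits 600 base frames badly
(test-set mean error ≈ 30° instead of ≈ 3–6°), and the centroid
regressor needs the shift variants for position diversity — pooling
global averages makes position an implicitly encoded quantity, and with
one position per base frame the regressor plateaus near 6 px where the
augmented version reaches ≈ 2.8 px. (A thresholded intensity-moment
estimator localises these easy phantoms to ≈ 0.7 px, so the residual gap
is a capacity limit of the small GAP-bottlenecked network, not an
information limit of the images.)

Problem sizes for the recovery runs: 64×64 easy phantoms, ~600 base
training frames, 160 validation, 200 test per task; the full recovery of
all three models runs in minutes on one CPU core.

## Metrics

* Position error: mean Euclidean distance in mm (default). The literal
  radial form — mean |‖P_GT‖ − ‖P‖| of centroid ranges from the image
  origin — is co-reported; as a difference of norms it vanishes for
  distinct points at equal range and, by the reverse triangle inequality,
  never exceeds the Euclidean error.
* Orientation error: mean/median/population-std of the per-frame error,
  180°-wrapped by default (angle ambiguity near horizontal otherwise turns
  a 2° miss into 178°); the unwrapped |Δθ| is co-reported. Success rate =
  fraction of errors ≤ 10°.
* State: accuracy = correct detections / N = trace(confusion)/N; per-class
  one-vs-rest precision, recall, F1 (zero-division → 0 with a warning);
  3×3 confusion matrix.
* Tracker-level evaluation scores state metrics on all frames and pose
  metrics only on frames that are ground-truth closed *and* predicted
  closed (the hierarchical gate); closed frames excluded by mis-gating are
  counted and reported separately, since it is unspecified whether
  hold-out pose metrics should include them.

## Degenerate inputs and numerical choices

Empty metric inputs raise; a gate that passes no frames yields absent
(None) pose metrics, not NaN. Corner annotations with edge-ratio < 1.05 or
zero area raise. Image resampling is bilinear for intensities and
nearest/soft for masks; border fill is 0 and the crop margin (16 px at
224 scale, covering any single ≤5° rotation or ≤12 px shift) removes it.
Augmentation variants whose transformed capsule leaves the valid region
are rejected, counted and logged — never silently dropped. Batches of size
1 are skipped during training (batch norm needs two samples). Seeds:
every stage derives its seed from the global seed and the stage name via
`SeedSequence`; results are bit-reproducible given (config, seed).

## Limitations

* Phantom realism as above; no claim about ex-vivo or in-vivo accuracy is
  made or tested.
* The tiny recipe's accuracy targets (state ≥ 0.90, OE ≤ 10°, PE ≤ 3 px on
  easy phantoms) are deliberately loose parameter-recovery checks, about
  an order of magnitude above the full-scale reference errors.
* Orientation near the capsule's symmetry axis remains the hardest case;
  the wrapped error metric treats a 179°↔1° confusion as 2°, which is the
  physically meaningful reading for an end-to-end symmetric capsule.
* The `resnet50` variant reproduces the block structure, not any specific
  pretrained weight set; parameter-for-parameter parity with other
  implementations is out of scope.
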