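# capstrack

Tracking a millimetre-scale magnetic sampling capsule in B-mode ultrasound:
simultaneous **mechanism-state classification** (closed / open / lost-in-FOV)
and **in-plane 2D pose estimation** (centroid + orientation), built around an
attention-based hierarchical convolutional network, plus a synthetic
ultrasound phantom generator so the whole pipeline is reproducible without
any external dataset.

## Who this is for

Ingestible capsule robots with magnetically actuated sampling mechanisms
need real-time feedback on *where* the capsule is and *whether its cavity is
open* while it is driven through the GI tract. B-mode ultrasound can provide
that feedback non-invasively, but the capsule appears as a small bright echo
inside layered, speckled tissue — a hard target for classical computer
vision. This package implements the deep-learning tracking pipeline for that
problem: researchers in medical robotics and ultrasound image analysis can
train and evaluate the tracker on synthetic phantoms or on their own
annotated B-mode frames.

## The method

A frame `I` (grayscale, resized to the network input) is processed by a
hierarchy of three models sharing one architecture:

1. **Model A — state.** Softmax over the three mechanism states
   {closed, open, lost}.
2. **Model B — orientation** (only if A says *closed*). Orientation is
   estimated by classification over 180 one-degree bins, θ ∈ {0°, …, 179°};
   the prediction is the argmax bin.
3. **Model C — centroid** (only if A says *closed*). Linear regression head
   for (x, y); pixel outputs are converted to millimetres with the probe
   scale factor (mm/px).

Each model is a residual convolutional backbone `F_l = f_l(F_{l−1}) + F_{l−1}`
followed by a **channel-attention module**: with global average- and
max-pooled channel statistics passed through a shared two-layer MLP,

    M(F) = σ( W₁(W₀(F_GAP)) + W₁(W₀(F_GMP)) ),   F' = F ⊕ (F ⊗ M(F)),

so each channel is re-weighted by a gate in (0, 1) with a residual floor
(`M → 0` leaves features untouched). A global-average-pooling layer, dropout
and a fully-connected head produce the output.

Training is **two-stage transfer learning**: stage 1 freezes the backbone and
trains the randomly initialised attention + head (Adam, LR 1e-4); stage 2
unfreezes the backbone down to a fine-tuning depth `FT = CB^i` (blocks 1..i
stay frozen) and fine-tunes at LR 1e-5, with early stopping on the
validation set. Classification uses mean cross-entropy; the centroid head
uses L = (1/2N) Σ‖y − t‖².

The dataset side reproduces the pose-label-preserving **augmentation**
protocol: rotations of 0.5°–5° in 0.5° steps about the image centre with the
standard affine rotation matrix, integer shifts t_x ∈ [−10, 10],
t_y ∈ [−10, 12] px, black-border cropping, and exact label updates
(θ′ = θ + δ mod 180; centroids mapped through the same matrix).

The **synthetic phantom** renders speckled, layered-tissue backgrounds
(multiplicative Rayleigh envelope, log compression) with a bright
8 mm × 14.5 mm stadium-shaped capsule in closed, open or lost appearance,
and returns exact ground-truth masks, poses and corner annotations.

## Worked example

```bash
# 1. generate a synthetic dataset (300 frames, 100 per state)
capstrack simulate --out data --seed 5 --width 64 --height 64 --scale-mm 0.5

# 2. split 7:2:1
capstrack split --manifest data/manifest.csv --out-dir splits --seed 5 --stratify

# 3. train one model per task (tiny backbone preset)
for task in state orientation centroid; do
  capstrack train --task $task --train-manifest splits/train.csv \
      --val-manifest splits/val.csv --out $task.npz --seed 5
done

# 4. score the tracker on the test split
capstrack evaluate --test-manifest splits/test.csv --state-model state.npz \
    --orientation-model orientation.npz --centroid-model centroid.npz \
    --out metrics.json
```

With this deliberately small demo dataset (210 training frames, of which
only ~70 are closed capsules) the `evaluate` step prints:

```
N = 30   accuracy = 0.8000
state    precision    recall        F1   support
closed        1.00      0.40      0.57        10
open          0.62      1.00      0.77        10
lost          1.00      1.00      1.00        10
pose (n=4, mis-gated closed=6): PE 2.969 mm (literal 1.612), OE 44.30 deg (success 0.0%)
```

`accuracy` is correct detections over total (here 24/30; the
under-trained state model calls most closed capsules open). The pose line
covers only frames that are ground-truth closed *and* predicted closed —
the hierarchical gate — with the 6 mis-gated closed frames counted
explicitly; it reports the mean Euclidean position error in mm, the
literal range-difference form of the error, the wrapped mean orientation
error and the ±10° success rate. Pose errors this large simply reflect 70
training frames; the properly sized run below reaches ≈ 97 % state
accuracy, ≈ 1.7 px (0.9 mm) position error and ≈ 3–8° mean orientation
error.

In Python the same pipeline is three calls:

```python
from capstrack import (PhantomConfig, render_dataset_arrays, build_model,
                       NetworkConfig, TrainConfig, two_stage_train,
                       evaluate_tracker)
```

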