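# Methods

## The problem and the model

Histology images of tumours contain densely packed, frequently touching
cell nuclei.  Two tasks recur in computational pathology pipelines:
delineating each nucleus as a separate *instance*, and assigning each
nucleus a *type* (e.g. malignant epithelium, inflammatory, normal).
This package implements both with a single multi-task encoder–decoder
plus a classical watershed post-processing step.

The network maps an RGB patch (sides divisible by 8; 80×80 is the
reference size) to three per-pixel outputs:

* **q** — a 2-channel softmax giving the probability that a pixel
  belongs to any nucleus (semantic segmentation branch);
* **p** — a 2-channel tanh-bounded regression of the *HV map*: the
  horizontal and vertical signed distances from each nucleus pixel to
  its instance's mass centre, normalized per instance to [−1, 1]
  (0 on background);
* **r** — a (K+1)-channel softmax of nucleus type, channel 0 being
  background.

The HV map is the key representation: inside a nucleus each channel is
a smooth ramp from −1 to +1, so *between* two touching nuclei the value
flips abruptly from +1 back to −1.  A derivative filter turns this flip
into a sharp ridge exactly on the inter-nucleus boundary, which is what
allows instances to be cut apart where a plain foreground mask shows a
single blob.

### Architecture

The encoder is a Conv–SN–ReLU stem followed by four residual-ghost
stages with 1, 2, 3 and 1 residual blocks respectively; stages 2–4
downsample ×2, placing the bottleneck at 1/8 resolution, and a 1×1
convolution mixes the bottleneck channels.  The decoder has three
structurally identical branches (q, p, r).  Each branch up-samples ×2
three times (nearest-neighbour followed by a convolution, which avoids
checkerboard artefacts), concatenates the matching encoder stage output
at every step, and applies a dense-ghost module of 8 blocks after the
first step and 4 after the second.

Two custom units recur throughout:

* **Ghost block (GBS)** — an ordinary 1×1 convolution produces only
  `out/s` "intrinsic" feature maps (`s` = 2 by default) and a 3×3
  depthwise convolution expands each intrinsic map into `s − 1` extra
  "ghost" maps; the concatenation is switchable-normalized.  Conv
  weight count is `C·O/s + (s−1)/s·O·k²` versus `C·O` for a dense 1×1
  convolution — cheaper whenever `C > k²`, i.e. for every width shipped
  here (all have `C > 9`).
* **Switchable normalization (SN)** — a learned softmax mixture of
  instance-, layer- and batch-normalization statistics (separate
  mixtures for mean and variance; logits are per layer).  Because the
  mixture can move weight off the minibatch statistics, the network
  trains and runs at batch size 1, where plain BN collapses.  Running
  BN moments are tracked with momentum 0.9 for inference; eps = 1e-5.

All convolutions are bias-free (the SN shift β plays that role) and
Kaiming-initialised.  Residual blocks are GBS → depthwise 3×3 (carrying
the stride) → GBS with an additive skip, 1×1-projected when the shape
changes, and ReLU after the addition (the standard residual
convention).  Dense blocks follow each GBS with an SN–ReLU as drawn in
the originating design.

### Joint loss

With ground-truth mask X, HV map Γ and one-hot types T:

    L = λa·BCE(q, X) + λb·Dice(q, X)
      + λc·MSE(p, Γ) + λd·MSGE(p, Γ; mask)
      + λe·BCE(r, T) + λf·Dice(r, T)

λ = (1, 1, 1, 1, 2, 1) and the Dice epsilon is 1e-4.  BCE is averaged
over all pixels and channels (the printed formula carries a 1/n factor
on one term only; we read that as a typesetting slip and average both
terms).  MSGE is the mean squared difference of the Sobel gradients of
prediction and target — horizontal derivative on the horizontal
channel, vertical on the vertical — restricted to ground-truth nuclei
pixels.  It directly sharpens the sign flips the watershed later
thresholds.  Numerical choices: Sobel kernels are normalized to unit
positive mass (so MSGE has the same order of magnitude as the other
terms and is invariant to kernel size); reflect padding keeps a
constant prediction offset exactly gradient-free; predictions entering
logs are clamped to [1e-7, 1−1e-7]; an empty mask defines MSGE = 0.

### Post-processing

Given q (foreground channel) and p:

1. **Gradient map** `Sm = max(Hor(p_h), Ver(p_v))`, each channel's
   Sobel response min–max rescaled to [0, 1] per image.  The responses
   are *signed* and negated so that inter-instance flips (steep steps
   of one sign) land at the top of the scale while the gentle interior
   ramps (opposite sign) land at the bottom.  Taking magnitudes instead
   collapses that margin and bridges obliquely touching nuclei — the
   signed form is essential, not cosmetic.  A constant channel maps
   to 0.
2. **Marker** `M = relu(1[q > h] − 1[Sm > k])`: confident nuclei pixels
   away from boundaries.  Components smaller than `min_object_px` are
   speckle and removed.
3. **Energy** `E = (1 − 1[Sm > k])·1[q > h]`, binary as printed; a
   continuous variant `(1 − Sm)·q` on the foreground is available via
   `PostprocessParams(continuous_energy=True)`.
4. **Marker-controlled watershed** floods −E from the marker
   components, restricted to the thresholded foreground,
   8-connectivity, deterministic tie-breaking; output labels are
   consecutive.  No markers ⇒ empty map with a logged warning.
5. **Typing**: each instance takes the majority vote of the per-pixel
   argmax over the non-background channels of r; ties break to the
   lowest class index; confidence is the winning-vote fraction.

Defaults: h = 0.5, k = 0.4, min_object_px = 10, Sobel size 5.  `h` is
the natural operating point of a 2-class softmax; `k` sits in the wide
gap between rescaled interior ramps (≈0–0.3) and boundary ridges
(≈0.7–1).

### Evaluation metrics

Dice over binary masks; AJI (greedy best-Jaccard matching in ascending
ground-truth label order, each prediction usable once, unmatched
predictions added to the union — the order dependence is inherent to
the definition); panoptic quality DQ·SQ with unique IoU > 0.5 matching;
detection F1 over the same matching; and the joint
detection+classification score Fct per type.  The same IoU > 0.5
matching backs Fd and Fct (the alternative centroid-radius pairing used
by some toolchains is not printed in our source material).  Degenerate
conventions, always logged: both maps empty scores 1.0, so a trivially
correct prediction is perfect; empty ground truth with predictions
scores 0.

## Synthetic data

`gsnhv.synthetic` renders H&E-like patches: a pink eosin background
(RGB ≈ (0.88, 0.76, 0.85) with per-image jitter), elliptical nuclei
with type-specific haematoxylin tones (dark purple / blue-violet /
maroon for the three default types), per-nucleus intensity jitter, and
additive Gaussian noise (σ = 0.03).  Each nucleus carries one type
drawn uniformly from {1..n_types}; because colour correlates with
type, the classification branch has signal to learn.

Geometry is the part that matters for the method.  Nuclei semi-axes are
drawn from (6, 13) px, matching the ~12–26 px nucleus diameters seen at
40× magnification; the lower end is additionally constrained by the
method itself — the Sobel-5 boundary band is ~4 px wide, so a nucleus
must have radius > ~5 px for a ≥10 px marker core to survive.  With
probability `overlap_prob` (default 0.3) a nucleus is seeded adjacent
to an existing one at centre distance U(0.85, 1.05)·(r_i + r_j) —
near-tangent contact, as in tissue, producing the 8-adjacent touching
instances the HV machinery exists to separate.  Placement is rejection
sampled with a minimum centre separation of 0.8·(r_i + r_j): deeper
interpenetration would carve concave crescents whose mass centre falls
outside the instance, a shape the convex-nucleus HV representation
cannot encode and which single-label annotations of real tissue do not
contain.  Later nuclei occlude earlier ones; occlusion survivors keep
their largest connected piece, and fragments under 8 px are erased.

The generator is a pure function of its config: one seed sequence is
spawned per image index, so any patch can be regenerated alone.
Augmentation (zoom, shear, quarter-turn rotation, flips, channel shift)
applies geometry identically to image and label rasters with
nearest-neighbour label interpolation.

What the generator does *not* model: stain variation and texture,
chromatin structure, out-of-focus blur, non-elliptical morphology
(spindle cells), and annotation noise.  Passing tests therefore show
that the architecture, loss, post-processing and metrics are correct
and that the pipeline can learn discriminable nuclei — they do not
certify performance on real stained tissue.

## Desk-scale experiments

`gsnhv.experiments` fixes two reference runs sized for one CPU:

* **Separation**: 50 patches containing touching nuclei, ideal inputs
  (q = binarized truth, p = exact HV map) through the post-processing;
  reports the exact-instance-count fraction and AJI.  This isolates
  steps 1–4 above from network quality.
* **End-to-end**: 200 patches (160 train / 40 held out), a narrow
  network (stage widths 12-16-24-32, growth 6 — the full architecture
  with every stage depth and both dense-module sizes intact, narrowed
  to keep a single-CPU run in minutes), 10 epochs of Adam at batch 4.
  The learning rate is 1e-3 with weight decay 0.1: the 1e-4 rate used
  for long GPU schedules on real data is too conservative for a
  400-step schedule.  Reports Dice, AJI, PQ, Fd and mean Fct on the
  held-out split.

`scripts/acceptance.py --seed S --out results.json` reruns both from
scratch and writes every quantity with the problem size used.

## Known limitations

* AJI's greedy matching is order-dependent by definition; we fix
  ascending ground-truth label order.
* The watershed's binary energy makes flooding within a plateau
  distance-like rather than probability-weighted; the continuous
  energy variant is available but not default.
* Very small nuclei (radius ≲ 5 px) lose their marker cores to the
  boundary band and merge into neighbours — a resolution limit of the
  fixed-size Sobel/threshold scheme, visible in real data too.
* The numpy engine is CPU-only and single-threaded; it is sized for
  patch-scale experiments, not whole-slide inference.
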