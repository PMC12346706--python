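# Methods

`lesionbag` implements a bag-of-local-features classifier for skin-lesion
images that is trained jointly on classification and on the *non-rigid
reconstruction* of two handcrafted feature families — edge information
(EI) and color–texture information (CTI) — and that produces per-patch
importance heatmaps whose fidelity can be audited by occlusion.

## The model

**Local-feature backbone.** The backbone B maps a 225×225×3 image I to a
feature grid X ∈ R^{25×25×2048} in which each cell depends on exactly one
33×33 input window, with windows spaced 8 pixels apart. The construction
follows the BagNet recipe on a ResNet-50 topology: a 1×1 + 3×3 stem, four
bottleneck stages of [3, 4, 6, 3] blocks in which only each stage's first
block carries a 3×3 convolution (all other spatial convolutions are 1×1),
no padding anywhere, and stage strides [2, 2, 2, 1] — composing to a
receptive field of exactly 3 → 5 → 9 → 17 → 33 pixels and a stride of 8.
Residual shortcuts are cropped top-left when the un-padded main path is
smaller, which anchors every cell's input support at (8i, 8j). The
locality claim is not assumed: `receptive_field_probe` backpropagates one
cell into the input and measures the bounding box of nonzero gradient
support, and the test suite requires it to be exactly 33×33.

**Divergers, gates, classifier.** Two independent affine 1×1 convolutions
split X into a CTI-biased stream X_CTI and an EI-biased stream X_EI. Each
stream is reweighted by a sigmoid spatial gate (1×1 conv C→64 → 1×1 conv
64→1 → sigmoid, broadcast over channels). The gated streams are
concatenated (4096 channels), globally average pooled, and classified by
a single affine FC layer. Because GAP and an affine map commute, the
image logit is exactly the mean of per-cell logits; the per-patch
decomposition the heatmaps use is an identity, not an approximation, and
is asserted to 1e-5 in the tests.

**Non-rigid reconstruction (NRR).** Rather than regressing the
handcrafted targets directly, each stream parameterizes a diagonal
Gaussian and the reconstruction is scored on a *sample*:

* CTI head: GAP → ReLU → FC 2048→128 → ReLU → FC 128→354, separately for
  μ_CTI and for log σ_CTI;
* EI head: ReLU → 1×1 conv 2048→128 → ReLU → 1×1 conv 128→2048 per cell,
  separately for μ_EI and log σ_EI;
* samples are drawn with the reparameterization trick, z = μ + σ·ε with
  ε ~ N(0, 1), so the draw is differentiable in (μ, σ);
* the EI sample is decoded to image resolution by ReLU → 1×1 conv
  2048→128 → ReLU → 1×1 conv 128→2048 → transposed convolution 2048→1
  with kernel 33 and stride 8, the exact adjoint geometry of the
  backbone's downsampling: a grid of side G maps to (G−1)·8 + 33 pixels,
  i.e. 25 → 225.

σ-branches output log σ and are exponentiated; positivity of σ is a
parameterization guarantee, not a clamp. The μ and σ branches share no
parameters, matching the equations' separate parameter sets.

**Reconstruction targets.** The CTI target C ∈ R^354 concatenates
uniform-LBP histograms (P = 8 integer neighbours, R = 1, "neighbour ≥
center" comparator, 58 uniform bins + 1 catch-all, reflect-padded
borders, L1-normalized per channel) over six channels: R, G, B and the
BT.601 Y, U, V. The chroma rows are derived exactly from the luma row
(U = 0.492(B−Y), V = 0.877(R−Y)) so that equal-RGB pixels have exactly
zero chroma. The EI target E is the Sobel gradient magnitude of the luma
channel (reflect borders), rescaled to [0, 1] by its maximum; the raw
(unrescaled) magnitude is also available, and is the right scale for
*between-image* edge-strength comparisons, since per-image rescaling
makes every image's strongest edge equal to 1 by construction.

**Losses.** L = L_S + L_Rec, with L_S the mean softmax cross-entropy and

    L_Rec = log(KL(C‖ĉ) + 1) + log(KL(E‖ê) + 1)

where each KL term is a sum-reduction divergence between the
L1-normalized target and the log-softmax of the corresponding
reconstruction (z_CTI, or the flattened decoded edge map), averaged over
the batch. Applying a KL loss requires both arguments on the simplex;
the target normalization (C renormalized globally; E + 1e-8 then
normalized over pixels) and the log-softmax link are the package's
resolution of that requirement. The log(· + 1) damping keeps early
training stable when the divergences are large.

**Optimization: SAM and PSAM.** The base optimizer is SGD (momentum 0.9,
weight decay 5e-4, batch 16, initial lr 0.002 with cosine annealing,
100 epochs at full scale). SAM evaluates the gradient at the
adversarially perturbed point w + ζ, ζ = ρ·g/‖g‖₂ (first-order
approximation of the inner maximization), and applies the base update at
w; batch-norm running statistics are frozen on the perturbed pass, and a
zero gradient skips the perturbation. PSAM draws, every step, an exact
random half of all parameter *elements* (sizes differ by at most one)
and gives that half the plain gradient while the rest receives the SAM
gradient — fine-grained, per-step randomness that acts like dropout
noise on the update rule. ρ defaults to 0.05; with ρ = 0 both reduce
exactly to SGD, and the psam fraction at 1 or 0 reduces to SGD or SAM —
all three limits are asserted to 1e-7 in the tests. Both SAM passes of a
step reuse the same reparameterization noise so the ascent and descent
see the same loss surface. The SAM ascent uses the full loss L (not
only L_S); this choice is deliberate — the perturbation should reflect
the landscape actually being minimized.

**Inference.** The decoders are dropped; only backbone, divergers, gates
and classifier run, in eval mode (frozen normalization statistics), which
is also what makes the per-patch locality exact at analysis time.

## Interpretability

For the predicted class k, every 33×33 window p (the image is zero-padded
by 16 pixels so there is one window per pixel, 225×225 of them at stride
1) yields a per-patch logit l_pk and the two gate weights A_CTI_p,
A_EI_p. Three raw maps are formed — A_CTI_p·l_pk, A_EI_p·l_pk, and
α_CTI·A_CTI_p·l_pk + α_EI·A_EI_p·l_pk, where α are the shares of positive
classifier-weight mass on the CTI/EI halves of class k's FC row
(negatives zeroed; α_CTI + α_EI = 1 whenever the row has positive mass;
an all-nonpositive row falls back to equal shares with a warning) — and
each is min-max normalized independently.

Computing 50,625 windows naively is wasteful; instead the padded image is
forwarded at all 64 (stride²) crop offsets through the eval-mode
backbone. Because each cell's output depends only on its window, this is
*bitwise* the same computation as explicit window extraction (asserted in
a padding-contract test against the explicit path) at a small multiple of
one image forward.

**Occlusion analyses.** Candidate windows are the stride-8 grid (grid²
of them; they overlap since 8 < 33). A heatmap ranks windows by the sum
of its pixels inside each window (ties broken row-major for
reproducibility; verified against exhaustive enumeration). `mask_top_k`
zeroes the top-k windows; `retain_top_k` zeroes their complement — the
two are pixelwise complementary by construction. The experiment harness
evaluates metrics against k for heatmap-guided versus seeded-random
window choices. Zero is used as the mask fill, consistent with the
zero-padding convention elsewhere.

## Synthetic study conditions

The generator emulates the two clinical cue axes the model is built to
detect, on a 3-class design in which one class pair differs *only* in
boundary sharpness and another *only* in mottling:

| class | border | texture |
|---|---|---|
| 0 | abrupt (hard cutoff) | uniform |
| 1 | gradual (smoothstep ramp, half-width 0.4 of the radius) | uniform |
| 2 | gradual | mottled (hard-edged multi-scale blobs) |

Each image is a skin-toned background (fixed palette with per-image tint
jitter and smooth low-frequency mottle) carrying one randomly placed and
oriented elliptical lesion (semi-axes 0.22–0.34 of the image side), plus
Gaussian pixel noise (sd 0.005) and, in every class, zero to four
zero-valued square occluder patches.

Three generator choices deserve explanation:

* **Hard-edged blotches.** Mottling is rendered by *thresholding* smooth
  noise fields into blobs with sharp boundaries rather than by adding the
  smooth field itself: LBP is a local-ordering statistic, and a smooth
  color shift barely changes orderings while a blob perimeter changes
  them decisively. With soft blotches the CTI cue is nearly invisible to
  the descriptor the model must reconstruct.
* **Low pixel noise.** At noise sd ≳ 0.02, i.i.d. pixel noise dominates
  the 8-neighbour orderings everywhere and both cue statistics drown;
  0.005 keeps smooth regions coherently ordered.
* **Occluder patches.** Occlusion analyses assume that a zeroed-out
  window is merely *uninformative*. A model trained on images that never
  contain dark pixels treats a black patch as far out of distribution
  and collapses after a single masked window, which measures
  distribution shift, not heatmap fidelity. Class-independent black
  occluders put zeroed patches inside the training distribution — the
  robustness that large heterogeneous clinical datasets confer
  naturally — so that masking experiments measure what they claim to.
  This fragility-without-occluders is reproducible with
  `max_occluders=0`.

The generated cues are validated with the package's own extractors: the
raw Sobel band statistic separates abrupt from gradual borders (≈ 0.65
vs ≈ 0.31 at 57 px), and a standardized linear probe on the 354-D
descriptor alone separates mottled from uniform above the majority rate.
What passing these tests shows is that the *mechanisms* behave as
specified on images whose cues are knowable by construction; it does not
show clinical-grade performance — the generator has no hair, rulers,
specular highlights, camera vignettes, stain variation, or inter-clinic
color shifts, and its class boundaries are far cleaner than real
dermoscopy.

## Test-scale configurations and problem sizes

Full-scale training of the 2048-channel model on dermoscopy archives is
out of scope for this package's test suite; the suite instead exercises
every mechanism at reduced scale, chosen so the whole suite runs on one
CPU:

* **tiny** — 57-px images, plain no-padding stack (k1s1→k3s1→k3s2→k3s2→
  k1s2; receptive field 9, stride 8, 64 channels, 7×7 grid). Used for
  unit and property tests. The bottleneck table cannot be shrunk to a
  9-px receptive field, so the tiny stack is plain by design; all
  locality and geometry guarantees are identical in kind.
* **small** — the same stack on a 105-px canvas (13×13 grid, 169
  candidate windows). Used for the trained-model checks: 300 images
  (100/class, split 60/20/20), 20 epochs of PSAM. At this density,
  masking the top-20 windows removes ~12% of the grid — close in kind to
  the full-scale regime (20 of 625 ≈ 3%) — whereas on the 7×7 grid 20 of
  49 windows blacks out ~40% of the image and saturates *any* masking
  strategy at the chance floor, making the guided-vs-random comparison
  degenerate. Under these conditions the trained model reaches ~90%
  held-out accuracy (chance 33.3%), and guided masking at k = 20 drops
  accuracy ~25 points below random masking for every baseline seed.
* **full** — 225-px, 2048 channels. Built (not trained) in the tests and
  the acceptance script to measure the architecture's constants: the
  33×33 gradient-support box, the 4096-D classifier input, the 2048
  output channels, and the 225-px decoder reconstruction.

## Numerical core

No deep-learning framework is assumed: the package carries its own
compact reverse-mode autodiff engine on NumPy (`lesionbag.autodiff`) —
Tensor with backward closures; un-padded strided convolution via
im2col/col2im; transposed convolution as its exact adjoint; batch norm
with train/eval modes and freezable running statistics; log-softmax;
an SGD optimizer with momentum and weight decay. Every operator's
gradient is checked against central finite differences in the test
suite. Model arithmetic is float32; probes and optimizer-equivalence
tests use float64 where exactness matters. Gradient-support probing
unions the support over two random inputs so a coincidentally inactive
ReLU path cannot shrink the measured box.

## Degenerate inputs and tie-breaks

* Constant raw heatmaps min-max-normalize to all zeros with a warning.
* An all-nonpositive classifier row yields α = (0.5, 0.5) with a warning.
* A class absent from the evaluation ground truth is excluded from the
  macro AUC with a warning; macro F1 uses zero-division = 0.
* Window-ranking ties break in row-major order; PSAM partitions and all
  data shuffles derive from explicit seeded generators — the package
  never touches global RNG state.
* A zero gradient skips the SAM perturbation (ζ = 0).
* Images are validated on entry (three channels, finite, [0, 1]);
  feature extraction refuses wrongly sized inputs rather than silently
  resizing.

## Known limitations

* The NumPy engine is single-device and unbatched across steps; full-
  scale (ISIC-sized) training is out of its intended range, and no
  pretrained backbone weights are shipped or downloaded.
* The reconstruction-loss normalization (targets to the simplex,
  log-softmax link) is one defensible reading of "a KL loss" applied to
  non-distribution targets; results can be sensitive to this choice.
* Heatmap semantics inherit the bag-of-features assumption: per-patch
  evidence is averaged, never contextualized, so interactions between
  distant regions are invisible by design.
* The synthetic world is a mechanism test bed, not a clinical benchmark;
  see the generator caveats above.
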