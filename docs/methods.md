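# Methods

## Model

The package implements two-stage indirect segmentation of a low-contrast
MR modality.

**Stage I (translation)** is a cycle-consistency GAN.  Generators
G_A : 𝒳→𝒴 and G_B : 𝒴→𝒳 are trained on unpaired image pools with

L^t = λ₁·L_cyc + L_gan(G_A, D_A) + L_gan(G_B, D_B),

where L_cyc is the summed mean-absolute round-trip error
E‖G_B(G_A(x)) − x‖₁ + E‖G_A(G_B(y)) − y‖₁ and each L_gan is a patch-level
adversarial loss.  λ₁ defaults to 10.  No identity-mapping loss and no
image-history pool are used (the first is a deliberate omission, the
second is available behind no flag because desk-scale runs never needed
it; both are noted under limitations).

**Stage II (segmentation)** treats mask prediction as image-to-image
translation.  Integer labels are encoded through a *mask codec* as
intensity levels (−1, −1/3, +1/3, +1) for (background, LV, MYO, RV) —
equally spaced in the canonical [−1, 1] range, which maximises the
nearest-level decoding margin.  Decoding is nearest-level quantisation
with ties toward the lower class id.  A cascade of generators refines
the prediction, I_S^k = G_k(I_S^{k−1}) with I_S^0 the (real or
translated) high-contrast image; the final cascade output is decoded to
the mask.  One shared conditional patch discriminator scores
(condition, mask-image) channel pairs, the condition being the same
source image for every cascade.  The training objective is

L^s = λ_l·Σ_k ω_k·E‖I_L − I_S^k‖₁ + Σ_k ω_k·L_gan(D(cond, I_S^k))
      + λ_vgg·L_vgg,

with defaults λ_l = 100, λ_vgg = 1, a unit coefficient on the
adversarial term, and ω^{L_g} = ω^{L1}.  All cascade outputs are
supervised jointly end-to-end; a `freeze_prior` option detaches each
previous cascade instead.

**Adversarial modes.**  `vanilla` is binary cross-entropy on raw patch
scores (computed as a stable softplus of signed logits), `lsgan` is the
least-squares form against targets 1/0, and `wgangp` is the Wasserstein
critic with a gradient penalty mean((‖∇_x D(cond, x̂)‖₂ − 1)²) at a
uniform interpolate x̂, weighted by λ_gp = 10 (the cited convention; the
source protocol does not restate it).  Generator updates always use the
non-saturating form (generated samples pushed toward the "real" target)
rather than the literal min–max, which stalls in practice.

**Perceptual loss.**  Feature maps φ_{i,j} of prediction and target are
compared per channel: `manh` takes the spatial mean absolute difference;
`cosine` takes 1 − cosine similarity of the vectorised channel maps,
with the numerical guard cos = (⟨a,b⟩ + ε)/(‖a‖‖b‖ + ε), ε = 1e−8, so
identical maps — including near-zero ones — score exactly zero loss.
Cosine of scalar entries is degenerate, which forces the per-channel
vectorised reading; the elementwise reading is kept for `manh`.  The
default extractor is a frozen, seeded 3-layer convolutional stack
(8/16/32 channels, stride 2, leaky-ReLU).  Random frozen features define
a valid perceptual metric (distances vanish iff activations agree); any
callable returning a list of feature stacks — e.g. an
ImageNet-pretrained backbone — can be substituted through the same
interface.

**Norm conventions.**  All L1-type losses are per-pixel *means*, not
sums, so the λ weights are independent of image size.

## Architectures

Generators are U-nets (stride-2 k4 encoder convolutions, nearest-up +
k3 decoder convolutions, skip concatenation, tanh output) or residual
networks (7×7 stem, two stride-2 stages, residual bottleneck, two
upsampling stages, tanh).  Instance normalisation everywhere except the
first encoder level and the bottleneck (degenerate at 1×1); weights are
seeded zero-mean Gaussians with σ = 0.02.  The discriminator is a
stack of three stride-2 k4 convolutions plus two stride-1 k4 head
convolutions; its analytic receptive field (r ← r + (k−1)·jump) is 70 px
and is verified against the requested patch size at construction.

The cascade depth rule: the first generator keeps full depth
log2(image_size), capped at 8 (so depth 8 at 256 px, 6 at 64 px);
cascades 2–4 use the reduced depths (2, 4, 5).  This reads the reduction
as the number of down/upsampling resolution stages, the only reading
consistent with shallower *later* cascades.  Later cascades consume only
the previous mask-image; an opt-in `recondition` flag re-stacks the
source image as a second input channel for experimentation.

## Synthetic phantoms

Each phantom is a short-axis-like slice: an LV blood-pool disk strictly
enclosed by a MYO annulus, an RV crescent attached outside the annulus.
Geometry (centre jitter, LV radius 8–12 px, MYO thickness 3–5 px, RV
thickness 4–7 px, RV angular extent 2.1 rad at 64 px, scaled
proportionally at other sizes) is sampled in continuous coordinates and
rasterised by pixel-centre membership, so masks are crisp.  The same
anatomy is rendered twice:

* modality B ("bSSFP-like"): class means (−0.75, 0.65, −0.20, 0.35),
  pairwise separated by ≥ 0.55 > 3σ of the additive Gaussian noise
  (σ = 0.08) — boundaries are unambiguous;
* modality A ("LGE-like"): class means (−0.55, −0.05, −0.35, −0.20),
  foreground separations of roughly 2–4 σ, plus (with probability 0.3)
  a bright myocardial "scar" patch in this modality only, emulating
  late-gadolinium enhancement.

No public per-class intensity statistics exist for the real modalities,
so these are free design parameters chosen once to make modality B
trivially separable and modality A genuinely ambiguous at the pixel
level.  What the phantoms do **not** emulate: anatomical variability
beyond ring/crescent geometry, partial-volume effects, bias fields,
motion, 3-D structure, or realistic MR noise statistics.  Passing tests
therefore demonstrate that the machinery trains, refines and transfers
as designed — not clinical-grade accuracy on real MR.

## Numerical engine

Because the pipeline needs trainable convolutional GANs, the package
carries a compact reverse-mode autodiff engine over numpy
(`cascadegan.nn`).  Each operation records vector-Jacobian products that
are themselves tape operations, so gradients are differentiable to
arbitrary order — this is what makes the WGAN-GP penalty trainable
(double backprop).  Convolution is im2col plus one BLAS GEMM; its input
gradient is a dilated full correlation with the flipped kernel, with
asymmetric padding handling non-divisible stride geometry exactly
(verified against central finite differences to 1e−7 on float64 tapes).
Tensors default to float32; float64 arrays propagate unchanged, which is
how the loss-vs-oracle checks reach ~1e−8 agreement.  Optimisation is
Adam (β = 0.5, 0.999) with optional linear learning-rate decay to zero
over the second half of training.

## Study conditions and problem sizes

The desk-scale study trains at 64×64 with batch size 1: the segmentation
cascade (n = 2, U-net, base 12 channels, first-cascade depth 4) for
3 epochs on 200 labelled high-contrast phantoms, and the translation
network for 6 epochs on 60 unpaired images per modality, both at
lr = 1e−3.  These sizes are where the synthetic task converges; the
task is intensity remapping plus shape denoising, far easier than real
MR, which is why a few epochs suffice.  The published protocol's
reference configuration (200 epochs, initial lr 1.0e−2, 256-px images)
remains expressible through `TrainConfig`/`RunConfig`; the printed
1.0e−2 is atypically high for Adam-GAN training and is exposed as
`LR_REFERENCE` rather than used by the presets.  Model selection across
epochs is not performed at desk scale (the last epoch is used); for
long runs the history log supports selecting on held-out round-trip
quality.

Training mixes a configurable fraction (default 7.5%, mirroring the
roughly 2-of-27 labelled-patient proportion of the motivating protocol)
of translated low-contrast images into the segmentation training set
when a translation model is supplied; the library-level study trains on
real high-contrast pairs only, which is the conservative variant.

## Design choices on genuinely open points

* **Discriminator pairing** — the critic sees (condition, target) vs
  (condition, prediction) pairs, the standard conditional-GAN reading,
  rather than a joint three-channel stack.
* **Joint vs greedy cascade training** — joint end-to-end by default,
  `freeze_prior` for the greedy variant.
* **Mask codec levels** — equally spaced, symmetric around 0.
* **Dice conventions** — empty-empty 1, empty-vs-nonempty 0.
* **Mutual information** — 32-bin joint histogram, natural-log units;
  reported MI values are therefore not numerically comparable to
  implementations with other binning.
* **PSNR** — peak 2.0 (the [−1, 1] range); identical images report the
  99 dB cap.

## Known limitations

* Random-feature perceptual loss is a valid metric but not a semantic
  one; swapping in pretrained features changes its character.
* The cycle-GAN stage at desk scale learns the intensity remapping
  reliably but its round-trip SSIM varies noticeably across seeds;
  averaging over seeds is built into the acceptance checks.
* No identity loss, history pool, or model selection — acceptable at
  phantom scale, likely suboptimal on real data.
* Everything is 2-D, single-channel, batch 1.
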