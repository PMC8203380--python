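# cascadegan

Indirect segmentation of low-contrast cardiac MR by cross-modality
translation and a multicascade conditional GAN, exercised end-to-end on
synthetic multimodal phantoms.

## The problem

Late-gadolinium-enhancement (LGE) cardiac MR highlights myocardial scar
but offers poor soft-tissue contrast and is rarely annotated; balanced
steady-state free-precession (bSSFP) cine MR shows crisp blood-pool and
myocardium boundaries and is comparatively easy to segment.  Rather than
segmenting the hard modality directly, this package implements the
*indirect* strategy:

1. **Stage I — translation.**  A cycle-consistency GAN with generators
   G_A : 𝒳→𝒴 (LGE-like → bSSFP-like) and G_B : 𝒴→𝒳, trained on
   *unpaired* image pools with the objective
   λ₁·L_cyc(G_A,G_B) + L_gan(G_A,D_A) + L_gan(G_B,D_B), λ₁ = 10.
2. **Stage II — multicascade segmentation.**  Segmentation is cast as
   image-to-image translation: labels {background, LV, MYO, RV} are
   encoded as a four-level intensity image, and a cascade of generators
   I_S^k = G_k ∘ … ∘ G_1(I_𝒴) refines the predicted mask-image stage by
   stage.  A single shared 70×70 patch discriminator judges
   (condition, mask-image) pairs for every cascade.  Training jointly
   minimises λ_l·L1 + L_gan + λ_vgg·L_vgg with λ_l = 100, λ_vgg = 1,
   where L1 and the adversarial term are cascade-weighted sums
   (Σ_k ω_k·…, reference weighting (1/3, 1/2, 1/6) for three cascades)
   and L_vgg is a perceptual loss on frozen convolutional feature maps
   under a Manhattan or cosine distance.

Adversarial losses come in vanilla (BCE), least-squares (LSGAN) and
Wasserstein-with-gradient-penalty (WGAN-GP) variants.  At test time an
LGE-like image is translated to the bSSFP-like domain and the cascade
output is decoded back to an integer mask.

No external dataset is required: `cascadegan.phantom` generates
short-axis-like cardiac phantoms (LV disk inside a MYO annulus with an
adjacent RV crescent) rendered in a high-contrast and a low-contrast
modality with ground-truth masks, so the whole pipeline is trainable and
testable on a laptop-scale CPU budget.

Networks are built on a compact numpy reverse-mode autodiff engine
(`cascadegan.nn`) whose op-level vector-Jacobian products are themselves
tape operations, so second-order terms such as the WGAN-GP gradient
penalty are trainable.

## Worked example

```python
from cascadegan.config import TrainConfig
from cascadegan.losses import LossConfig
from cascadegan.phantom import PhantomParams, make_dataset
from cascadegan.segmentation import (evaluate_segmentation, segment,
                                     segment_lge_indirect, train_segmentation)
from cascadegan.translation import train_translation

params = PhantomParams()                       # 64x64 phantoms
train = make_dataset(params, 200, seed=11).samples_a
heldout = make_dataset(params, 50, seed=977).samples_a
unpaired = make_dataset(params, 60, seed=55, paired=False)

seg = train_segmentation(
    [(s.image_B, s.mask) for s in train],
    LossConfig(gan_mode="lsgan", perceptual_mode="manh",
               omega_g=(0.5, 0.5), omega_1=(0.5, 0.5)),
    TrainConfig(epochs=3, lr=1e-3, seed=0), first_depth=4)

trans = train_translation(
    [s.image_A for s in unpaired.samples_a],
    [s.image_B for s in unpaired.samples_b],
    LossConfig(gan_mode="lsgan"), TrainConfig(epochs=6, lr=1e-3, seed=0))

for name, predict in [
        ("direct high-contrast", lambda im: segment(seg, im)[0]),
        ("indirect low-contrast",
         lambda im: segment_lge_indirect(trans, seg, im))]:
    pairs = [(s.image_B if "high" in name else s.image_A, s.mask)
             for s in heldout]
    table = evaluate_segmentation(predict, pairs)
    print(name, {k: f"{r.mean:.3f}±{r.sd:.3f}" for k, r in table.items()})
```

On one CPU this trains in a few minutes and prints (seed 0):

```
direct high-contrast {'LV': '0.946±0.015', 'MYO': '0.903±0.020', 'RV': '0.923±0.025'}
indirect low-contrast {'LV': '0.845±0.035', 'MYO': '0.629±0.079', 'RV': '0.739±0.075'}
```

Direct segmentation of the *easy* modality is near-ceiling; the indirect
path recovers most of that accuracy on the *hard* modality, while
feeding the same model raw low-contrast images collapses to Dice ≈ 0.2
— the quantitative motivation for the two-stage design.

The same pipeline is scriptable from the shell:

```sh
cascadegan run-all --seed 7 --out-dir runs/demo   # data → both stages → Dice CSV
cascadegan losses-check                           # every loss vs its loop oracle
cascadegan gen-data --n 20 --out-dir data --format nifti
```

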