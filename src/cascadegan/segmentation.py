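"""Stage II: multicascade conditional-GAN segmentation.

Segmentation is treated as image-to-image translation: integer label
masks are encoded as single-channel images at four equally spaced
intensity levels (background -1, LV -1/3, MYO +1/3, RV +1), a cascade of
generators G_n ∘ … ∘ G_1 maps the input image to a mask-image, and a
shared conditional patch discriminator judges (condition, mask-image)
pairs — every cascade's output against the same condition.  The
generator step jointly minimises the cascade-weighted adversarial, L1
and perceptual losses over all cascade outputs; decoding is
nearest-level quantisation with ties toward the lower class id.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .config import TrainConfig
from .losses import (LossConfig, NumericError, RandomFeatureExtractor,
                     cascade_adversarial_losses, cascade_l1_loss,
                     perceptual_loss, segmentation_total_loss)
from .metrics import MetricReport, dice_table
from .networks import (ConfigurationError, DiscriminatorSpec, GeneratorSpec,
                       build_generator, build_patch_discriminator,
                       build_simplified_unet_cascade, cascade_forward)
from .nn import Tensor

from .translation import TranslationModel, _as_batch, translate


class DataError(ValueError):
    pass


@dataclass
class MaskCodec:
    """Bijection between class labels and intensity levels in [-1, 1]."""

    levels: Tuple[float, ...] = (-1.0, -1.0 / 3.0, 1.0 / 3.0, 1.0)

    def __post_init__(self):
        if len(set(self.levels)) != len(self.levels):
            raise ConfigurationError("codec levels must be pairwise distinct")

    def encode(self, mask: np.ndarray) -> np.ndarray:
        """Pixelwise label -> level lookup."""
        labels = np.unique(mask)
        if labels.min() < 0 or labels.max() >= len(self.levels):
            raise DataError(f"mask labels outside codec table: {labels}")
        table = np.asarray(self.levels, dtype=np.float32)
        return table[mask.astype(np.int64)]

    def decode(self, image: np.ndarray) -> np.ndarray:
        """Nearest-level quantisation; ties go to the lower class id."""
        img = np.asarray(image, dtype=np.float32)
        table = np.asarray(self.levels, dtype=np.float32)
        dist = np.abs(img[..., None] - table)  # (..., n_levels)
        return np.argmin(dist, axis=-1).astype(np.int16)


@dataclass
class SegModel:
    generators: List[nn.Module]
    discriminator: nn.Module
    codec: MaskCodec
    image_size: int
    history: List[Dict[str, float]] = field(default_factory=list)
    config_digest: str = ""
    build_info: Dict = field(default_factory=dict)

    @property
    def n_cascades(self) -> int:
        return len(self.generators)

    def digest(self) -> str:
        import hashlib
        h = hashlib.sha256()
        for g in self.generators:
            h.update(g.param_digest().encode())
        h.update(self.discriminator.param_digest().encode())
        return h.hexdigest()

    def save(self, path: str) -> None:
        os.makedirs(path, exist_ok=True)
        for i, g in enumerate(self.generators):
            np.savez(os.path.join(path, f"g{i + 1}.npz"), **g.state_dict())
        np.savez(os.path.join(path, "d.npz"),
                 **self.discriminator.state_dict())
        meta = {"image_size": self.image_size, "n_cascades": self.n_cascades,
                "levels": list(self.codec.levels), "digest": self.digest(),
                "config_digest": self.config_digest, "history": self.history,
                "build_info": self.build_info}
        with open(os.path.join(path, "meta.json"), "w") as fh:
            json.dump(meta, fh)


def build_seg_model(n_cascades: int = 2, image_size: int = 64,
                    arch: str = "unet", base_channels: int = 12,
                    seed: int = 0, first_depth: Optional[int] = None,
                    recondition: bool = False,
                    disc_norm: str = "instance") -> SegModel:
    """Cascade generators plus one shared conditional patch critic.

    ``first_depth`` overrides the full-depth rule for the first cascade
    (desk-scale presets use shallower first stages).
    """
    if arch == "unet":
        specs = build_simplified_unet_cascade(n_cascades, image_size,
                                              base_channels, recondition)
        if first_depth is not None:
            specs[0] = GeneratorSpec(kind="unet", depth=first_depth,
                                     base_channels=base_channels,
                                     in_channels=1, out_channels=1)
    elif arch == "resnet":
        if not 1 <= n_cascades <= 4:
            raise ConfigurationError("n_cascades must be in [1, 4]")
        specs = [GeneratorSpec(kind="resnet", depth=2,
                               base_channels=base_channels,
                               in_channels=1 if (k == 0 or not recondition) else 2,
                               out_channels=1)
                 for k in range(n_cascades)]
    else:
        raise ConfigurationError(f"unknown arch {arch!r}")
    gens = [build_generator(s, seed=seed + 10 + k) for k, s in enumerate(specs)]
    disc = build_patch_discriminator(
        DiscriminatorSpec(in_channels=2, base_channels=24), seed=seed + 99,
        norm=disc_norm)
    return SegModel(generators=gens, discriminator=disc, codec=MaskCodec(),
                    image_size=image_size,
                    build_info={"n_cascades": n_cascades,
                                "image_size": image_size, "arch": arch,
                                "base_channels": base_channels,
                                "first_depth": first_depth,
                                "recondition": recondition,
                                "disc_norm": disc_norm})


def load_seg_model(path: str) -> SegModel:
    with open(os.path.join(path, "meta.json")) as fh:
        meta = json.load(fh)
    bi = meta.get("build_info", {})
    model = build_seg_model(int(meta["n_cascades"]), int(meta["image_size"]),
                            bi.get("arch", "unet"),
                            bi.get("base_channels", 12),
                            first_depth=bi.get("first_depth"),
                            recondition=bi.get("recondition", False),
                            disc_norm=bi.get("disc_norm", "instance"))
    model.codec = MaskCodec(tuple(meta["levels"]))
    for i, g in enumerate(model.generators):
        with np.load(os.path.join(path, f"g{i + 1}.npz")) as z:
            g.load_state_dict(dict(z))
    with np.load(os.path.join(path, "d.npz")) as z:
        model.discriminator.load_state_dict(dict(z))
    model.history = meta.get("history", [])
    if meta.get("digest") and meta["digest"] != model.digest():
        raise IOError("checkpoint digest mismatch (corrupt or wrong spec)")
    return model


def train_segmentation(dataset: Sequence[Tuple[np.ndarray, np.ndarray]],
                       loss_config: LossConfig,
                       train_config: TrainConfig,
                       model: Optional[SegModel] = None,
                       arch: str = "unet",
                       base_channels: int = 12,
                       first_depth: Optional[int] = None,
                       extractor: Optional[nn.Module] = None,
                       freeze_prior: bool = False) -> SegModel:
    """Train the multicascade segmentation GAN on (image, mask) pairs.

    All cascade outputs are supervised jointly (end-to-end); with
    ``freeze_prior`` each generator update detaches the previous
    cascade's output instead.  Deterministic given ``train_config.seed``.
    """
    if len(dataset) == 0:
        raise DataError("segmentation training needs a nonempty dataset")
    n_casc = loss_config.n_cascades
    image_size = int(np.asarray(dataset[0][0]).shape[-1])
    if model is None:
        model = build_seg_model(n_casc, image_size, arch, base_channels,
                                seed=train_config.seed,
                                first_depth=first_depth)
    if model.n_cascades != n_casc:
        raise ConfigurationError(
            f"loss_config has {n_casc} cascade weights but the model has "
            f"{model.n_cascades} generators")
    if extractor is None and loss_config.perceptual_mode != "off":
        extractor = RandomFeatureExtractor(seed=0)
    mode = loss_config.gan_mode
    rng = np.random.default_rng([train_config.seed, 0x5E6])

    gen_params = [p for g in model.generators for p in g.parameters()]
    opt_g = nn.Adam(gen_params, lr=train_config.lr, betas=train_config.betas)
    opt_d = nn.Adam(model.discriminator.parameters(), lr=train_config.lr,
                    betas=train_config.betas)

    encoded = [(np.asarray(img, dtype=np.float32),
                model.codec.encode(np.asarray(msk)))
               for img, msk in dataset]

    for epoch in range(train_config.epochs):
        f = train_config.lr_factor(epoch)
        opt_g.set_lr_factor(f)
        opt_d.set_lr_factor(f)
        order = rng.permutation(len(encoded))
        ep = {"L1": 0.0, "L_gan": 0.0, "L_vgg": 0.0, "L_D": 0.0, "total": 0.0}
        for idx in order:
            img, enc = encoded[idx]
            cond = _as_batch(img)
            target = _as_batch(enc)

            preds = _cascade(model, cond, freeze_prior)

            d_loss, g_gan = cascade_adversarial_losses(
                model.discriminator, cond, target, preds,
                loss_config.omega_g, mode,
                lambda_gp=loss_config.lambda_gp, rng=rng)

            opt_d.zero_grad()
            # generator outputs are detached inside for the D half-step
            d_loss.backward()
            opt_d.step()

            l1 = cascade_l1_loss(preds, target, loss_config.omega_1)
            if loss_config.perceptual_mode != "off":
                l_vgg = perceptual_loss(extractor, preds, target,
                                        loss_config.perceptual_mode)
            else:
                l_vgg = Tensor(np.float32(0.0))
            total = segmentation_total_loss(l1, g_gan, l_vgg,
                                            loss_config.lambda_l,
                                            loss_config.lambda_vgg)
            if not np.isfinite(total.item()):
                raise NumericError(
                    f"segmentation loss diverged at epoch {epoch}")
            opt_g.zero_grad()
            total.backward()
            opt_g.step()

            ep["L1"] += l1.item()
            ep["L_gan"] += g_gan.item()
            ep["L_vgg"] += l_vgg.item()
            ep["L_D"] += d_loss.item()
            ep["total"] += total.item()
        model.history.append(
            {k: v / len(encoded) for k, v in ep.items()} | {"epoch": epoch})
    return model


def _cascade(model: SegModel, cond: Tensor, freeze_prior: bool) -> List[Tensor]:
    if not freeze_prior:
        return cascade_forward(model.generators, cond, condition=cond)
    outs: List[Tensor] = []
    cur = cond
    for g in model.generators:
        cur = g(cur)
        outs.append(cur)
        cur = cur.detach()
    return outs


def segment(model: SegModel, image: np.ndarray
            ) -> Tuple[np.ndarray, List[np.ndarray]]:
    """Decode the final cascade output; also return all intermediates."""
    arr = np.asarray(image, dtype=np.float32)
    if arr.shape[-1] != model.image_size:
        raise DataError(
            f"image size {arr.shape} != trained size {model.image_size}")
    with nn.no_grad():
        cond = _as_batch(arr)
        preds = cascade_forward(model.generators, cond, condition=cond)
    outs = [p.data[0, 0] for p in preds]
    return model.codec.decode(outs[-1]), outs


def segment_lge_indirect(tmodel: TranslationModel, smodel: SegModel,
                         lge_image: np.ndarray) -> np.ndarray:
    """Indirect path: translate low-contrast -> high-contrast, then segment."""
    if tmodel.image_size != smodel.image_size:
        raise ConfigurationError(
            "translation and segmentation models trained at different sizes")
    fake_b = translate(tmodel, lge_image, "A2B")
    mask, _ = segment(smodel, fake_b)
    return mask


def evaluate_segmentation(predict_fn, dataset: Sequence[Tuple[np.ndarray, np.ndarray]]
                          ) -> Dict[str, MetricReport]:
    """Per-class Dice (LV/MYO/RV), mean ± sd, for any image->mask callable."""
    if len(dataset) == 0:
        raise ConfigurationError("evaluate_segmentation: empty dataset")
    preds = [predict_fn(img) for img, _ in dataset]
    truths = [np.asarray(m) for _, m in dataset]
    return dice_table(preds, truths)


def mixed_training_set(samples, tmodel: Optional[TranslationModel],
                       fake_fraction: float = 0.075,
                       rng: Optional[np.random.Generator] = None
                       ) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Training pairs: real high-contrast images plus a fraction of fake
    high-contrast images translated from labelled low-contrast ones."""
    rng = rng or np.random.default_rng(0)
    pairs = [(s.image_B, s.mask) for s in samples]
    if tmodel is not None and fake_fraction > 0:
        k = max(1, int(round(fake_fraction * len(samples))))
        idx = rng.choice(len(samples), size=k, replace=False)
        for i in idx:
            fake_b = translate(tmodel, samples[i].image_A, "A2B")
            pairs.append((fake_b, samples[i].mask))
    return pairs
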