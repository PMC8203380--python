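"""Stage I: unpaired cross-modality translation (cycle-consistency GAN).

Two generators (G_A: low-contrast -> high-contrast domain, G_B the
reverse) and two patch discriminators are trained on unpaired image
pools.  Each iteration updates the discriminators on real-vs-generated
pairs and the generators on the adversarial terms plus λ1 times the
round-trip (cycle) error.  No identity-mapping loss and no image history
pool are used.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import nn
from .config import TrainConfig
from .losses import (LossConfig, NumericError, cycle_loss, gan_loss,
                     translation_total_loss)
from .metrics import MetricReport, mutual_information, psnr, ssim
from .networks import (DiscriminatorSpec, GeneratorSpec,
                       build_generator, build_patch_discriminator)
from .nn import Tensor


def _as_batch(img: np.ndarray) -> Tensor:
    arr = np.asarray(img, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        arr = arr[None]
    return Tensor(arr)


@dataclass
class TranslationModel:
    g_a: nn.Module  # A (low contrast) -> B (high contrast)
    g_b: nn.Module  # B -> A
    d_a: nn.Module  # judges B-domain images
    d_b: nn.Module  # judges A-domain images
    image_size: int
    history: List[Dict[str, float]] = field(default_factory=list)
    config_digest: str = ""
    build_info: Dict = field(default_factory=dict)

    def digest(self) -> str:
        import hashlib
        h = hashlib.sha256()
        for m in (self.g_a, self.g_b, self.d_a, self.d_b):
            h.update(m.param_digest().encode())
        return h.hexdigest()

    def save(self, path: str) -> None:
        os.makedirs(path, exist_ok=True)
        for name, m in (("g_a", self.g_a), ("g_b", self.g_b),
                        ("d_a", self.d_a), ("d_b", self.d_b)):
            np.savez(os.path.join(path, f"{name}.npz"), **m.state_dict())
        meta = {"image_size": self.image_size, "digest": self.digest(),
                "config_digest": self.config_digest, "history": self.history,
                "build_info": self.build_info}
        with open(os.path.join(path, "meta.json"), "w") as fh:
            json.dump(meta, fh)


def default_translation_model(image_size: int = 64, base_channels: int = 12,
                              kind: str = "unet", seed: int = 0,
                              depth: int = 3) -> TranslationModel:
    spec = GeneratorSpec(kind=kind, depth=depth, base_channels=base_channels)
    dspec = DiscriminatorSpec(in_channels=1, base_channels=24)
    return TranslationModel(
        g_a=build_generator(spec, seed=seed),
        g_b=build_generator(spec, seed=seed + 1),
        d_a=build_patch_discriminator(dspec, seed=seed + 2),
        d_b=build_patch_discriminator(dspec, seed=seed + 3),
        image_size=image_size,
        build_info={"image_size": image_size, "base_channels": base_channels,
                    "kind": kind, "depth": depth},
    )


def load_translation_model(path: str) -> TranslationModel:
    with open(os.path.join(path, "meta.json")) as fh:
        meta = json.load(fh)
    bi = meta.get("build_info", {})
    model = default_translation_model(
        bi.get("image_size", 64), bi.get("base_channels", 12),
        bi.get("kind", "unet"), depth=bi.get("depth", 3))
    for name, m in (("g_a", model.g_a), ("g_b", model.g_b),
                    ("d_a", model.d_a), ("d_b", model.d_b)):
        with np.load(os.path.join(path, f"{name}.npz")) as z:
            m.load_state_dict(dict(z))
    model.image_size = int(meta["image_size"])
    model.history = meta.get("history", [])
    if meta.get("digest") and meta["digest"] != model.digest():
        raise IOError("checkpoint digest mismatch (corrupt or wrong spec)")
    return model


def train_translation(dataset_a: Sequence[np.ndarray],
                      dataset_b: Sequence[np.ndarray],
                      loss_config: LossConfig,
                      train_config: TrainConfig,
                      model: Optional[TranslationModel] = None,
                      image_size: Optional[int] = None,
                      base_channels: int = 12) -> TranslationModel:
    """Train the cycle-consistency translation network.

    ``dataset_a`` / ``dataset_b`` are unpaired pools of 2-D images in
    [-1, 1].  Deterministic given ``train_config.seed``.
    """
    if len(dataset_a) == 0 or len(dataset_b) == 0:
        raise ValueError("translation training needs nonempty datasets")
    if image_size is None:
        image_size = int(np.asarray(dataset_a[0]).shape[-1])
    if model is None:
        model = default_translation_model(image_size, base_channels,
                                          seed=train_config.seed)
    mode = loss_config.gan_mode
    rng = np.random.default_rng([train_config.seed, 0xC1C1E])

    opt_g = nn.Adam(model.g_a.parameters() + model.g_b.parameters(),
                    lr=train_config.lr, betas=train_config.betas)
    opt_d = nn.Adam(model.d_a.parameters() + model.d_b.parameters(),
                    lr=train_config.lr, betas=train_config.betas)

    n = max(len(dataset_a), len(dataset_b))
    for epoch in range(train_config.epochs):
        f = train_config.lr_factor(epoch)
        opt_g.set_lr_factor(f)
        opt_d.set_lr_factor(f)
        order_a = rng.permutation(len(dataset_a))
        order_b = rng.permutation(len(dataset_b))
        ep = {"L_cyc": 0.0, "L_gan_A": 0.0, "L_gan_B": 0.0, "total": 0.0}
        for it in range(n):
            xa = _as_batch(dataset_a[order_a[it % len(dataset_a)]])
            xb = _as_batch(dataset_b[order_b[it % len(dataset_b)]])

            # generator update
            fake_b = model.g_a(xa)
            rec_a = model.g_b(fake_b)
            fake_a = model.g_b(xb)
            rec_b = model.g_a(fake_a)
            l_cyc = cycle_loss(xa, rec_a, xb, rec_b)
            l_gan_a = gan_loss(mode, model.d_a(fake_b), True)
            l_gan_b = gan_loss(mode, model.d_b(fake_a), True)
            g_total = translation_total_loss(l_cyc, l_gan_a, l_gan_b,
                                             loss_config.lambda_1)
            if not np.isfinite(g_total.item()):
                raise NumericError(
                    f"translation loss diverged at epoch {epoch}")
            opt_g.zero_grad()
            g_total.backward()
            opt_g.step()

            # discriminator update on detached fakes
            d_loss = (gan_loss(mode, model.d_a(xb), True) +
                      gan_loss(mode, model.d_a(fake_b.detach()), False) +
                      gan_loss(mode, model.d_b(xa), True) +
                      gan_loss(mode, model.d_b(fake_a.detach()), False))
            opt_d.zero_grad()
            d_loss.backward()
            opt_d.step()

            ep["L_cyc"] += l_cyc.item()
            ep["L_gan_A"] += l_gan_a.item()
            ep["L_gan_B"] += l_gan_b.item()
            ep["total"] += g_total.item()
        model.history.append({k: v / n for k, v in ep.items()} | {"epoch": epoch})
    return model


def translate(model: TranslationModel, image: np.ndarray,
              direction: str = "A2B") -> np.ndarray:
    """Single deterministic forward pass; output in [-1, 1], same shape."""
    if direction not in ("A2B", "B2A"):
        raise ValueError(f"direction must be A2B or B2A, got {direction!r}")
    arr = np.asarray(image, dtype=np.float32)
    if arr.shape[-1] != model.image_size:
        raise ValueError(
            f"image size {arr.shape} does not match trained size "
            f"{model.image_size}")
    gen = model.g_a if direction == "A2B" else model.g_b
    with nn.no_grad():
        out = gen(_as_batch(arr))
    return out.data[0, 0]


def evaluate_translation(model: TranslationModel,
                         paired_a: Sequence[np.ndarray],
                         paired_b: Sequence[np.ndarray]) -> Dict[str, Dict[str, MetricReport]]:
    """Round-trip quality table, one row per direction.

    Row "A2B2A" compares each real A image with its reconstruction
    G_B(G_A(A)); row "B2A2B" the reverse.  SSIM/PSNR/MI are computed
    per sample and aggregated mean ± sd.
    """
    if len(paired_a) != len(paired_b) or len(paired_a) == 0:
        raise ValueError("evaluate_translation needs aligned, nonempty pairs")
    rows: Dict[str, Dict[str, MetricReport]] = {}
    for row, pool, d1, d2 in (("A2B2A", paired_a, "A2B", "B2A"),
                              ("B2A2B", paired_b, "B2A", "A2B")):
        s_vals, p_vals, m_vals = [], [], []
        for img in pool:
            rt = translate(model, translate(model, img, d1), d2)
            s_vals.append(ssim(img, rt))
            p_vals.append(psnr(img, rt))
            m_vals.append(mutual_information(img, rt))
        rows[row] = {"SSIM": MetricReport("SSIM", s_vals),
                     "PSNR": MetricReport("PSNR", p_vals),
                     "MI": MetricReport("MI", m_vals)}
    return rows
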