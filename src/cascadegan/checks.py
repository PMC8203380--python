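"""Oracle cross-checks: every loss against its nested-loop reference.

Runs each vectorised loss on seeded random tiny instances (float64
tapes, so deviations reflect logic, not rounding) and reports the
maximum absolute deviation from :mod:`cascadegan.reference`.
"""

from __future__ import annotations

from typing import Dict

import numpy as np

from . import losses as L
from . import nn
from . import reference as R
from .networks import DiscriminatorSpec, build_patch_discriminator
from .nn import Tensor

ORACLE_TOL = 1e-6


def _float64_extractor(seed: int = 0) -> L.RandomFeatureExtractor:
    ext = L.RandomFeatureExtractor(seed=seed)
    for p in ext.parameters():
        p.data = p.data.astype(np.float64)
    return ext


def _float64_disc(seed: int = 0, in_channels: int = 2):
    disc = build_patch_discriminator(
        DiscriminatorSpec(in_channels=in_channels, base_channels=4), seed=seed)
    for p in disc.parameters():
        p.data = p.data.astype(np.float64)
    return disc


def run_oracle_suite(seed: int = 0, n_instances: int = 50,
                     perturb: float = 0.0) -> Dict[str, float]:
    """Max |implementation − reference| per loss over random instances.

    ``perturb`` adds a known offset to the implementation side — a
    self-test that the comparison actually detects a broken loss.
    """
    rng = np.random.default_rng(seed)
    dev: Dict[str, float] = {}

    def upd(key: str, impl: float, ref: float) -> None:
        dev[key] = max(dev.get(key, 0.0), abs(impl + perturb - ref))

    ext = _float64_extractor(seed)

    def ext_np(img):
        with nn.no_grad():
            return [f.data for f in ext(Tensor(img))]

    disc = _float64_disc(seed)

    def disc_np(cond, img):
        with nn.no_grad():
            return disc(nn.concat([Tensor(cond), Tensor(img)], axis=1)).data

    for _ in range(n_instances):
        sm = rng.normal(0, 1, (2, 4, 4))
        for mode in L.GAN_MODES:
            for tgt in (True, False):
                upd(f"gan_{mode}_{'real' if tgt else 'fake'}",
                    L.gan_loss(mode, Tensor(sm), tgt).item(),
                    R.gan_loss_ref(mode, sm, tgt))

        x, xr, y, yr = (rng.normal(0, 1, (1, 1, 4, 4)) for _ in range(4))
        upd("cycle", L.cycle_loss(*map(Tensor, (x, xr, y, yr))).item(),
            R.cycle_loss_ref(x, xr, y, yr))

        n_c = int(rng.integers(1, 4))
        omega = rng.uniform(0, 1, n_c)
        target = rng.normal(0, 1, (1, 1, 4, 4))
        preds = [rng.normal(0, 1, (1, 1, 4, 4)) for _ in range(n_c)]
        upd("cascade_l1",
            L.cascade_l1_loss([Tensor(p) for p in preds], Tensor(target),
                              omega).item(),
            R.cascade_l1_loss_ref(preds, target, omega))

        cond64 = rng.normal(0, 1, (1, 1, 64, 64))
        tgt64 = rng.normal(0, 1, (1, 1, 64, 64))
        preds64 = [rng.normal(0, 1, (1, 1, 64, 64)) for _ in range(n_c)]
        for mode in L.GAN_MODES:
            dl, gl = L.cascade_adversarial_losses(
                disc, Tensor(cond64), Tensor(tgt64),
                [Tensor(p) for p in preds64], omega, mode, lambda_gp=0.0,
                rng=np.random.default_rng(0))
            dlr, glr = R.cascade_adversarial_losses_ref(
                disc_np, cond64, tgt64, preds64, omega, mode)
            upd(f"cascade_adv_{mode}_d", dl.item(), dlr)
            upd(f"cascade_adv_{mode}_g", gl.item(), glr)

        # gradient penalty against an exactly-differentiable linear critic
        wlin = rng.normal(0, 1, (1, 1, 3, 3))

        def d_lin(cond, img):
            return nn.sum_(img * Tensor(wlin))

        real = rng.normal(0, 1, (2, 1, 3, 3))
        fake = rng.normal(0, 1, (2, 1, 3, 3))
        pen = L.gradient_penalty(d_lin, Tensor(np.zeros((2, 1, 3, 3))),
                                 Tensor(real), Tensor(fake),
                                 np.random.default_rng(seed))
        # analytic: gradient of sum(w*x) is w everywhere
        gnorm = np.sqrt(np.sum(wlin ** 2))
        upd("gradient_penalty", pen.item(), (gnorm - 1.0) ** 2)

        tgt8 = rng.normal(0, 1, (1, 1, 8, 8))
        preds8 = [rng.normal(0, 1, (1, 1, 8, 8)) for _ in range(2)]
        for mode in ("manh", "cosine"):
            upd(f"perceptual_{mode}",
                L.perceptual_loss(ext, [Tensor(p) for p in preds8],
                                  Tensor(tgt8), mode).item(),
                R.perceptual_loss_ref(ext_np, preds8, tgt8, mode))

        parts = rng.uniform(0, 1, 3)
        upd("translation_total",
            L.translation_total_loss(*(Tensor(np.float64(v)) for v in parts)).item(),
            R.translation_total_loss_ref(*parts))
        upd("segmentation_total",
            L.segmentation_total_loss(*(Tensor(np.float64(v)) for v in parts)).item(),
            R.segmentation_total_loss_ref(*parts))

    return dev
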