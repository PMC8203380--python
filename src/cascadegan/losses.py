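"""Training objectives for both stages.

Adversarial losses come in three flavours: ``vanilla`` (binary
cross-entropy on pre-sigmoid patch scores), ``lsgan`` (least squares
against 1/0 targets) and ``wgangp`` (Wasserstein critic with gradient
penalty).  The generator term always uses the non-saturating form, i.e.
generated samples are pushed toward the "real" target.

Cascade losses weight each generator stage k by ω_k: the L1 term is
Σ_k ω_k·mean|target − I_S^k| and the adversarial terms weight the
per-stage GAN losses the same way.  Norms are per-pixel means, not sums,
so the λ weights stay independent of the image size.

The perceptual loss compares frozen convolutional feature maps of
prediction and target, channel by channel, under either a Manhattan
(mean absolute, spatially averaged) or cosine (1 − cosine similarity of
the vectorised channel map) distance.

A nested-loop transcription of every formula lives in
:mod:`cascadegan.reference` and is used as the test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .networks import ConfigurationError
from .nn import Tensor

GAN_MODES = ("vanilla", "lsgan", "wgangp")
PERCEPTUAL_MODES = ("off", "manh", "cosine")


class NumericError(ArithmeticError):
    """Raised when a loss evaluates to NaN/Inf."""


@dataclass
class LossConfig:
    """Weights and modes for the segmentation-stage objective.

    Defaults: λ1=10 (cycle), λ_l=100 (cascade L1), λ_vgg=1 (perceptual),
    unit weight on the adversarial term; ω_g == ω_1 across cascades.
    """

    gan_mode: str = "lsgan"
    perceptual_mode: str = "off"
    omega_g: Tuple[float, ...] = (1.0,)
    omega_1: Tuple[float, ...] = (1.0,)
    lambda_1: float = 10.0
    lambda_l: float = 100.0
    lambda_vgg: float = 1.0
    lambda_gp: float = 10.0

    def __post_init__(self):
        if self.gan_mode not in GAN_MODES:
            raise ConfigurationError(f"unknown gan_mode {self.gan_mode!r}")
        if self.perceptual_mode not in PERCEPTUAL_MODES:
            raise ConfigurationError(
                f"unknown perceptual_mode {self.perceptual_mode!r}")
        self.omega_g = tuple(float(w) for w in self.omega_g)
        self.omega_1 = tuple(float(w) for w in self.omega_1)
        if len(self.omega_g) != len(self.omega_1):
            raise ConfigurationError("omega_g and omega_1 lengths differ")
        if any(w < 0 for w in self.omega_g + self.omega_1):
            raise ConfigurationError("cascade weights must be >= 0")
        for name in ("lambda_1", "lambda_l", "lambda_vgg", "lambda_gp"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    @property
    def n_cascades(self) -> int:
        return len(self.omega_g)


def _check_finite(x: np.ndarray) -> None:
    if not np.all(np.isfinite(x)):
        raise NumericError("non-finite score map")


def gan_loss(mode: str, score_map: Tensor, target_is_real: bool) -> Tensor:
    """Scalar adversarial loss of a patch score map against a target.

    ``vanilla`` expects raw (pre-sigmoid) scores and applies binary
    cross-entropy; ``lsgan`` squares the distance to 1 (real) or 0
    (fake); ``wgangp`` is the critic mean with a sign.
    """
    if mode not in GAN_MODES:
        raise ConfigurationError(f"unknown gan_mode {mode!r}")
    _check_finite(score_map.data)
    if mode == "vanilla":
        # BCE-with-logits: real -> softplus(-s); fake -> softplus(s)
        s = nn.neg(score_map) if target_is_real else score_map
        return nn.mean(nn.softplus(s))
    if mode == "lsgan":
        t = 1.0 if target_is_real else 0.0
        d = score_map - t
        return nn.mean(d * d)
    # wgangp
    m = nn.mean(score_map)
    return nn.neg(m) if target_is_real else m


def cycle_loss(x: Tensor, x_roundtrip: Tensor,
               y: Tensor, y_roundtrip: Tensor) -> Tensor:
    """Mean-absolute round-trip error, summed over both domains."""
    if x.shape != x_roundtrip.shape or y.shape != y_roundtrip.shape:
        raise ValueError("cycle_loss shape mismatch")
    return nn.mean(nn.abs_(x - x_roundtrip)) + nn.mean(nn.abs_(y - y_roundtrip))


def cascade_l1_loss(predictions: Sequence[Tensor], target: Tensor,
                    omega_1: Sequence[float]) -> Tensor:
    """Σ_k ω_k · mean|target − I_S^k|."""
    if len(predictions) != len(omega_1):
        raise ConfigurationError("omega_1 length != number of cascade outputs")
    dt = target.data.dtype
    total = Tensor(dt.type(0.0))
    for w, pred in zip(omega_1, predictions):
        if pred.shape != target.shape:
            raise ValueError("prediction/target shape mismatch")
        total = total + Tensor(dt.type(w)) * nn.mean(nn.abs_(target - pred))
    return total


def gradient_penalty(d_apply, condition: Tensor, real: Tensor, fake: Tensor,
                     rng: np.random.Generator) -> Tensor:
    """WGAN-GP penalty mean((‖∇_x D(cond, x̂)‖₂ − 1)²) at a random
    interpolate x̂ between real and fake.

    ``d_apply(condition, image)`` must return the score map.  The returned
    tensor is differentiable w.r.t. the critic parameters (double
    backprop through the tape).
    """
    if real.shape != fake.shape:
        raise ValueError("real/fake shape mismatch")
    eps = rng.uniform(0.0, 1.0, (real.shape[0],) + (1,) * (real.ndim - 1))
    x_hat = Tensor((eps * real.data + (1.0 - eps) * fake.data
                    ).astype(real.data.dtype), requires_grad=True)
    score = d_apply(condition, x_hat)
    from .nn.tensor import grad as tape_grad
    gx, = tape_grad(nn.sum_(score), [x_hat], create_graph=True)
    n = real.shape[0]
    g2 = nn.reshape(gx * gx, (n, -1)).sum(axis=1)
    norm = nn.pow_(g2 + 1e-12, 0.5)
    pen = (norm - 1.0) ** 2
    return nn.mean(pen)


def cascade_adversarial_losses(discriminator, condition: Tensor,
                               target: Tensor,
                               predictions: Sequence[Tensor],
                               omega_g: Sequence[float], mode: str,
                               lambda_gp: float = 10.0,
                               rng: Optional[np.random.Generator] = None
                               ) -> Tuple[Tensor, Tensor]:
    """Cascade-weighted (d_loss, g_loss) for a shared conditional critic.

    d_loss = Σ_k ω_k·[gan(D(cond,target), real) + gan(D(cond,I_S^k), fake)]
    g_loss = Σ_k ω_k·gan(D(cond,I_S^k), real)          (non-saturating)

    For ``wgangp`` a λ_gp-weighted gradient penalty is added per cascade.
    The fake images fed to the critic for d_loss are detached so the
    discriminator update never reaches generator parameters.
    """
    if len(predictions) != len(omega_g):
        raise ConfigurationError("omega_g length != number of cascade outputs")
    if mode not in GAN_MODES:
        raise ConfigurationError(f"unknown gan_mode {mode!r}")

    def d_apply(cond, img):
        return discriminator(nn.concat([cond, img], axis=1))

    dt = target.data.dtype
    score_real = d_apply(condition, target)
    d_loss = Tensor(dt.type(0.0))
    g_loss = Tensor(dt.type(0.0))
    for w, pred in zip(omega_g, predictions):
        if w == 0.0:
            continue
        wt = Tensor(dt.type(w))
        fake_detached = pred.detach()
        d_term = gan_loss(mode, score_real, True) + \
            gan_loss(mode, d_apply(condition, fake_detached), False)
        if mode == "wgangp":
            pen = gradient_penalty(d_apply, condition, target, fake_detached,
                                   rng or np.random.default_rng(0))
            d_term = d_term + Tensor(dt.type(lambda_gp)) * pen
        d_loss = d_loss + wt * d_term
        g_loss = g_loss + wt * gan_loss(mode, d_apply(condition, pred), True)
    return d_loss, g_loss


class RandomFeatureExtractor(nn.Module):
    """Frozen convolutional stack defining the perceptual feature space.

    Three stride-2 convolutions (8/16/32 channels) with leaky-ReLU,
    Gaussian weights from a fixed seed.  Random frozen features define a
    valid perceptual metric: distances vanish iff the activations agree.
    An ImageNet-pretrained extractor can be substituted via the same
    interface (a callable returning a list of feature stacks).
    """

    def __init__(self, in_channels: int = 1, channels=(8, 16, 32),
                 seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.convs: List[nn.Conv2d] = []
        prev = in_channels
        for i, ch in enumerate(channels):
            conv = nn.Conv2d(prev, ch, 3, stride=2, padding=1, rng=rng)
            conv.weight.requires_grad = False
            conv.bias.requires_grad = False
            setattr(self, f"conv{i}", conv)
            self.convs.append(conv)
            prev = ch

    def forward(self, x: Tensor) -> List[Tensor]:
        feats = []
        out = x
        for conv in self.convs:
            out = nn.leaky_relu(conv(out), 0.2)
            feats.append(out)
        return feats


def perceptual_loss(extractor, predictions: Sequence[Tensor], target: Tensor,
                    mode: str = "manh", eps: float = 1e-8) -> Tensor:
    """Feature-space distance summed over cascades, layers and channels.

    ``manh``: mean absolute feature difference per channel map.
    ``cosine``: 1 − cosine similarity of the vectorised channel maps.
    """
    if mode not in ("manh", "cosine"):
        raise ConfigurationError(f"unknown perceptual mode {mode!r}")
    if not predictions:
        raise ConfigurationError("perceptual_loss needs >= 1 prediction")
    feats_t = extractor(target)
    total = Tensor(target.data.dtype.type(0.0))
    for pred in predictions:
        if pred.shape != target.shape:
            raise ValueError("prediction/target shape mismatch")
        feats_p = extractor(pred)
        for ft, fp in zip(feats_t, feats_p):
            n, c = ft.shape[0], ft.shape[1]
            if mode == "manh":
                # mean over pixels, summed over channels (and batch)
                total = total + nn.sum_(nn.mean(nn.abs_(ft - fp), axis=(2, 3)))
            else:
                a = nn.reshape(ft, (n, c, -1))
                b = nn.reshape(fp, (n, c, -1))
                dot = nn.sum_(a * b, axis=2)
                denom = nn.pow_(nn.sum_(a * a, axis=2) *
                                nn.sum_(b * b, axis=2), 0.5)
                if eps == 0.0 and np.any(denom.data == 0.0):
                    raise NumericError(
                        "cosine perceptual distance undefined for an "
                        "exactly-zero feature map with eps=0")
                # eps in numerator and denominator so identical (even
                # tiny or zero) maps score cosine 1, i.e. zero loss
                cos = (dot + eps) * nn.pow_(denom + eps, -1.0)
                total = total + nn.sum_(1.0 - cos)
    return total


def translation_total_loss(l_cyc: Tensor, l_gan_a: Tensor, l_gan_b: Tensor,
                           lambda_1: float = 10.0) -> Tensor:
    """λ1·L_cyc + L_gan(G_A,D_A) + L_gan(G_B,D_B)."""
    return Tensor(l_cyc.data.dtype.type(lambda_1)) * l_cyc + l_gan_a + l_gan_b


def segmentation_total_loss(l1: Tensor, l_gan: Tensor, l_vgg: Tensor,
                            lambda_l: float = 100.0,
                            lambda_vgg: float = 1.0) -> Tensor:
    """λ_l·L1 + L_gan + λ_vgg·L_vgg."""
    dt = l1.data.dtype
    return (Tensor(dt.type(lambda_l)) * l1 + l_gan +
            Tensor(dt.type(lambda_vgg)) * l_vgg)
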