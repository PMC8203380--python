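"""Generator and discriminator builders.

Generators are U-nets (encoder/decoder with skip connections) or residual
networks, both fully convolutional with a tanh output so every
network-facing image lives in [-1, 1].  The discriminator is a
conditional patch critic: a stack of stride-2 convolutions followed by two
stride-1 head convolutions whose analytic receptive field is checked
against the requested patch size (70 px by default) at build time.

Cascade helpers compose several generators G_n ∘ … ∘ G_1 where cascade
k >= 2 refines the previous stage's predicted mask-image.  Following the
reduced-depth design, the first cascade keeps full depth (log2 of the
image size, at most 8) while cascades 2..4 use depths (2, 4, 5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from . import nn
from .nn import Tensor


class ConfigurationError(ValueError):
    """Raised for specs that cannot be built."""


REDUCED_DEPTHS = (2, 4, 5)  # cascades 2..4
MAX_FULL_DEPTH = 8


@dataclass
class GeneratorSpec:
    kind: str = "unet"  # unet | resnet
    depth: int = 3
    base_channels: int = 16
    in_channels: int = 1
    out_channels: int = 1
    norm: str = "instance"  # instance | none
    n_res_blocks: int = 3  # resnet kind only

    def __post_init__(self):
        if self.kind not in ("unet", "resnet"):
            raise ConfigurationError(f"unknown generator kind {self.kind!r}")
        if self.depth < 1:
            raise ConfigurationError("generator depth must be >= 1")


@dataclass
class DiscriminatorSpec:
    in_channels: int = 2  # condition + image
    n_layers: int = 3  # stride-2 convolutions
    base_channels: int = 32
    target_receptive_field: int = 70


def _norm(kind: str, ch: int) -> nn.Module:
    return nn.InstanceNorm2d(ch) if kind == "instance" else nn.Identity()


def _ch(base: int, level: int) -> int:
    return min(base * (2 ** level), base * 8)


class UnetGenerator(nn.Module):
    """Encoder-decoder with skip connections and tanh output."""

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        d, b = spec.depth, spec.base_channels
        self.downs: List[nn.Module] = []
        self.down_norms: List[nn.Module] = []
        in_ch = spec.in_channels
        for lv in range(d):
            out_ch = _ch(b, lv)
            conv = nn.Conv2d(in_ch, out_ch, 4, stride=2, padding=1, rng=rng)
            # no norm on the first level (raw intensities) nor on the
            # bottleneck (may be 1x1, where instance norm is degenerate)
            norm = _norm(spec.norm, out_ch) if 0 < lv < d - 1 else nn.Identity()
            setattr(self, f"down{lv}", conv)
            setattr(self, f"dnorm{lv}", norm)
            self.downs.append(conv)
            self.down_norms.append(norm)
            in_ch = out_ch
        self.ups: List[nn.Module] = []
        self.up_norms: List[nn.Module] = []
        for lv in reversed(range(d)):
            skip_ch = _ch(b, lv - 1) if lv > 0 else 0
            out_ch = _ch(b, lv - 1) if lv > 0 else b
            conv = nn.Conv2d(in_ch, out_ch, 3, stride=1, padding=1, rng=rng)
            norm = _norm(spec.norm, out_ch) if lv > 0 else nn.Identity()
            setattr(self, f"up{lv}", conv)
            setattr(self, f"unorm{lv}", norm)
            self.ups.append(conv)
            self.up_norms.append(norm)
            in_ch = out_ch + skip_ch
        self.final = nn.Conv2d(b, spec.out_channels, 3, stride=1, padding=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        d = self.spec.depth
        h, w = x.shape[2], x.shape[3]
        if h % (2 ** d) or w % (2 ** d):
            raise ConfigurationError(
                f"input size {h}x{w} not divisible by 2^depth={2 ** d}")
        skips = []
        out = x
        for lv in range(d):
            out = self.downs[lv](out)
            out = self.down_norms[lv](out)
            out = nn.leaky_relu(out, 0.2)
            skips.append(out)
        for i, lv in enumerate(reversed(range(d))):
            out = nn.upsample_nearest(out, 2)
            out = self.ups[i](out)
            out = self.up_norms[i](out)
            out = nn.relu(out)
            if lv > 0:
                out = nn.concat([out, skips[lv - 1]], axis=1)
        return nn.tanh(self.final(out))


class ResnetGenerator(nn.Module):
    """c7s1 stem, two downsampling stages, residual bottleneck, two
    upsampling stages, c7s1 head with tanh."""

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        b = spec.base_channels
        self.stem = nn.Conv2d(spec.in_channels, b, 7, stride=1, padding=3, rng=rng)
        self.stem_norm = _norm(spec.norm, b)
        self.down1 = nn.Conv2d(b, 2 * b, 3, stride=2, padding=1, rng=rng)
        self.dn1 = _norm(spec.norm, 2 * b)
        self.down2 = nn.Conv2d(2 * b, 4 * b, 3, stride=2, padding=1, rng=rng)
        self.dn2 = _norm(spec.norm, 4 * b)
        self.res_convs: List[nn.Module] = []
        for i in range(spec.n_res_blocks):
            c1 = nn.Conv2d(4 * b, 4 * b, 3, stride=1, padding=1, rng=rng)
            n1 = _norm(spec.norm, 4 * b)
            c2 = nn.Conv2d(4 * b, 4 * b, 3, stride=1, padding=1, rng=rng)
            n2 = _norm(spec.norm, 4 * b)
            setattr(self, f"res{i}a", c1)
            setattr(self, f"res{i}an", n1)
            setattr(self, f"res{i}b", c2)
            setattr(self, f"res{i}bn", n2)
            self.res_convs.append((c1, n1, c2, n2))
        self.up1 = nn.Conv2d(4 * b, 2 * b, 3, stride=1, padding=1, rng=rng)
        self.un1 = _norm(spec.norm, 2 * b)
        self.up2 = nn.Conv2d(2 * b, b, 3, stride=1, padding=1, rng=rng)
        self.un2 = _norm(spec.norm, b)
        self.head = nn.Conv2d(b, spec.out_channels, 7, stride=1, padding=3, rng=rng)

    def zero_residual_blocks(self) -> None:
        """Zero every residual-branch weight, reducing the network to its
        plain encoder-decoder path."""
        for c1, n1, c2, n2 in self.res_convs:
            for m in (c1, c2):
                m.weight.data[...] = 0.0
                m.bias.data[...] = 0.0

    def forward(self, x: Tensor) -> Tensor:
        out = nn.relu(self.stem_norm(self.stem(x)))
        out = nn.relu(self.dn1(self.down1(out)))
        out = nn.relu(self.dn2(self.down2(out)))
        for c1, n1, c2, n2 in self.res_convs:
            res = n2(c2(nn.relu(n1(c1(out)))))
            out = out + res
        out = nn.relu(self.un1(self.up1(nn.upsample_nearest(out, 2))))
        out = nn.relu(self.un2(self.up2(nn.upsample_nearest(out, 2))))
        return nn.tanh(self.head(out))


class PatchDiscriminator(nn.Module):
    """Fully convolutional conditional critic producing a 2-D score map.

    ``forward`` takes the (condition, image) pair already channel-stacked.
    Scores are raw (pre-sigmoid); the adversarial losses decide how to
    interpret them.
    """

    def __init__(self, spec: DiscriminatorSpec, rng: np.random.Generator,
                 norm: str = "instance"):
        super().__init__()
        self.spec = spec
        b = spec.in_channels
        layers = []
        self.layer_geoms = []  # (kernel, stride) for receptive-field math
        ch = spec.base_channels
        prev = spec.in_channels
        for i in range(spec.n_layers):
            layers.append(nn.Conv2d(prev, ch, 4, stride=2, padding=1, rng=rng))
            if i > 0:
                layers.append(_norm(norm, ch))
            layers.append(nn.LeakyReLU(0.2))
            self.layer_geoms.append((4, 2))
            prev = ch
            ch = min(ch * 2, spec.base_channels * 8)
        layers.append(nn.Conv2d(prev, ch, 4, stride=1, padding=1, rng=rng))
        layers.append(_norm(norm, ch))
        layers.append(nn.LeakyReLU(0.2))
        self.layer_geoms.append((4, 1))
        layers.append(nn.Conv2d(ch, 1, 4, stride=1, padding=1, rng=rng))
        self.layer_geoms.append((4, 1))
        self.net = nn.Sequential(*layers)
        rf = receptive_field(self.layer_geoms)
        if rf != spec.target_receptive_field:
            raise ConfigurationError(
                f"receptive field {rf} != requested "
                f"{spec.target_receptive_field}; adjust n_layers")

    def forward(self, x: Tensor) -> Tensor:
        score = self.net(x)
        # (N,1,h,w) -> (N,h,w)
        return nn.reshape(score, (score.shape[0],) + score.shape[2:])


def receptive_field(layer_geoms: Sequence) -> int:
    """Analytic receptive field via r <- r + (k-1)*jump; jump <- jump*s."""
    r, j = 1, 1
    for k, s in layer_geoms:
        r += (k - 1) * j
        j *= s
    return r


def score_map_shape(input_hw, layer_geoms: Sequence, padding: int = 1):
    """Spatial score-map size by convolution shape arithmetic."""
    h, w = input_hw
    for k, s in layer_geoms:
        h = (h + 2 * padding - k) // s + 1
        w = (w + 2 * padding - k) // s + 1
    return h, w


def build_generator(spec: GeneratorSpec, seed: int = 0) -> nn.Module:
    rng = np.random.default_rng(seed)
    if spec.kind == "unet":
        return UnetGenerator(spec, rng)
    return ResnetGenerator(spec, rng)


def build_unet_generator(spec: GeneratorSpec, seed: int = 0) -> UnetGenerator:
    if spec.kind != "unet":
        raise ConfigurationError("spec.kind must be 'unet'")
    return UnetGenerator(spec, np.random.default_rng(seed))


def build_resnet_generator(spec: GeneratorSpec, seed: int = 0) -> ResnetGenerator:
    if spec.kind != "resnet":
        raise ConfigurationError("spec.kind must be 'resnet'")
    return ResnetGenerator(spec, np.random.default_rng(seed))


def build_patch_discriminator(spec: DiscriminatorSpec, seed: int = 0,
                              norm: str = "instance") -> PatchDiscriminator:
    return PatchDiscriminator(spec, np.random.default_rng(seed), norm=norm)


def full_depth_for_size(image_size: int) -> int:
    return min(MAX_FULL_DEPTH, int(math.log2(image_size)))


def build_simplified_unet_cascade(n_cascades: int, image_size: int,
                                  base_channels: int = 16,
                                  recondition: bool = False) -> List[GeneratorSpec]:
    """Specs for a cascade of U-net generators.

    The first cascade keeps full depth (log2(image_size), capped at 8);
    later cascades use the reduced depths (2, 4, 5).  With
    ``recondition`` the source image is re-stacked as an extra input
    channel for cascades >= 2.
    """
    if not 1 <= n_cascades <= 4:
        raise ConfigurationError("n_cascades must be in [1, 4]")
    if image_size < 4 or image_size & (image_size - 1):
        raise ConfigurationError("image_size must be a power of two >= 4")
    depths = [full_depth_for_size(image_size)] + list(REDUCED_DEPTHS[:n_cascades - 1])
    specs = []
    for k, d in enumerate(depths):
        in_ch = 1 if (k == 0 or not recondition) else 2
        specs.append(GeneratorSpec(kind="unet", depth=d,
                                   base_channels=base_channels,
                                   in_channels=in_ch, out_channels=1))
    return specs


def cascade_forward(generators: Sequence[nn.Module], x: Tensor,
                    condition: Optional[Tensor] = None) -> List[Tensor]:
    """Apply G_k successively: returns [I_S^1, ..., I_S^n].

    If ``condition`` is given, cascades whose spec asks for two input
    channels receive it stacked alongside the running prediction.
    """
    if not generators:
        raise ConfigurationError("cascade needs at least one generator")
    outs: List[Tensor] = []
    cur = x
    for k, g in enumerate(generators):
        inp = cur
        spec = getattr(g, "spec", None)
        if k > 0 and spec is not None and spec.in_channels == 2:
            if condition is None:
                raise ConfigurationError("reconditioned cascade needs the source image")
            inp = nn.concat([cur, condition], axis=1)
        cur = g(inp)
        outs.append(cur)
    return outs
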