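"""Synthetic multimodal cardiac phantoms.

Each phantom is a short-axis-like 2-D slice: a left-ventricular blood
pool (LV, label 1) disk strictly enclosed by a myocardial annulus (MYO,
label 2), with a right-ventricular crescent (RV, label 3) attached to
the outside of the annulus; everything else is background (label 0).

The same anatomy is rendered in two modalities:

* ``image_B`` — high contrast ("bSSFP-like"): class mean intensities are
  pairwise separated by more than 3 sigma of the additive noise, so
  boundaries are crisp.
* ``image_A`` — low contrast ("LGE-like"): foreground class means sit
  close together (separations on the order of the noise sigma), and with
  some probability a bright "scar" patch perturbs the myocardium —
  emulating late-gadolinium enhancement.  Scars perturb only this
  modality.

Geometry is sampled in continuous coordinates and rasterised by
pixel-centre membership (no anti-aliasing), so masks are crisp integer
label maps.  Every output is a pure function of (params, seed).

All images live in the canonical intensity range [-1, 1].
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np

BACKGROUND, LV, MYO, RV = 0, 1, 2, 3
LABELS = (BACKGROUND, LV, MYO, RV)
CANONICAL_RANGE = (-1.0, 1.0)


class PhantomConfigError(ValueError):
    pass


class PhantomDataError(ValueError):
    pass


@dataclass
class IntensityModel:
    """Per-class mean (and optional per-class sigma override) in [-1, 1]."""

    means: Dict[int, float]
    sigmas: Optional[Dict[int, float]] = None

    def mean(self, label: int) -> float:
        return self.means[label]

    def sigma(self, label: int, default: float) -> float:
        if self.sigmas and label in self.sigmas:
            return self.sigmas[label]
        return default


# Default study conditions.  Modality B (high contrast): minimum pairwise
# class-mean separation 0.55 > 3*0.08.  Modality A (low contrast):
# foreground separations 0.15-0.30, i.e. about 2-4 noise sigmas, with
# scar patches adding further myocardial heterogeneity.
DEFAULT_MODEL_B = IntensityModel(
    means={BACKGROUND: -0.75, LV: 0.65, MYO: -0.20, RV: 0.35})
DEFAULT_MODEL_A = IntensityModel(
    means={BACKGROUND: -0.55, LV: -0.05, MYO: -0.35, RV: -0.20})


@dataclass
class PhantomParams:
    image_size: int = 64
    lv_radius_range: Tuple[float, float] = (8.0, 12.0)
    myo_thickness_range: Tuple[float, float] = (3.0, 5.0)
    rv_thickness_range: Tuple[float, float] = (4.0, 7.0)
    rv_angular_extent: float = 2.1  # radians
    center_jitter: float = 4.0
    intensity_model_A: IntensityModel = field(
        default_factory=lambda: IntensityModel(dict(DEFAULT_MODEL_A.means)))
    intensity_model_B: IntensityModel = field(
        default_factory=lambda: IntensityModel(dict(DEFAULT_MODEL_B.means)))
    noise_sigma: float = 0.08
    scar_probability: float = 0.3

    def __post_init__(self):
        if self.image_size < 32:
            raise PhantomConfigError("image_size must be >= 32")
        for name in ("lv_radius_range", "myo_thickness_range",
                     "rv_thickness_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise PhantomConfigError(f"{name} must be positive and ordered")
        if self.noise_sigma < 0:
            raise PhantomConfigError("noise_sigma must be >= 0")
        if not 0.0 <= self.scar_probability <= 1.0:
            raise PhantomConfigError("scar_probability must be in [0, 1]")
        max_r = (self.lv_radius_range[1] + self.myo_thickness_range[1] +
                 self.rv_thickness_range[1] + self.center_jitter)
        if max_r >= self.image_size / 2:
            raise PhantomConfigError(
                "geometry does not fit: lv_radius + myo_thickness + "
                "rv_thickness + jitter must stay below image_size/2")
        sep = _min_separation(self.intensity_model_B)
        if sep <= 3.0 * self.noise_sigma:
            raise PhantomConfigError(
                f"modality-B class means must be separated by > 3*noise_sigma "
                f"(min separation {sep:.3f})")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def for_size(cls, image_size: int, **overrides) -> "PhantomParams":
        """Defaults with geometry scaled proportionally to the image size
        (the stock numbers are calibrated for 64 px)."""
        f = image_size / 64.0
        scaled = dict(
            image_size=image_size,
            lv_radius_range=(8.0 * f, 12.0 * f),
            myo_thickness_range=(max(2.0, 3.0 * f), max(3.0, 5.0 * f)),
            rv_thickness_range=(max(2.5, 4.0 * f), max(3.5, 7.0 * f)),
            center_jitter=4.0 * f,
        )
        scaled.update(overrides)
        return cls(**scaled)


def _min_separation(model: IntensityModel) -> float:
    ms = [model.means[c] for c in LABELS]
    return min(abs(a - b) for i, a in enumerate(ms) for b in ms[i + 1:])


@dataclass
class PhantomSample:
    mask: np.ndarray          # int labels in {0,1,2,3}
    image_A: np.ndarray       # low-contrast rendering, float32 in [-1,1]
    image_B: np.ndarray       # high-contrast rendering, float32 in [-1,1]
    seed: int
    params_digest: str
    scar: bool = False


def _rasterize(params: PhantomParams, rng: np.random.Generator) -> np.ndarray:
    n = params.image_size
    cx = n / 2.0 + rng.uniform(-params.center_jitter, params.center_jitter)
    cy = n / 2.0 + rng.uniform(-params.center_jitter, params.center_jitter)
    r_lv = rng.uniform(*params.lv_radius_range)
    t_myo = rng.uniform(*params.myo_thickness_range)
    t_rv = rng.uniform(*params.rv_thickness_range)
    theta0 = rng.uniform(0.0, 2.0 * np.pi)

    yy, xx = np.mgrid[0:n, 0:n]
    # pixel-centre coordinates
    dx = xx + 0.5 - cx
    dy = yy + 0.5 - cy
    r = np.hypot(dx, dy)
    ang = np.mod(np.arctan2(dy, dx) - theta0 + np.pi, 2.0 * np.pi) - np.pi

    mask = np.zeros((n, n), dtype=np.int16)
    mask[r <= r_lv] = LV
    mask[(r > r_lv) & (r <= r_lv + t_myo)] = MYO
    rv_zone = ((r > r_lv + t_myo) & (r <= r_lv + t_myo + t_rv) &
               (np.abs(ang) <= params.rv_angular_extent / 2.0))
    mask[rv_zone] = RV
    return mask


def render_modality(mask: np.ndarray, model: IntensityModel,
                    noise_sigma: float, seed: int) -> np.ndarray:
    """Piecewise-constant class means plus Gaussian noise, clipped to [-1, 1]."""
    if noise_sigma < 0:
        raise PhantomConfigError("noise_sigma must be >= 0")
    labels = np.unique(mask)
    unknown = set(int(v) for v in labels) - set(model.means)
    if unknown:
        raise PhantomDataError(f"unknown class ids in mask: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    img = np.zeros(mask.shape, dtype=np.float32)
    for label in sorted(model.means):
        sel = mask == label
        if not np.any(sel):
            continue
        sigma = model.sigma(int(label), noise_sigma)
        vals = model.mean(int(label)) + sigma * rng.standard_normal(int(sel.sum()))
        img[sel] = vals.astype(np.float32)
    return np.clip(img, *CANONICAL_RANGE)


def _scar_patch(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A small disk centred on a random myocardial pixel, restricted to MYO."""
    myo = np.argwhere(mask == MYO)
    if len(myo) == 0:
        return np.zeros(mask.shape, dtype=bool)
    cy, cx = myo[rng.integers(len(myo))]
    yy, xx = np.mgrid[0:mask.shape[0], 0:mask.shape[1]]
    disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= rng.uniform(2.0, 4.0) ** 2
    return disk & (mask == MYO)


def generate_phantom(params: PhantomParams, seed: int) -> PhantomSample:
    """One anatomy with both modality renderings; pure in (params, seed)."""
    master = np.random.default_rng([seed, 0x9E3779B9])
    geom_rng = np.random.default_rng(master.integers(2 ** 31))
    seed_a = int(master.integers(2 ** 31))
    seed_b = int(master.integers(2 ** 31))
    scar_rng = np.random.default_rng(master.integers(2 ** 31))

    mask = _rasterize(params, geom_rng)
    image_a = render_modality(mask, params.intensity_model_A,
                              params.noise_sigma, seed_a)
    image_b = render_modality(mask, params.intensity_model_B,
                              params.noise_sigma, seed_b)
    has_scar = bool(scar_rng.uniform() < params.scar_probability)
    if has_scar:
        patch = _scar_patch(mask, scar_rng)
        image_a[patch] = np.clip(image_a[patch] + 0.45, *CANONICAL_RANGE)
    return PhantomSample(mask=mask, image_A=image_a, image_B=image_b,
                         seed=seed, params_digest=params.digest(),
                         scar=has_scar)


@dataclass
class PhantomDataset:
    """Aligned A/B sample lists; with ``paired`` the lists are identical
    objects (same anatomy under both renderings), otherwise the two sides
    are independently drawn anatomies (the translation training regime)."""

    samples_a: List[PhantomSample]
    samples_b: List[PhantomSample]
    paired: bool
    seed: int

    def __len__(self) -> int:
        return len(self.samples_a)


def make_dataset(params: PhantomParams, n: int, seed: int,
                 paired: bool = True) -> PhantomDataset:
    if n < 1:
        raise PhantomConfigError("dataset size n must be >= 1")
    if paired:
        samples = [generate_phantom(params, seed * 1_000_003 + i)
                   for i in range(n)]
        return PhantomDataset(samples, samples, True, seed)
    sa = [generate_phantom(params, seed * 1_000_003 + i) for i in range(n)]
    sb = [generate_phantom(params, seed * 1_000_003 + 500_000 + i)
          for i in range(n)]
    return PhantomDataset(sa, sb, False, seed)


# ---------------------------------------------------------------------
# anatomy assertions (used by tests and by the CLI manifest)
# ---------------------------------------------------------------------

def lv_enclosed_by_myo(mask: np.ndarray) -> bool:
    """Every LV pixel that touches a non-LV 4-neighbour touches only MYO."""
    lv = mask == LV
    if not lv.any():
        return False
    padded = np.pad(mask, 1, constant_values=BACKGROUND)
    for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        neigh = padded[1 + dy:1 + dy + mask.shape[0],
                       1 + dx:1 + dx + mask.shape[1]]
        bad = lv & (neigh != LV) & (neigh != MYO)
        if bad.any():
            return False
    return True


def contrast_ratio(images: List[np.ndarray], masks: List[np.ndarray]) -> float:
    """Pooled between-class over within-class variance ratio."""
    pix = np.concatenate([im.ravel() for im in images])
    lab = np.concatenate([m.ravel() for m in masks])
    grand = pix.mean()
    between = 0.0
    within = 0.0
    for c in LABELS:
        sel = lab == c
        if not sel.any():
            continue
        v = pix[sel]
        between += sel.sum() * (v.mean() - grand) ** 2
        within += sel.sum() * v.var()
    return float(between / within)


# ---------------------------------------------------------------------
# fixture I/O
# ---------------------------------------------------------------------

def _to_uint8(img: np.ndarray) -> np.ndarray:
    lo, hi = CANONICAL_RANGE
    return np.round((np.clip(img, lo, hi) - lo) / (hi - lo) * 255).astype(np.uint8)


def _from_uint8(arr: np.ndarray) -> np.ndarray:
    lo, hi = CANONICAL_RANGE
    return (arr.astype(np.float32) / 255.0 * (hi - lo) + lo).astype(np.float32)


def write_sample(sample: PhantomSample, path: str, fmt: str = "png") -> None:
    """Write a sample as a directory of images plus a JSON sidecar.

    ``png`` stores 8-bit quantised images (mask as raw labels); ``nifti``
    stores lossless float32 / int16 volumes.
    """
    if fmt not in ("png", "nifti"):
        raise IOError(f"unsupported format {fmt!r} (use png or nifti)")
    os.makedirs(path, exist_ok=True)
    meta = {"seed": sample.seed, "params_digest": sample.params_digest,
            "format": fmt, "scar": sample.scar}
    with open(os.path.join(path, "meta.json"), "w") as fh:
        json.dump(meta, fh)
    if fmt == "png":
        from PIL import Image
        Image.fromarray(sample.mask.astype(np.uint8), mode="L").save(
            os.path.join(path, "mask.png"))
        Image.fromarray(_to_uint8(sample.image_A), mode="L").save(
            os.path.join(path, "image_A.png"))
        Image.fromarray(_to_uint8(sample.image_B), mode="L").save(
            os.path.join(path, "image_B.png"))
    else:
        import nibabel as nib
        aff = np.eye(4)
        nib.save(nib.Nifti1Image(sample.mask.astype(np.int16), aff),
                 os.path.join(path, "mask.nii.gz"))
        nib.save(nib.Nifti1Image(sample.image_A.astype(np.float32), aff),
                 os.path.join(path, "image_A.nii.gz"))
        nib.save(nib.Nifti1Image(sample.image_B.astype(np.float32), aff),
                 os.path.join(path, "image_B.nii.gz"))


def read_sample(path: str) -> PhantomSample:
    meta_path = os.path.join(path, "meta.json")
    try:
        with open(meta_path) as fh:
            meta = json.load(fh)
    except (OSError, json.JSONDecodeError) as e:
        raise IOError(f"cannot read sample metadata at {meta_path}: {e}") from e
    fmt = meta.get("format")
    try:
        if fmt == "png":
            from PIL import Image
            mask = np.asarray(Image.open(os.path.join(path, "mask.png"))).astype(np.int16)
            img_a = _from_uint8(np.asarray(Image.open(os.path.join(path, "image_A.png"))))
            img_b = _from_uint8(np.asarray(Image.open(os.path.join(path, "image_B.png"))))
        elif fmt == "nifti":
            import nibabel as nib
            mask = np.asanyarray(nib.load(os.path.join(path, "mask.nii.gz")).dataobj).astype(np.int16)
            img_a = np.asanyarray(nib.load(os.path.join(path, "image_A.nii.gz")).dataobj).astype(np.float32)
            img_b = np.asanyarray(nib.load(os.path.join(path, "image_B.nii.gz")).dataobj).astype(np.float32)
        else:
            raise IOError(f"unsupported format {fmt!r} in {meta_path}")
    except IOError:
        raise
    except Exception as e:
        raise IOError(f"corrupt {fmt} sample at {path}: {e}") from e
    return PhantomSample(mask=mask, image_A=img_a, image_B=img_b,
                         seed=int(meta.get("seed", -1)),
                         params_digest=str(meta.get("params_digest", "")),
                         scar=bool(meta.get("scar", False)))
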