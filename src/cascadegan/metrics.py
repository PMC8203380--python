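"""Evaluation metrics: Dice overlap, SSIM, PSNR, histogram mutual information.

SSIM and PSNR delegate to scikit-image (11x11 Gaussian window, K1=0.01,
K2=0.03 for SSIM).  The canonical image range is [-1, 1], so the declared
dynamic range / peak is 2.0 unless stated otherwise.  PSNR of identical
images is reported as the 99 dB cap.  Mutual information uses a joint
intensity histogram (32 bins by default) in natural-log units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
from skimage.metrics import peak_signal_noise_ratio, structural_similarity

PSNR_CAP_DB = 99.0
DEFAULT_MI_BINS = 32
DEFAULT_DATA_RANGE = 2.0  # canonical [-1, 1]


@dataclass
class MetricReport:
    name: str
    per_sample: List[float]

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_sample))

    @property
    def sd(self) -> float:
        return float(np.std(self.per_sample, ddof=0))

    def __str__(self) -> str:
        return f"{self.name}: {self.mean:.4f} ± {self.sd:.4f}"


def dice(pred: np.ndarray, truth: np.ndarray, class_id: int) -> float:
    """2|P∩T| / (|P|+|T|); empty-empty -> 1, empty-vs-nonempty -> 0."""
    if pred.shape != truth.shape:
        raise ValueError("dice: shape mismatch")
    p = pred == class_id
    t = truth == class_id
    denom = int(p.sum()) + int(t.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & t).sum()) / denom


def dice_table(preds: Sequence[np.ndarray], truths: Sequence[np.ndarray],
               class_ids=(1, 2, 3),
               class_names=("LV", "MYO", "RV")) -> Dict[str, MetricReport]:
    """Per-class Dice over a dataset, reported mean ± sd."""
    if len(preds) == 0:
        raise ValueError("dice_table: empty dataset")
    out = {}
    for cid, name in zip(class_ids, class_names):
        out[name] = MetricReport(
            name, [dice(p, t, cid) for p, t in zip(preds, truths)])
    return out


def ssim(a: np.ndarray, b: np.ndarray,
         data_range: float = DEFAULT_DATA_RANGE) -> float:
    if a.shape != b.shape:
        raise ValueError("ssim: shape mismatch")
    if min(a.shape) < 11:
        raise ValueError("ssim: image smaller than the 11x11 window")
    return float(structural_similarity(
        a.astype(np.float64), b.astype(np.float64),
        data_range=data_range, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, K1=0.01, K2=0.03))


def psnr(a: np.ndarray, b: np.ndarray,
         peak: float = DEFAULT_DATA_RANGE) -> float:
    if a.shape != b.shape:
        raise ValueError("psnr: shape mismatch")
    if np.array_equal(a, b):
        return PSNR_CAP_DB
    val = float(peak_signal_noise_ratio(
        a.astype(np.float64), b.astype(np.float64), data_range=peak))
    return min(val, PSNR_CAP_DB)


def mutual_information(a: np.ndarray, b: np.ndarray,
                       bins: int = DEFAULT_MI_BINS) -> float:
    """MI of the joint intensity histogram, in nats.

    Degenerate single-valued images carry no information: returns 0.
    """
    if a.shape != b.shape:
        raise ValueError("mutual_information: shape mismatch")
    if bins < 2:
        raise ValueError("mutual_information: bins must be >= 2")
    av, bv = a.ravel(), b.ravel()
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        return 0.0
    joint, _, _ = np.histogram2d(av, bv, bins=bins)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    nz = pxy > 0
    outer = np.outer(px, py)
    return float(np.sum(pxy[nz] * np.log(pxy[nz] / outer[nz])))


def histogram_entropy(a: np.ndarray, bins: int = DEFAULT_MI_BINS) -> float:
    """Shannon entropy (nats) of the intensity histogram of ``a``."""
    counts, _ = np.histogram(a.ravel(), bins=bins)
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))
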