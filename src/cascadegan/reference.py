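"""Slow, literal transcriptions of every loss, used as test oracles.

Everything here operates on plain numpy arrays with explicit Python
loops over pixels/channels/cascades — no vectorisation, no shared code
with :mod:`cascadegan.losses` beyond numpy itself.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np


def gan_loss_ref(mode: str, score_map: np.ndarray, target_is_real: bool) -> float:
    vals = []
    for s in np.asarray(score_map, dtype=np.float64).ravel():
        if mode == "vanilla":
            p = 1.0 / (1.0 + math.exp(-s))
            vals.append(-math.log(p) if target_is_real else -math.log(1.0 - p))
        elif mode == "lsgan":
            t = 1.0 if target_is_real else 0.0
            vals.append((s - t) ** 2)
        elif mode == "wgangp":
            vals.append(-s if target_is_real else s)
        else:
            raise ValueError(mode)
    return sum(vals) / len(vals)


def cycle_loss_ref(x, x_rt, y, y_rt) -> float:
    def mae(a, b):
        a = np.asarray(a, dtype=np.float64).ravel()
        b = np.asarray(b, dtype=np.float64).ravel()
        return sum(abs(u - v) for u, v in zip(a, b)) / len(a)

    return mae(x, x_rt) + mae(y, y_rt)


def cascade_l1_loss_ref(predictions: Sequence[np.ndarray], target: np.ndarray,
                        omega_1: Sequence[float]) -> float:
    total = 0.0
    t = np.asarray(target, dtype=np.float64).ravel()
    for w, pred in zip(omega_1, predictions):
        p = np.asarray(pred, dtype=np.float64).ravel()
        total += w * sum(abs(u - v) for u, v in zip(t, p)) / len(t)
    return total


def cascade_adversarial_losses_ref(d_fn, condition: np.ndarray,
                                   target: np.ndarray,
                                   predictions: Sequence[np.ndarray],
                                   omega_g: Sequence[float],
                                   mode: str) -> tuple:
    """d_fn(condition, image) -> numpy score map (pure function)."""
    score_real = d_fn(condition, target)
    d_loss = 0.0
    g_loss = 0.0
    for w, pred in zip(omega_g, predictions):
        if w == 0.0:
            continue
        score_fake = d_fn(condition, pred)
        d_loss += w * (gan_loss_ref(mode, score_real, True) +
                       gan_loss_ref(mode, score_fake, False))
        g_loss += w * gan_loss_ref(mode, score_fake, True)
    return d_loss, g_loss


def perceptual_loss_ref(extract_fn, predictions: Sequence[np.ndarray],
                        target: np.ndarray, mode: str,
                        eps: float = 1e-8) -> float:
    """extract_fn(image) -> list of (N, C_i, h_i, w_i) numpy feature maps."""
    feats_t = extract_fn(target)
    total = 0.0
    for pred in predictions:
        feats_p = extract_fn(pred)
        for ft, fp in zip(feats_t, feats_p):
            n, c, h, w = ft.shape
            for b in range(n):
                for j in range(c):
                    if mode == "manh":
                        acc = 0.0
                        for p in range(h):
                            for q in range(w):
                                acc += abs(float(ft[b, j, p, q]) -
                                           float(fp[b, j, p, q]))
                        total += acc / (h * w)
                    elif mode == "cosine":
                        xv = [float(v) for v in ft[b, j].ravel()]
                        yv = [float(v) for v in fp[b, j].ravel()]
                        dot = sum(u * v for u, v in zip(xv, yv))
                        nx = math.sqrt(sum(u * u for u in xv))
                        ny = math.sqrt(sum(v * v for v in yv))
                        total += 1.0 - (dot + eps) / (nx * ny + eps)
                    else:
                        raise ValueError(mode)
    return total


def gradient_penalty_ref(d_fn, condition: np.ndarray,
                         x_hat: np.ndarray, eps_fd: float = 1e-3) -> float:
    """Central finite-difference gradient of sum(d_fn) w.r.t. x_hat."""
    g = np.zeros_like(x_hat, dtype=np.float64)
    it = np.nditer(x_hat, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        xp = x_hat.copy()
        xp[idx] += eps_fd
        xm = x_hat.copy()
        xm[idx] -= eps_fd
        g[idx] = (float(np.sum(d_fn(condition, xp))) -
                  float(np.sum(d_fn(condition, xm)))) / (2 * eps_fd)
    pens = []
    for b in range(x_hat.shape[0]):
        norm = math.sqrt(sum(v * v for v in g[b].ravel()))
        pens.append((norm - 1.0) ** 2)
    return sum(pens) / len(pens)


def translation_total_loss_ref(l_cyc, l_gan_a, l_gan_b, lambda_1=10.0) -> float:
    return lambda_1 * l_cyc + l_gan_a + l_gan_b


def segmentation_total_loss_ref(l1, l_gan, l_vgg, lambda_l=100.0,
                                lambda_vgg=1.0) -> float:
    return lambda_l * l1 + l_gan + lambda_vgg * l_vgg
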