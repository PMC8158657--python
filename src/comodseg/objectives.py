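"""Training loss: soft Dice + hard-pixel-weighted BCE deep supervision.

The total is ``l_total = alpha * l_sg + (1 - alpha) * l_deep`` with alpha 0.7.
``l_sg`` is soft Dice over the three region channels; ``l_deep`` sums a
weighted BCE term over the (upsampled) global map and the three side-output
maps. The BCE weight emphasizes voxels near region boundaries:
``w = 1 + lambda_w * |meanpool_k(G) - G|`` with the window scaled to grid size.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from . import autograd as ag
from .autograd import Tensor

DICE_EPS = 1.0
LAMBDA_W = 5.0
ALPHA = 0.7


def _as5d(t):
    """Promote (C, D, H, W) to (1, C, D, H, W)."""
    if t.ndim == 4:
        if isinstance(t, Tensor):
            return ag.reshape(t, (1,) + t.shape)
        return t[None]
    if t.ndim != 5:
        raise ValueError(f"expected 4D or 5D input, got {t.ndim}D")
    return t


def dice_loss(prediction: Tensor, target: np.ndarray, eps: float = DICE_EPS) -> Tensor:
    """Soft Dice loss, per region channel, averaged over channels and batch."""
    prediction = _as5d(ag.as_tensor(prediction))
    target = _as5d(np.asarray(target, dtype=np.float64))
    if prediction.shape != target.shape:
        raise ValueError(f"shape mismatch: {prediction.shape} vs {target.shape}")
    axes = (2, 3, 4)
    tgt = ag.Tensor(target)
    inter = (prediction * tgt).sum(axis=axes)
    sizes = prediction.sum(axis=axes) + tgt.sum(axis=axes)
    dice = (2.0 * inter + eps) / (sizes + eps)
    return (1.0 - dice).mean()


def bce_weights(target: np.ndarray, lambda_w: float = LAMBDA_W,
                window: int | None = None) -> np.ndarray:
    """Per-voxel weights 1 + lambda_w * |meanpool_k(G) - G| (no gradient)."""
    target = _as5d(np.asarray(target, dtype=np.float64))
    if window is None:
        m = min(target.shape[2:])
        window = max(3, int(round(31.0 * m / 128.0)) | 1)
    pooled = np.empty_like(target)
    for n in range(target.shape[0]):
        for c in range(target.shape[1]):
            pooled[n, c] = ndimage.uniform_filter(target[n, c], size=window,
                                                  mode="nearest")
    return 1.0 + lambda_w * np.abs(pooled - target)


def weighted_bce(logit_map: Tensor, target_map: np.ndarray,
                 lambda_w: float = LAMBDA_W, window: int | None = None) -> Tensor:
    """Weight-normalized BCE with logits, averaged over region channels."""
    logits = _as5d(ag.as_tensor(logit_map))
    target = _as5d(np.asarray(target_map, dtype=np.float64))
    if logits.shape != target.shape:
        raise ValueError(f"shape mismatch: {logits.shape} vs {target.shape}")
    w = bce_weights(target, lambda_w=lambda_w, window=window)
    # per-voxel BCE with logits: softplus(x) - g*x  (stable form)
    pointwise = ag.softplus(logits) - logits * ag.Tensor(target)
    axes = (2, 3, 4)
    wt = ag.Tensor(w)
    num = (wt * pointwise).sum(axis=axes)
    den = w.sum(axis=(2, 3, 4))
    return (num * ag.Tensor(1.0 / den)).mean()


def upsample_to(map_tensor: Tensor, spatial_shape: tuple) -> Tensor:
    """Repeated trilinear x2 upsampling until the map matches spatial_shape."""
    t = _as5d(ag.as_tensor(map_tensor))
    while t.shape[2:] != tuple(spatial_shape):
        if t.shape[2] > spatial_shape[0]:
            raise ValueError(f"map {t.shape[2:]} larger than target {spatial_shape}")
        t = ag.upsample2x(t)
    return t


def deep_supervision_loss(m_g: Tensor, m3: Tensor, m4: Tensor, m5: Tensor,
                          target: np.ndarray, lambda_w: float = LAMBDA_W) -> Tensor:
    """Sum of weighted BCE of the global and three side maps, upsampled to G."""
    target = _as5d(np.asarray(target, dtype=np.float64))
    full = target.shape[2:]
    total = None
    for m in (m_g, m3, m4, m5):
        if m is None:
            raise ValueError("deep supervision requires all four maps")
        term = weighted_bce(upsample_to(m, full), target, lambda_w=lambda_w)
        total = term if total is None else total + term
    return total


@dataclasses.dataclass
class LossBreakdown:
    """Scalar components of one batch's loss (``total`` keeps the graph)."""

    l_sg: float
    l_deep: float
    l_total: float
    per_map: dict
    alpha: float
    total: Tensor | None = None

    def to_record(self):
        rec = {"l_sg": self.l_sg, "l_deep": self.l_deep, "l_total": self.l_total,
               "alpha": self.alpha}
        rec.update({f"l_sd_{k}": v for k, v in self.per_map.items()})
        return rec


def total_loss(prediction: Tensor, maps: dict, y: np.ndarray,
               g: np.ndarray | None = None, alpha: float = ALPHA,
               lambda_w: float = LAMBDA_W) -> LossBreakdown:
    """alpha-weighted combination of Dice loss and deep supervision.

    ``maps`` holds the logit maps under keys ``m_g, m3, m4, m5``; ``y`` is the
    3-channel region target for the Dice term and ``g`` (default: ``y``) the
    target for the saliency terms.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    g = y if g is None else g
    g5 = _as5d(np.asarray(g, dtype=np.float64))
    full = g5.shape[2:]
    l_sg = dice_loss(prediction, y)
    per_map = {}
    l_deep = None
    for key in ("m_g", "m3", "m4", "m5"):
        term = weighted_bce(upsample_to(maps[key], full), g5, lambda_w=lambda_w)
        per_map[key] = term.item()
        l_deep = term if l_deep is None else l_deep + term
    total = l_sg * alpha + l_deep * (1.0 - alpha)
    return LossBreakdown(l_sg=l_sg.item(), l_deep=l_deep.item(),
                         l_total=total.item(), per_map=per_map, alpha=alpha,
                         total=total)
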