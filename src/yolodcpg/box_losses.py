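"""Bounding-box regression losses: IoU, Wise-IoU v1/v3 and Inner-WIoU.

Boxes are axis-aligned in **center form** ``(cx, cy, w, h)``; all functions
are vectorised over a leading batch dimension (shape ``(..., 4)``) and accept
either NumPy arrays or autograd :class:`~yolodcpg.autograd.Tensor` objects.
When every input is a plain array the result is returned as a plain array
(or Python float for scalars); pass Tensors to obtain gradients.

The loss chain
--------------

* ``iou`` — intersection over union of the two boxes.
* ``wiou_distance_penalty`` — ``exp(d^2 / D)`` where ``d`` is the distance
  between box centers and ``D`` is an enclosing-box normaliser, treated as a
  constant (no gradient) as in the original Wise-IoU construction.  ``D`` is
  ``Wg^2 + Hg^2`` by default; ``(Wg + Hg)^2`` is available via
  ``denominator_mode="squared_sum"``.
* ``wiou_v1`` — distance penalty times ``1 - IoU``.
* ``wiou_v3`` — v1 scaled by the non-monotonic focusing coefficient
  ``r = beta / (delta * alpha^(beta - delta))`` with outlierness
  ``beta = L*_IoU / mean(L_IoU)``, the running mean being tracked by
  :class:`WIoUState` (momentum EMA, excluded from gradients).
* ``inner_iou`` — IoU of auxiliary boxes scaled about their centers by a
  ``ratio`` in [0.5, 1.5]; ``ratio < 1`` sharpens gradients for high-IoU
  pairs, ``ratio > 1`` widens the effective regression range.
* ``inner_wiou_loss`` — ``L_WIoUv3 + IoU - InnerIoU``; the combined loss
  used for dense small-target regression (``ratio = 1.05`` recommended).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, astensor, where

__all__ = [
    "WIoUConfig", "WIoUState", "iou", "make_inner_box", "inner_iou",
    "wiou_distance_penalty", "wiou_v1", "wiou_v3", "inner_wiou_loss",
    "box_loss", "DEFAULT_RATIO", "DENSE_SMALL_TARGET_RATIO",
]

#: library default auxiliary-box scale
DEFAULT_RATIO = 0.7
#: recommended scale for scenes dominated by small, dense targets
DENSE_SMALL_TARGET_RATIO = 1.05


@dataclass
class WIoUConfig:
    """Hyper-parameters of the WIoU v3 / Inner-WIoU loss family."""

    alpha: float = 1.9
    delta: float = 3.0
    ratio: float = DEFAULT_RATIO
    momentum: float = 0.01
    denominator_mode: str = "sum_squared"

    def __post_init__(self):
        if not self.alpha > 1:
            raise ValueError("alpha must be > 1")
        if not self.delta > 0:
            raise ValueError("delta must be > 0")
        if not 0.5 <= self.ratio <= 1.5:
            raise ValueError("ratio must lie in [0.5, 1.5]")
        if not 0 < self.momentum <= 1:
            raise ValueError("momentum must lie in (0, 1]")
        if self.denominator_mode not in ("sum_squared", "squared_sum"):
            raise ValueError("denominator_mode must be 'sum_squared' or 'squared_sum'")


@dataclass
class WIoUState:
    """Running mean of the IoU loss used by the v3 focusing mechanism.

    The mean is updated once per batch by an exponential moving average and
    is never part of the gradient graph.
    """

    running_mean_liou: float = 0.0
    initialized: bool = False

    def update(self, batch_mean_liou: float, momentum: float):
        if not self.initialized:
            self.running_mean_liou = float(batch_mean_liou)
            self.initialized = True
        else:
            self.running_mean_liou += momentum * (float(batch_mean_liou) - self.running_mean_liou)
        self.running_mean_liou = max(self.running_mean_liou, 0.0)


def _wrap(*boxes):
    tensors = [astensor(b) for b in boxes]
    keep = any(isinstance(b, Tensor) for b in boxes)
    return tensors, keep


def _unwrap(t: Tensor, keep: bool):
    if keep:
        return t
    return t.item() if t.data.ndim == 0 else t.data


def _split(b: Tensor):
    return b[..., 0], b[..., 1], b[..., 2], b[..., 3]


def _corner_iou(l1, r1, t1, b1, l2, r2, t2, b2, a1, a2):
    zero = Tensor(np.zeros(np.broadcast_shapes(l1.shape, l2.shape)))
    iw = (r1.minimum(r2) - l1.maximum(l2)).maximum(zero)
    ih = (b1.minimum(b2) - t1.maximum(t2)).maximum(zero)
    inter = iw * ih
    union = a1 + a2 - inter
    if np.any(union.data <= 0):
        warnings.warn("zero-area union encountered; IoU defined as 0 for those pairs")
    safe = where(union.data > 0, union, Tensor(np.ones_like(union.data)))
    val = where(union.data > 0, inter / safe, Tensor(np.zeros_like(union.data)))
    return val.clip(0.0, 1.0)  # guard against fp round-off just above 1


def iou(pred, gt):
    """IoU of two center-form boxes; 0 for a zero-area union (with warning)."""
    (p, g), keep = _wrap(pred, gt)
    pcx, pcy, pw, ph = _split(p)
    gcx, gcy, gw, gh = _split(g)
    val = _corner_iou(pcx - pw * 0.5, pcx + pw * 0.5, pcy - ph * 0.5, pcy + ph * 0.5,
                      gcx - gw * 0.5, gcx + gw * 0.5, gcy - gh * 0.5, gcy + gh * 0.5,
                      pw * ph, gw * gh)
    return _unwrap(val, keep)


def make_inner_box(b, ratio: float):
    """Corner-form ``(l, r, t, b)`` of the box scaled by `ratio` about its center."""
    if not 0.5 <= ratio <= 1.5:
        raise ValueError("ratio must lie in [0.5, 1.5]")
    (bt,), keep = _wrap(b)
    cx, cy, w, h = _split(bt)
    half_w, half_h = w * (ratio / 2.0), h * (ratio / 2.0)
    from .autograd import stack
    out = stack([cx - half_w, cx + half_w, cy - half_h, cy + half_h], axis=-1)
    return _unwrap(out, keep)


def inner_iou(pred, gt, ratio: float):
    """IoU of the two ratio-scaled auxiliary boxes (axis overlaps clamped at 0)."""
    if not 0.5 <= ratio <= 1.5:
        raise ValueError("ratio must lie in [0.5, 1.5]")
    (p, g), keep = _wrap(pred, gt)
    pcx, pcy, pw, ph = _split(p)
    gcx, gcy, gw, gh = _split(g)
    r2 = ratio / 2.0
    val = _corner_iou(pcx - pw * r2, pcx + pw * r2, pcy - ph * r2, pcy + ph * r2,
                      gcx - gw * r2, gcx + gw * r2, gcy - gh * r2, gcy + gh * r2,
                      pw * ph * ratio ** 2, gw * gh * ratio ** 2)
    return _unwrap(val, keep)


def wiou_distance_penalty(pred, gt, mode: str = "sum_squared"):
    """``exp(center_distance^2 / D)`` with the enclosing-box normaliser detached.

    ``D = Wg^2 + Hg^2`` (``sum_squared``, default) or ``(Wg + Hg)^2``
    (``squared_sum``); returns 1 when ``D`` vanishes (coincident point boxes).
    """
    if mode not in ("sum_squared", "squared_sum"):
        raise ValueError(mode)
    (p, g), keep = _wrap(pred, gt)
    pcx, pcy, pw, ph = _split(p)
    gcx, gcy, gw, gh = _split(g)
    wg = (pcx + pw * 0.5).maximum(gcx + gw * 0.5) - (pcx - pw * 0.5).minimum(gcx - gw * 0.5)
    hg = (pcy + ph * 0.5).maximum(gcy + gh * 0.5) - (pcy - ph * 0.5).minimum(gcy - gh * 0.5)
    d2 = (pcx - gcx) ** 2 + (pcy - gcy) ** 2
    denom = (wg ** 2 + hg ** 2) if mode == "sum_squared" else (wg + hg) ** 2
    denom = denom.detach()  # constant within each step, as in the WIoU paper
    ok = denom.data > 0
    safe = where(ok, denom, Tensor(np.ones_like(denom.data)))
    val = where(ok, (d2 / safe).exp(), Tensor(np.ones_like(denom.data)))
    return _unwrap(val, keep)


def wiou_v1(pred, gt, cfg: WIoUConfig | None = None):
    """WIoU v1: distance penalty times the IoU loss ``1 - IoU``."""
    cfg = cfg or WIoUConfig()
    (p, g), keep = _wrap(pred, gt)
    val = wiou_distance_penalty(p, g, cfg.denominator_mode) * (1.0 - astensor(iou(p, g)))
    return _unwrap(val, keep)


def _focus_coefficient(liou_detached: np.ndarray, cfg: WIoUConfig, state: WIoUState) -> np.ndarray:
    mean = state.running_mean_liou if state.initialized else float(np.mean(liou_detached))
    mean = max(mean, 1e-12)
    beta = liou_detached / mean
    return beta / (cfg.delta * cfg.alpha ** (beta - cfg.delta))


def wiou_v3(pred, gt, cfg: WIoUConfig | None = None, state: WIoUState | None = None):
    """WIoU v3 focusing loss; returns ``(loss, state)``.

    Per-box: ``r * L_WIoUv1`` with ``r`` from the detached outlierness
    ``beta``; the batch loss is the mean of per-box losses and the state's
    running mean is advanced once by the batch-mean IoU loss.
    """
    cfg = cfg or WIoUConfig()
    state = state if state is not None else WIoUState()
    (p, g), keep = _wrap(pred, gt)
    liou = 1.0 - astensor(iou(p, g))
    r = _focus_coefficient(np.asarray(liou.data), cfg, state)
    per_box = Tensor(r) * wiou_distance_penalty(p, g, cfg.denominator_mode) * liou
    state.update(float(np.mean(liou.data)), cfg.momentum)
    loss = per_box.mean() if per_box.data.ndim else per_box
    return _unwrap(loss, keep), state


def inner_wiou_loss(pred, gt, cfg: WIoUConfig | None = None, state: WIoUState | None = None):
    """Inner-WIoU: ``L_WIoUv3 + IoU - InnerIoU(ratio)``; returns ``(loss, state)``.

    With ``ratio = 1`` the correction term vanishes and the loss equals WIoU
    v3 exactly; the loss is zero when prediction and target coincide.
    """
    cfg = cfg or WIoUConfig()
    state = state if state is not None else WIoUState()
    (p, g), keep = _wrap(pred, gt)
    liou = 1.0 - astensor(iou(p, g))
    r = _focus_coefficient(np.asarray(liou.data), cfg, state)
    v3 = Tensor(r) * wiou_distance_penalty(p, g, cfg.denominator_mode) * liou
    per_box = v3 + astensor(iou(p, g)) - astensor(inner_iou(p, g, cfg.ratio))
    state.update(float(np.mean(liou.data)), cfg.momentum)
    loss = per_box.mean() if per_box.data.ndim else per_box
    return _unwrap(loss, keep), state


_LOSSES = {"iou", "wiou_v1", "wiou_v3", "inner_wiou"}


def box_loss(name: str, pred, gt, cfg: WIoUConfig | None = None,
             state: WIoUState | None = None):
    """Select a regression loss by config string; returns ``(loss, state)``.

    ``name`` is one of ``iou`` (plain ``1 - IoU``), ``wiou_v1``, ``wiou_v3``
    or ``inner_wiou``.
    """
    if name not in _LOSSES:
        raise ValueError(f"unknown loss '{name}'; choose from {sorted(_LOSSES)}")
    cfg = cfg or WIoUConfig()
    state = state if state is not None else WIoUState()
    if name == "iou":
        (p, g), keep = _wrap(pred, gt)
        val = 1.0 - astensor(iou(p, g))
        loss = val.mean() if val.data.ndim else val
        return _unwrap(loss, keep), state
    if name == "wiou_v1":
        (p, g), keep = _wrap(pred, gt)
        val = astensor(wiou_v1(p, g, cfg))
        loss = val.mean() if val.data.ndim else val
        return _unwrap(loss, keep), state
    if name == "wiou_v3":
        return wiou_v3(pred, gt, cfg, state)
    return inner_wiou_loss(pred, gt, cfg, state)
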