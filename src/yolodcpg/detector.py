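"""Detector assembly, profiling, decoding/NMS, evaluation and toy training.

``build_model`` assembles a backbone (StarNet or the reference YOLOv8n
CSP backbone), an optional DCPGAttention instance at the backbone end, a
neck (Small-Neck or the retained YOLOv8 PAN) and the retained anchor-free
YOLOv8 detection head (distribution focal regression + per-class logits).

Presets
-------
``yolov8n``            the reference baseline (3.02 M params, ~8.1 GFLOPs @640)
``yolov8n-starnet``    StarNet-S100 backbone, retained PAN neck (2.39 M)
``yolov8n-smallneck``  reference backbone, Small-Neck (1.88 M)
``yolo-dcpg``          StarNet-S100 + DCPGAttention + Small-Neck (1.47 M, ~5.6 G)
``yolo-dcpg-noattn``   as above without the attention module
``toy``                a scaled-down configuration for CPU training demos

GFLOPs follow the fused-model convention: 2 x convolution
multiply-accumulates; normalisation, activations, pooling and resampling
are free.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .autograd import Tensor, astensor, concat, no_grad, softmax
from .box_losses import WIoUConfig, WIoUState, box_loss, iou
from .dcpg_attention import DCPGAttention
from .nn import (Conv2d, MaxPool2d, Module, SGD, Sequential, count_macs,
                 parameter)
from .small_neck import ConvBNAct, NeckConfig, SmallNeck
from .starnet_backbone import StarNet, StarNetConfig

__all__ = [
    "ModelConfig", "Detector", "build_model", "count_params", "count_flops",
    "DetectionSet", "decode_and_nms", "nms", "EvalReport", "evaluate",
    "evaluate_model", "train_toy", "save_model", "load_model", "PRESETS",
]

LEVEL_STRIDES = {"P2": 4, "P3": 8, "P4": 16, "P5": 32}


# ---------------------------------------------------------------------------
# Reference YOLOv8 building blocks
# ---------------------------------------------------------------------------


class Bottleneck(Module):
    def __init__(self, c1, c2, shortcut=True, rng=None):
        super().__init__()
        self.cv1 = ConvBNAct(c1, c2, 3, rng=rng)
        self.cv2 = ConvBNAct(c2, c2, 3, rng=rng)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C2f(Module):
    """Cross-stage partial block with a growing concat of bottleneck outputs."""

    def __init__(self, c1, c2, n=1, shortcut=False, rng=None):
        super().__init__()
        self.ch = c2 // 2
        self.cv1 = ConvBNAct(c1, 2 * self.ch, 1, rng=rng)
        self.m = [Bottleneck(self.ch, self.ch, shortcut, rng=rng) for _ in range(n)]
        self.cv2 = ConvBNAct((2 + n) * self.ch, c2, 1, rng=rng)

    def forward(self, x):
        y = self.cv1(x)
        a = y[:, : self.ch]
        b = y[:, self.ch:]
        ys = [a, b]
        for blk in self.m:
            ys.append(blk(ys[-1]))
        return self.cv2(concat(ys, axis=1))


class SPPF(Module):
    def __init__(self, c1, c2, k=5, rng=None):
        super().__init__()
        half = c1 // 2
        self.cv1 = ConvBNAct(c1, half, 1, rng=rng)
        self.cv2 = ConvBNAct(half * 4, c2, 1, rng=rng)
        self.pool = MaxPool2d(k, stride=1)

    def forward(self, x):
        y0 = self.cv1(x)
        y1 = self.pool(y0)
        y2 = self.pool(y1)
        y3 = self.pool(y2)
        return self.cv2(concat([y0, y1, y2, y3], axis=1))


class V8Backbone(Module):
    """The YOLOv8n CSP backbone (width 0.25, depth 0.33), taps P2..P5."""

    def __init__(self, rng=None):
        super().__init__()
        w = (16, 32, 64, 128, 256)
        self.stem = ConvBNAct(3, w[0], 3, stride=2, rng=rng)
        self.d1 = ConvBNAct(w[0], w[1], 3, stride=2, rng=rng)
        self.c1 = C2f(w[1], w[1], 1, True, rng=rng)
        self.d2 = ConvBNAct(w[1], w[2], 3, stride=2, rng=rng)
        self.c2 = C2f(w[2], w[2], 2, True, rng=rng)
        self.d3 = ConvBNAct(w[2], w[3], 3, stride=2, rng=rng)
        self.c3 = C2f(w[3], w[3], 2, True, rng=rng)
        self.d4 = ConvBNAct(w[3], w[4], 3, stride=2, rng=rng)
        self.c4 = C2f(w[4], w[4], 1, True, rng=rng)
        self.sppf = SPPF(w[4], w[4], rng=rng)
        self.out_channels = {"P2": w[1], "P3": w[2], "P4": w[3], "P5": w[4]}

    def forward(self, img):
        img = astensor(img)
        h, wd = img.shape[2], img.shape[3]
        if h % 32 or wd % 32:
            raise ValueError(f"input spatial size {h}x{wd} must be divisible by 32")
        p2 = self.c1(self.d1(self.stem(img)))
        p3 = self.c2(self.d2(p2))
        p4 = self.c3(self.d3(p3))
        p5 = self.sppf(self.c4(self.d4(p4)))
        return {"P2": p2, "P3": p3, "P4": p4, "P5": p5}


class V8PAN(Module):
    """The retained YOLOv8 PAN neck; C2f widths configurable per node."""

    def __init__(self, in_channels, widths=(128, 64, 128, 256), rng=None):
        super().__init__()
        c3, c4, c5 = in_channels["P3"], in_channels["P4"], in_channels["P5"]
        wtd, w3, w4, w5 = widths
        from .nn import Upsample2x
        self.up = Upsample2x()
        self.td4 = C2f(c5 + c4, wtd, 1, False, rng=rng)
        self.td3 = C2f(wtd + c3, w3, 1, False, rng=rng)
        self.down3 = ConvBNAct(w3, w3, 3, stride=2, rng=rng)
        self.bu4 = C2f(w3 + wtd, w4, 1, False, rng=rng)
        self.down4 = ConvBNAct(w4, w4, 3, stride=2, rng=rng)
        self.bu5 = C2f(w4 + c5, w5, 1, False, rng=rng)
        self.out_channels = {"P3": w3, "P4": w4, "P5": w5}

    def forward(self, feats):
        p3, p4, p5 = feats["P3"], feats["P4"], feats["P5"]
        t4 = self.td4(concat([self.up(p5), p4], axis=1))
        t3 = self.td3(concat([self.up(t4), p3], axis=1))
        o4 = self.bu4(concat([self.down3(t3), t4], axis=1))
        o5 = self.bu5(concat([self.down4(o4), p5], axis=1))
        return {"P3": t3, "P4": o4, "P5": o5}


class Detect(Module):
    """Retained anchor-free YOLOv8 head: DFL box regression + class logits."""

    def __init__(self, num_classes, in_channels, reg_max=16, rng=None):
        super().__init__()
        self.nc = num_classes
        self.reg_max = reg_max
        chs = list(in_channels)
        c2 = max(16, chs[0] // 4, reg_max * 4)
        c3 = max(chs[0], min(num_classes, 100))
        self.box_branches = []
        self.cls_branches = []
        for c in chs:
            box_out = Conv2d(c2, 4 * reg_max, 1, bias=True, rng=rng)
            box_out.bias.data[:] = 1.0
            cls_out = Conv2d(c3, num_classes, 1, bias=True, rng=rng)
            cls_out.bias.data[:] = -4.0  # start with low foreground scores
            self.box_branches.append(Sequential(
                ConvBNAct(c, c2, 3, rng=rng), ConvBNAct(c2, c2, 3, rng=rng), box_out))
            self.cls_branches.append(Sequential(
                ConvBNAct(c, c3, 3, rng=rng), ConvBNAct(c3, c3, 3, rng=rng), cls_out))
        # integral-projection weights of the distribution focal decode (fixed)
        self.dfl_project = np.arange(reg_max, dtype=np.float32)

    def forward(self, feats_list):
        outs = []
        for x, bb, cb in zip(feats_list, self.box_branches, self.cls_branches):
            outs.append(concat([bb(x), cb(x)], axis=1))
        return outs


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


@dataclass
class ModelConfig:
    backbone: str = "starnet"              # "starnet" | "yolov8n"
    starnet: StarNetConfig = field(default_factory=StarNetConfig)
    neck: str = "smallneck"                # "smallneck" | "v8pan"
    neck_cfg: NeckConfig = field(default_factory=NeckConfig)
    v8pan_widths: tuple = (128, 64, 128, 256)
    attention: bool = True
    num_classes: int = 24
    reg_max: int = 16
    head_levels: tuple = ("P3", "P4", "P5")
    input_size: int = 640

    def __post_init__(self):
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32")


class Detector(Module):
    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        if cfg.backbone == "starnet":
            self.backbone = StarNet(cfg.starnet, rng=rng)
        elif cfg.backbone == "yolov8n":
            self.backbone = V8Backbone(rng=rng)
        else:
            raise ValueError(f"unknown backbone '{cfg.backbone}'")
        taps = dict(self.backbone.out_channels)
        self.attention = DCPGAttention(taps["P5"]) if cfg.attention else None
        if cfg.neck == "smallneck":
            self.neck = SmallNeck(taps, cfg.neck_cfg, rng=rng)
        elif cfg.neck == "v8pan":
            self.neck = V8PAN(taps, cfg.v8pan_widths, rng=rng)
        else:
            raise ValueError(f"unknown neck '{cfg.neck}'")
        for lv in cfg.head_levels:
            if lv not in self.neck.out_channels:
                raise ValueError(f"head level {lv} not produced by the neck")
        self.head = Detect(cfg.num_classes,
                           [self.neck.out_channels[lv] for lv in cfg.head_levels],
                           reg_max=cfg.reg_max, rng=rng)
        self.strides = [LEVEL_STRIDES[lv] for lv in cfg.head_levels]

    def forward(self, img):
        feats = self.backbone(img)
        if self.attention is not None:
            feats["P5"] = self.attention(feats["P5"])
        fused = self.neck(feats)
        return self.head([fused[lv] for lv in self.cfg.head_levels])


def _preset_cfg(name: str, num_classes: int = 24) -> ModelConfig:
    if name == "yolov8n":
        return ModelConfig(backbone="yolov8n", neck="v8pan", attention=False,
                           num_classes=num_classes)
    if name == "yolov8n-starnet":
        return ModelConfig(backbone="starnet", neck="v8pan", attention=False,
                           v8pan_widths=(112, 48, 128, 256), num_classes=num_classes)
    if name == "yolov8n-smallneck":
        return ModelConfig(backbone="yolov8n", neck="smallneck", attention=False,
                           num_classes=num_classes)
    if name == "yolo-dcpg":
        return ModelConfig(num_classes=num_classes)
    if name == "yolo-dcpg-noattn":
        return ModelConfig(attention=False, num_classes=num_classes)
    if name == "toy":
        return ModelConfig(
            starnet=StarNetConfig(variant="s100", base_width=12,
                                  stage_depths=(1, 1, 1, 1), mlp_ratio=3, stem_width=16),
            neck_cfg=NeckConfig(level_widths={"P2": 16, "P3": 24, "P4": 32, "P5": 48}),
            num_classes=num_classes, reg_max=8, input_size=160)
    raise ValueError(f"unknown preset '{name}'")


PRESETS = ("yolov8n", "yolov8n-starnet", "yolov8n-smallneck",
           "yolo-dcpg", "yolo-dcpg-noattn", "toy")


def build_model(cfg, num_classes: int = 24, seed: int = 0) -> Detector:
    """Build a detector from a preset name or a :class:`ModelConfig`."""
    if isinstance(cfg, str):
        cfg = _preset_cfg(cfg, num_classes)
    return Detector(cfg, seed=seed)


# ---------------------------------------------------------------------------
# Profiling
# ---------------------------------------------------------------------------


def count_params(model: Module) -> int:
    """Exact number of learnable scalars (fixed buffers excluded)."""
    return model.num_params()


def params_millions(model: Module) -> float:
    return round(count_params(model) / 1e6, 2)


def count_flops(model: Detector, input_size: int | None = None) -> float:
    """GFLOPs = 2 x conv MACs of a forward pass at `input_size` (square)."""
    size = input_size or model.cfg.input_size
    model.eval()
    with no_grad(), count_macs() as counter:
        model(np.zeros((1, 3, size, size), dtype=np.float32))
    return 2.0 * counter[0] / 1e9


# ---------------------------------------------------------------------------
# Decoding and NMS
# ---------------------------------------------------------------------------


@dataclass
class DetectionSet:
    """Scored, class-labelled boxes for one image (cxcywh, pixels)."""

    boxes: np.ndarray
    scores: np.ndarray
    labels: np.ndarray

    @staticmethod
    def empty():
        return DetectionSet(np.zeros((0, 4)), np.zeros(0), np.zeros(0, dtype=int))


def _decode_level(raw: Tensor, stride: int, reg_max: int, nc: int):
    """Raw (n, 4*reg_max+nc, h, w) -> (boxes cxcywh Tensor (n, h*w, 4), cls logits)."""
    n, _, h, w = raw.shape
    box = raw[:, : 4 * reg_max].reshape(n, 4, reg_max, h * w)
    cls = raw[:, 4 * reg_max:].reshape(n, nc, h * w)
    prob = softmax(box, axis=2)
    proj = Tensor(np.arange(reg_max, dtype=np.float32).reshape(1, 1, reg_max, 1))
    dist = (prob * proj).sum(axis=2) * stride  # (n, 4, h*w): l, t, r, b in pixels
    gy, gx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    ax = ((gx.ravel() + 0.5) * stride).astype(np.float32)
    ay = ((gy.ravel() + 0.5) * stride).astype(np.float32)
    l, t, r, b = dist[:, 0], dist[:, 1], dist[:, 2], dist[:, 3]
    cx = (Tensor(ax) - l + Tensor(ax) + r) * 0.5
    cy = (Tensor(ay) - t + Tensor(ay) + b) * 0.5
    from .autograd import stack
    boxes = stack([cx, cy, l + r, t + b], axis=-1)
    return boxes, cls


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float) -> list:
    """Greedy non-maximum suppression on cxcywh boxes; returns kept indices."""
    order = np.argsort(-scores)
    keep = []
    while order.size:
        i = order[0]
        keep.append(int(i))
        if order.size == 1:
            break
        rest = order[1:]
        ious = iou(np.broadcast_to(boxes[i], (rest.size, 4)), boxes[rest])
        order = rest[np.asarray(ious) < iou_threshold]
    return keep


def decode_and_nms(raw_maps, strides, num_classes, reg_max=16,
                   conf_threshold=0.25, iou_threshold=0.45,
                   image_size=None, max_det=300):
    """Decode raw head maps into per-image :class:`DetectionSet` objects."""
    if not raw_maps:
        return []
    n = raw_maps[0].shape[0]
    all_boxes, all_scores = [], []
    with no_grad():
        for raw, stride in zip(raw_maps, strides):
            boxes, cls = _decode_level(astensor(raw), stride, reg_max, num_classes)
            all_boxes.append(boxes.data)
            all_scores.append(1.0 / (1.0 + np.exp(-cls.data)))
    boxes = np.concatenate(all_boxes, axis=1)          # (n, cells, 4)
    scores = np.concatenate(all_scores, axis=2)        # (n, nc, cells)
    results = []
    for i in range(n):
        cls_scores = scores[i]
        best_cls = cls_scores.argmax(axis=0)
        best_score = cls_scores.max(axis=0)
        mask = best_score >= conf_threshold
        if not mask.any():
            results.append(DetectionSet.empty())
            continue
        b, s, c = boxes[i][mask], best_score[mask], best_cls[mask]
        if image_size is not None:
            cx = np.clip(b[:, 0], 0, image_size)
            cy = np.clip(b[:, 1], 0, image_size)
            x1 = np.clip(cx - b[:, 2] / 2, 0, image_size)
            x2 = np.clip(cx + b[:, 2] / 2, 0, image_size)
            y1 = np.clip(cy - b[:, 3] / 2, 0, image_size)
            y2 = np.clip(cy + b[:, 3] / 2, 0, image_size)
            b = np.stack([(x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1], axis=1)
        keep = []
        for cl in np.unique(c):
            idx = np.where(c == cl)[0]
            keep += [idx[j] for j in nms(b[idx], s[idx], iou_threshold)]
        keep = sorted(keep, key=lambda j: -s[j])[:max_det]
        results.append(DetectionSet(b[keep], s[keep], c[keep].astype(int)))
    return results


# ---------------------------------------------------------------------------
# Evaluation (precision / recall / AP / mAP)
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    precision: float
    recall: float
    ap_per_class: dict
    map50: float
    map50_95: float


def _match_greedy(dets: DetectionSet, gt_boxes, gt_used, cls, thr):
    """Greedily match class `cls` detections to ground truths at IoU >= thr."""
    flags = []
    order = np.argsort(-dets.scores)
    for j in order:
        if dets.labels[j] != cls:
            continue
        best, best_iou = -1, thr
        for k in range(len(gt_boxes)):
            if gt_used[k]:
                continue
            ov = iou(dets.boxes[j], gt_boxes[k])
            if ov >= best_iou:
                best, best_iou = k, ov
        if best >= 0:
            gt_used[best] = True
            flags.append((dets.scores[j], 1))
        else:
            flags.append((dets.scores[j], 0))
    return flags


def _average_precision(flags, n_gt):
    """101-point interpolated AP from (score, is_tp) pairs."""
    if n_gt == 0:
        return np.nan
    if not flags:
        return 0.0
    flags = sorted(flags, key=lambda f: -f[0])
    tp = np.cumsum([f[1] for f in flags])
    fp = np.cumsum([1 - f[1] for f in flags])
    recall = tp / n_gt
    precision = tp / np.maximum(tp + fp, 1e-12)
    ap = 0.0
    for r in np.linspace(0, 1, 101):
        p = precision[recall >= r]
        ap += (p.max() if p.size else 0.0) / 101
    return float(ap)


def evaluate(detections, ground_truths, num_classes, iou_thresholds=None) -> EvalReport:
    """Dataset-level detection metrics.

    Parameters
    ----------
    detections:
        One :class:`DetectionSet` per image.
    ground_truths:
        Per image, a list of ``(class_id, (cx, cy, w, h))`` in the same units
        as the detections.
    iou_thresholds:
        Defaults to ``0.5:0.05:0.95`` (ten thresholds).
    """
    thrs = (np.round(np.arange(0.5, 0.96, 0.05), 2) if iou_thresholds is None
            else np.atleast_1d(iou_thresholds))
    n_gt = {c: 0 for c in range(num_classes)}
    for gts in ground_truths:
        for c, _ in gts:
            n_gt[int(c)] += 1
    active = [c for c in range(num_classes) if n_gt[c] > 0]
    skipped = [c for c in range(num_classes) if n_gt[c] == 0]
    if skipped:
        warnings.warn(f"classes {skipped} have no ground truths; excluded from mAP")

    ap = {float(t): {c: [] for c in active} for t in thrs}
    tp50 = fp50 = 0
    for dets, gts in zip(detections, ground_truths):
        gt_cls = np.array([int(c) for c, _ in gts]) if gts else np.zeros(0, dtype=int)
        gt_boxes = np.array([list(b) for _, b in gts], dtype=float).reshape(-1, 4)
        for t in thrs:
            for c in active:
                sel = np.where(gt_cls == c)[0]
                used = [False] * len(sel)
                flags = _match_greedy(dets, gt_boxes[sel], used, c, t)
                ap[float(t)][c] += flags
                if abs(t - 0.5) < 1e-9:
                    tp50 += sum(f[1] for f in flags)
                    fp50 += sum(1 - f[1] for f in flags)
    per_thr_map = []
    ap50_per_class = {}
    for t in thrs:
        vals = [_average_precision(ap[float(t)][c], n_gt[c]) for c in active]
        per_thr_map.append(float(np.mean(vals)) if vals else 0.0)
        if abs(t - 0.5) < 1e-9:
            ap50_per_class = {c: 100.0 * _average_precision(ap[float(t)][c], n_gt[c])
                              for c in active}
    total_gt = sum(n_gt.values())
    precision = 100.0 * tp50 / (tp50 + fp50) if (tp50 + fp50) else 0.0
    recall = 100.0 * tp50 / total_gt if total_gt else 0.0
    map50 = 100.0 * per_thr_map[np.argmin(np.abs(thrs - 0.5))] if len(per_thr_map) else 0.0
    map50_95 = 100.0 * float(np.mean(per_thr_map)) if len(per_thr_map) else 0.0
    return EvalReport(precision=precision, recall=recall, ap_per_class=ap50_per_class,
                      map50=map50, map50_95=map50_95)


# ---------------------------------------------------------------------------
# Toy training
# ---------------------------------------------------------------------------


def _scene_to_input(scene):
    img = scene.image.astype(np.float32) / 255.0
    return img.transpose(2, 0, 1)[None]


def _scene_gts_pixels(scene):
    size = scene.image.shape[0]
    return [(c, (b[0] * size, b[1] * size, b[2] * size, b[3] * size))
            for c, b in scene.annotations]


def _assign_targets(gts, strides, shapes, nc):
    """Center-cell assignment: each gt goes to the coarsest level whose
    stride window (4 x stride) still covers its longer side."""
    targets = []
    for (h, w) in shapes:
        targets.append({"cls": np.zeros((nc, h * w), dtype=np.float32), "pos": {}})
    for c, (cx, cy, bw, bh) in gts:
        size = max(bw, bh)
        li = 0
        for i, s in enumerate(strides):
            li = i
            if size <= 4 * s:
                break
        s = strides[li]
        h, w = shapes[li]
        gx = min(int(cx / s), w - 1)
        gy = min(int(cy / s), h - 1)
        cell = gy * w + gx
        targets[li]["cls"][int(c), cell] = 1.0
        targets[li]["pos"].setdefault(cell, (cx, cy, bw, bh))
    return targets


def _bce_sum(logits: Tensor, target: np.ndarray) -> Tensor:
    """Numerically stable elementwise binary cross-entropy, summed."""
    z, y = logits, Tensor(target)
    zero = Tensor(np.zeros(1, dtype=np.float32))
    return (z.maximum(zero) - z * y + (1.0 + (-z.maximum(-z)).exp()).log()).sum()


def train_toy(model: Detector, scenes, loss_cfg: WIoUConfig | None = None,
              epochs: int = 10, seed: int = 0, lr: float = 0.05,
              batch_size: int = 8, loss_name: str = "inner_wiou",
              box_weight: float = 1.0, verbose: bool = False):
    """Train the detector on synthetic scenes with the Inner-WIoU loss.

    Deterministic given `seed`.  Returns a log dict with per-epoch mean
    losses.  Raises ``RuntimeError`` on divergence (non-finite loss).
    """
    loss_cfg = loss_cfg or WIoUConfig(ratio=1.05)
    rng = np.random.default_rng(seed)
    opt = SGD(model.parameters(), lr=lr, momentum=0.9, weight_decay=5e-4)
    state = WIoUState()
    nc, reg_max = model.cfg.num_classes, model.cfg.reg_max
    log = {"epoch_loss": [], "epoch_cls": [], "epoch_box": []}
    model.train()
    for epoch in range(epochs):
        order = rng.permutation(len(scenes))
        ep_loss = ep_cls = ep_box = 0.0
        nb = 0
        for start in range(0, len(order), batch_size):
            idx = order[start:start + batch_size]
            imgs = np.concatenate([_scene_to_input(scenes[i]) for i in idx])
            raws = model(imgs)
            shapes = [(r.shape[2], r.shape[3]) for r in raws]
            cls_loss = None
            box_terms = []
            per_image_targets = [
                _assign_targets(_scene_gts_pixels(scenes[i]), model.strides, shapes, nc)
                for i in idx]
            n_pos = 0
            for li, (raw, stride) in enumerate(zip(raws, model.strides)):
                n, _, h, w = raw.shape
                boxes, cls_logits = _decode_level(raw, stride, reg_max, nc)
                tcls = np.zeros((n, nc, h * w), dtype=np.float32)
                pred_list, gt_list = [], []
                for bi in range(len(idx)):
                    tgt = per_image_targets[bi][li]
                    tcls[bi] = tgt["cls"]
                    for cell, gtbox in tgt["pos"].items():
                        pred_list.append(boxes[bi, cell])
                        gt_list.append(gtbox)
                n_pos += len(pred_list)
                term = _bce_sum(cls_logits, tcls)
                cls_loss = term if cls_loss is None else cls_loss + term
                if pred_list:
                    from .autograd import stack
                    pred_t = stack(pred_list, axis=0)
                    gt_arr = np.array(gt_list, dtype=np.float32)
                    bloss, state = box_loss(loss_name, pred_t, gt_arr, loss_cfg, state)
                    box_terms.append(bloss)
            cls_loss = cls_loss * (1.0 / max(n_pos, 1))
            total = cls_loss
            box_val = 0.0
            if box_terms:
                bsum = box_terms[0]
                for b in box_terms[1:]:
                    bsum = bsum + b
                total = total + box_weight * bsum
                box_val = float(bsum.data)
            if not np.isfinite(total.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={float(total.data)}")
            opt.zero_grad()
            total.backward()
            opt.step()
            ep_loss += float(total.data)
            ep_cls += float(cls_loss.data)
            ep_box += box_val
            nb += 1
        log["epoch_loss"].append(ep_loss / nb)
        log["epoch_cls"].append(ep_cls / nb)
        log["epoch_box"].append(ep_box / nb)
        if verbose:
            print(f"epoch {epoch + 1}/{epochs}  loss {ep_loss / nb:.4f} "
                  f"(cls {ep_cls / nb:.4f}, box {ep_box / nb:.4f})")
    model.eval()
    return log


def evaluate_model(model: Detector, scenes, conf_threshold=0.05,
                   iou_threshold=0.45) -> EvalReport:
    """Run inference over scenes and score against their annotations."""
    model.eval()
    dets, gts = [], []
    size = scenes[0].image.shape[0]
    with no_grad():
        for scene in scenes:
            raws = model(_scene_to_input(scene))
            d = decode_and_nms(raws, model.strides, model.cfg.num_classes,
                               model.cfg.reg_max, conf_threshold, iou_threshold,
                               image_size=size)
            dets.append(d[0])
            gts.append(_scene_gts_pixels(scene))
    return evaluate(dets, gts, model.cfg.num_classes)


# ---------------------------------------------------------------------------
# Serialization (native format: JSON config + NPZ weight arrays)
# ---------------------------------------------------------------------------


def save_model(model: Detector, path):
    """Serialise config + weights to an ``.npz`` archive (portable, no pickle)."""
    cfg = model.cfg
    meta = {
        "backbone": cfg.backbone, "neck": cfg.neck, "attention": cfg.attention,
        "num_classes": cfg.num_classes, "reg_max": cfg.reg_max,
        "head_levels": list(cfg.head_levels), "input_size": cfg.input_size,
        "v8pan_widths": list(cfg.v8pan_widths),
        "starnet": {"variant": cfg.starnet.variant, "base_width": cfg.starnet.base_width,
                     "stage_depths": list(cfg.starnet.stage_depths) if cfg.starnet.stage_depths else None,
                     "mlp_ratio": cfg.starnet.mlp_ratio, "stem_width": cfg.starnet.stem_width,
                     "dw_kernel": cfg.starnet.dw_kernel},
        "neck_cfg": {"level_widths": cfg.neck_cfg.level_widths,
                      "pruned_channels": cfg.neck_cfg.pruned_channels,
                      "use_gsconv": cfg.neck_cfg.use_gsconv,
                      "use_vovgscsp": cfg.neck_cfg.use_vovgscsp,
                      "xi": cfg.neck_cfg.xi},
    }
    state = model.state_dict()
    np.savez(path, __config__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def load_model(path) -> Detector:
    data = np.load(path)
    meta = json.loads(bytes(data["__config__"]).decode())
    cfg = ModelConfig(
        backbone=meta["backbone"], neck=meta["neck"], attention=meta["attention"],
        num_classes=meta["num_classes"], reg_max=meta["reg_max"],
        head_levels=tuple(meta["head_levels"]), input_size=meta["input_size"],
        v8pan_widths=tuple(meta["v8pan_widths"]),
        starnet=StarNetConfig(**{**meta["starnet"],
                                 "stage_depths": tuple(meta["starnet"]["stage_depths"])
                                 if meta["starnet"]["stage_depths"] else None}),
        neck_cfg=NeckConfig(**meta["neck_cfg"]))
    model = Detector(cfg)
    state = {k: data[k] for k in data.files if k != "__config__"}
    model.load_state_dict(state)
    model.eval()
    return model
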