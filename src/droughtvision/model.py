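"""MC-YOLOv13-L assembly: layer registry, graph builder, trainer, predictor.

The architecture is expressed as an ordered table of layer rows
(id, from, module, args) mirroring the network-parameter table shipped in
``configs/mc_yolov13_l.yaml``. The detector is anchor-free with three
detection scales (strides 8/16/32 of a 640 input) over 4 drought-grade
classes.

Two parameter totals are exposed deliberately:

* :func:`total_parameters` sums the reference ``params`` column carried by
  the architecture config — the published per-layer accounting (3,477,567
  in total for this network).
* ``Model.count_parameters()`` counts the actual trainable scalars of the
  built network. Plain ``Conv`` rows match the reference column exactly by
  construction (conv-without-bias + batch norm); composite blocks whose
  internals are not published (C3k2_MSLA, A2C2f, HyperACE, CMUNeXt, Detect)
  are this package's own designs, so their actual counts are close to but
  not pinned at the reference values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from . import losses as L
from .blocks import MSLA, CMUNeXtBlock
from .nn import core as ag
from .nn import layers as nl
from .nn.core import Tensor

__all__ = [
    "LayerSpec",
    "ModelGraph",
    "Model",
    "MODULE_REGISTRY",
    "build_module",
    "load_graph",
    "build_model",
    "total_parameters",
    "detection_loss",
    "smoke_train",
    "decode_predictions",
    "DEFAULT_CONFIG",
]

DEFAULT_CONFIG = "mc_yolov13_l.yaml"


# ---------------------------------------------------------------------------
# graph description
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LayerSpec:
    id: int
    frm: int | list[int]          # source layer id(s); -1 = previous
    module: str
    args: list = field(default_factory=list)
    params_ref: int | None = None  # reference (published) parameter count

    def sources(self) -> list[int]:
        f = self.frm
        return [f] if isinstance(f, int) else list(f)


@dataclass
class ModelGraph:
    layers: list[LayerSpec]
    nc: int = 4
    input_side: int = 640

    def validate(self) -> "ModelGraph":
        for pos, spec in enumerate(self.layers):
            if spec.id != pos:
                raise ValueError(f"layer ids must be contiguous; got {spec.id} at {pos}")
            for s in spec.sources():
                ref = spec.id - 1 if s == -1 else s
                if not (0 <= ref < spec.id) and spec.id > 0:
                    raise ValueError(f"layer {spec.id} references {s} which does not precede it")
            if spec.module not in MODULE_REGISTRY:
                raise ValueError(f"unknown module {spec.module!r} at layer {spec.id}")
        if self.layers[-1].module != "Detect":
            raise ValueError("last layer must be the Detect head")
        return self


def load_graph(path: str | Path | None = None) -> ModelGraph:
    """Load an architecture table (bundled MC-YOLOv13-L by default)."""
    if path is None:
        text = resources.files("droughtvision.configs").joinpath(DEFAULT_CONFIG).read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    layers = [
        LayerSpec(id=int(r["id"]), frm=r["from"], module=str(r["module"]),
                  args=list(r.get("args", [])), params_ref=r.get("params"))
        for r in doc["layers"]
    ]
    return ModelGraph(layers=layers, nc=int(doc.get("nc", 4)),
                      input_side=int(doc.get("input_side", 640))).validate()


def total_parameters(graph: ModelGraph) -> int:
    """Sum of the reference per-layer parameter column of the graph."""
    missing = [s.id for s in graph.layers if s.params_ref is None]
    if missing:
        raise ValueError(f"layers {missing} carry no reference parameter count")
    return int(sum(s.params_ref for s in graph.layers))


# ---------------------------------------------------------------------------
# composite modules
# ---------------------------------------------------------------------------


class DSConv(nl.Module):
    """Depthwise conv + pointwise conv with one BN after the pointwise stage."""

    def __init__(self, c1, c2, k=3, s=1, rng=None):
        super().__init__()
        self.dw = nl.Conv2d(c1, c1, k, s, groups=c1, rng=rng)
        self.pw = nl.Conv2d(c1, c2, 1, rng=rng)
        self.bn = nl.BatchNorm2d(c2)

    def forward(self, x):
        return ag.silu(self.bn(self.pw(self.dw(x))))


class C3k2MSLA(nl.Module):
    """CSP-style block whose interior bottleneck is multi-scale linear attention.

    ``cv1`` projects to two hidden halves; the running half passes through
    ``n`` MSLA units (with residual when ``shortcut``); all intermediate
    halves are concatenated and fused by ``cv2``.
    """

    def __init__(self, c1, c2, n=1, shortcut=False, e=0.5, rng=None):
        super().__init__()
        c = int(c2 * e)
        if c % 4:
            raise ValueError(f"hidden width {c} must be divisible by 4 for MSLA")
        self.c, self.n, self.shortcut = c, n, shortcut
        self.cv1 = nl.ConvBlock(c1, 2 * c, 1, rng=rng)
        self.msla = [MSLA(c, rng=rng) for _ in range(n)]
        self.cv2 = nl.ConvBlock((2 + n) * c, c2, 1, rng=rng)

    def forward(self, x):
        y = self.cv1(x)
        parts = [y[:, : self.c], y[:, self.c:]]
        for m in self.msla:
            out = m(parts[-1])
            parts.append(out + parts[-1] if self.shortcut else out)
        return self.cv2(ag.concatenate(parts, axis=1))


class Bottleneck(nl.Module):
    def __init__(self, c, shortcut=True, g=1, rng=None):
        super().__init__()
        self.cv1 = nl.ConvBlock(c, c, 3, groups=g, rng=rng)
        self.cv2 = nl.ConvBlock(c, c, 3, groups=g, rng=rng)
        self.shortcut = shortcut

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.shortcut else y


class A2C2f(nl.Module):
    """Aggregation block in the C2f idiom: split, n grouped bottlenecks, fuse."""

    def __init__(self, c1, c2, n=1, shortcut=True, g=1, rng=None):
        super().__init__()
        c = c2 // 2
        self.c = c
        self.cv1 = nl.ConvBlock(c1, 2 * c, 1, rng=rng)
        self.blocks = [Bottleneck(c, shortcut, g, rng=rng) for _ in range(n)]
        self.cv2 = nl.ConvBlock((2 + n) * c, c2, 1, rng=rng)

    def forward(self, x):
        y = self.cv1(x)
        parts = [y[:, : self.c], y[:, self.c:]]
        for b in self.blocks:
            parts.append(b(parts[-1]))
        return self.cv2(ag.concatenate(parts, axis=1))


class HyperACEBlock(nl.Module):
    """Cross-scale correlation mixer over three pyramid levels.

    Brings the high-resolution input down (average pooling) and the
    low-resolution input up (nearest upsample + 1x1 projection) to the middle
    scale, concatenates, fuses with a 1x1 conv and refines with ``n`` 3x3
    convs. Output: ``c2`` channels at the middle scale.
    """

    def __init__(self, c1, c2, n=1, *rest, rng=None):
        super().__init__()
        self.proj_low = nl.ConvBlock(2 * c1, c1, 1, rng=rng)  # low-res has 2*c1 ch
        self.fuse = nl.ConvBlock(3 * c1, c2, 1, rng=rng)
        self.refine = [nl.ConvBlock(c2, c2, 3, rng=rng) for _ in range(max(n, 0))]

    def forward(self, xs):
        hi, mid, low = xs  # strides 8 / 16 / 32
        hi_d = ag.avg_pool2d(hi, 2)
        low_u = self.proj_low(ag.upsample_nearest2d(low, 2))
        y = self.fuse(ag.concatenate([hi_d, mid, low_u], axis=1))
        for r in self.refine:
            y = r(y)
        return y


class FullPADTunnel(nl.Module):
    """Gated residual injection: ``a + gate * b`` with one learnable scalar."""

    def __init__(self, rng=None):
        super().__init__()
        self.gate = Tensor(np.zeros(()), requires_grad=True)

    def forward(self, xs):
        a, b = xs
        return a + b * self.gate


class UpsampleLayer(nl.Module):
    def __init__(self, _size=None, scale=2, mode="nearest", rng=None):
        super().__init__()
        if mode != "nearest":
            raise ValueError(f"unsupported upsample mode {mode!r}")
        self.scale = int(scale)

    def forward(self, x):
        return ag.upsample_nearest2d(x, self.scale)


class DownsampleConv(nl.Module):
    """2x spatial reduction (average pool) + channel doubling 1x1 conv."""

    def __init__(self, c, rng=None):
        super().__init__()
        self.cv = nl.ConvBlock(c, 2 * c, 1, rng=rng)

    def forward(self, x):
        return self.cv(ag.avg_pool2d(x, 2))


class ConcatLayer(nl.Module):
    def __init__(self, axis=1, rng=None):
        super().__init__()
        self.axis = axis

    def forward(self, xs):
        return ag.concatenate(xs, axis=self.axis)


class DetectHead(nl.Module):
    """Anchor-free head: per scale a 3x3 stem then a 1x1 map to 4 + nc."""

    def __init__(self, nc, chs, rng=None):
        super().__init__()
        self.nc = nc
        self.no = 4 + nc
        self.stems = [nl.ConvBlock(c, c, 3, rng=rng) for c in chs]
        self.heads = [nl.Conv2d(c, self.no, 1, rng=rng) for c in chs]
        self.biases = [Tensor(np.zeros(self.no), requires_grad=True) for _ in chs]

    def forward(self, xs):
        outs = []
        for x, stem, head, bias in zip(xs, self.stems, self.heads, self.biases):
            y = head(stem(x)) + bias.reshape(1, self.no, 1, 1)
            outs.append(y)
        return outs


class _CMUNeXtWrap(nl.Module):
    def __init__(self, c1, c2, n=1, rng=None):
        super().__init__()
        if c1 != c2:
            raise ValueError("CMUNeXt stage preserves channel count")
        self.block = CMUNeXtBlock(c1, depth=n, rng=rng)

    def forward(self, x):
        return self.block(x)


MODULE_REGISTRY = {
    "Conv": lambda args, rng: nl.ConvBlock(*args[:2], *(args[2:] or []), rng=rng),
    "DSConv": lambda args, rng: DSConv(*args, rng=rng),
    "C3k2_MSLA": lambda args, rng: C3k2MSLA(*args, rng=rng),
    "A2C2f": lambda args, rng: A2C2f(*args, rng=rng),
    "CMUNeXt": lambda args, rng: _CMUNeXtWrap(*args, rng=rng),
    "HyperACE": lambda args, rng: HyperACEBlock(*args[:3], *args[3:], rng=rng),
    "Upsample": lambda args, rng: UpsampleLayer(*args, rng=rng),
    "DownsampleConv": lambda args, rng: DownsampleConv(*args, rng=rng),
    "FullPAD_Tunnel": lambda args, rng: FullPADTunnel(rng=rng),
    "Concat": lambda args, rng: ConcatLayer(*args, rng=rng),
    "Detect": lambda args, rng: DetectHead(*args, rng=rng),
}


def build_module(name: str, args: list, rng: np.random.Generator | None = None):
    if name not in MODULE_REGISTRY:
        raise KeyError(f"unknown module {name!r}")
    return MODULE_REGISTRY[name](args, rng or np.random.default_rng(0))


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


class Model(nl.Module):
    """Executable detection graph built from a :class:`ModelGraph`."""

    def __init__(self, graph: ModelGraph, seed: int = 0):
        super().__init__()
        graph.validate()
        self.graph = graph
        self.nc = graph.nc
        rng = np.random.default_rng(seed)
        self.layers = [build_module(s.module, s.args, rng) for s in graph.layers]
        self.strides = (8, 16, 32)

    def forward(self, x: Tensor):
        x = ag.as_tensor(x)
        outputs: list[Tensor] = []
        y = x
        for spec, mod in zip(self.graph.layers, self.layers):
            srcs = spec.sources()
            if srcs == [-1]:
                inp = y
            elif len(srcs) == 1:
                s = srcs[0]
                inp = y if s == -1 else outputs[s]
            else:
                inp = [y if s == -1 else outputs[s] for s in srcs]
            y = mod(inp)
            outputs.append(y)
        return y  # Detect output: list of three (B, 4+nc, H, W) maps


def build_model(graph: ModelGraph | None = None, seed: int = 0) -> Model:
    return Model(graph or load_graph(), seed=seed)


# ---------------------------------------------------------------------------
# desk-scale training
# ---------------------------------------------------------------------------


def _bce_with_logits(z: Tensor, target: np.ndarray) -> Tensor:
    """Elementwise stable binary cross-entropy on logits, mean-reduced."""
    t = ag.as_tensor(target)
    absz = ag.relu(z) + ag.relu(-z)
    loss = ag.relu(z) - z * t + ag.log(1.0 + ag.exp(-absz))
    return loss.mean()


def _assign_scale(side_px: float, strides=(8, 16, 32)) -> int:
    if side_px < 4 * strides[0]:
        return 0
    if side_px < 4 * strides[1]:
        return 1
    return 2


def detection_loss(raw_outputs, gt_by_image, input_side: int, nc: int,
                   ratio: float = 1.0, box_gain: float = 7.5,
                   cls_gain: float = 0.5, variant: str = "paper") -> Tensor:
    """Composite loss: Inner-CIoU box regression + BCE classification.

    ``raw_outputs``: the three Detect maps for a batch. ``gt_by_image``:
    per-image (M, 5) arrays [class, cx, cy, w, h] in normalized units of the
    input. Each ground truth is assigned to one scale by box size and to the
    grid cell containing its center.
    """
    strides = [input_side // o.data.shape[2] for o in raw_outputs]
    B = raw_outputs[0].data.shape[0]
    # per-scale assignment tables
    assign = {s: {"b": [], "gy": [], "gx": [], "cls": [], "box": []} for s in range(3)}
    n_gt = 0
    for b in range(B):
        for row in np.atleast_2d(np.asarray(gt_by_image[b], float)):
            if row.size == 0:
                continue
            cid, cx, cy, w, h = row
            bx, by, bw, bh = cx * input_side, cy * input_side, w * input_side, h * input_side
            s = _assign_scale(max(bw, bh), tuple(strides))
            gsz = raw_outputs[s].data.shape[2]
            gx = min(int(bx // strides[s]), gsz - 1)
            gy = min(int(by // strides[s]), gsz - 1)
            a = assign[s]
            a["b"].append(b); a["gy"].append(gy); a["gx"].append(gx)
            a["cls"].append(int(cid)); a["box"].append((bx, by, bw, bh))
            n_gt += 1

    total = ag.as_tensor(0.0)
    for s, out in enumerate(raw_outputs):
        a = assign[s]
        # classification over every cell: one-hot at assigned cells, else 0
        Hs = out.data.shape[2]
        target = np.zeros((B, nc, Hs, Hs))
        for b, gy, gx, cid in zip(a["b"], a["gy"], a["gx"], a["cls"]):
            target[b, cid, gy, gx] = 1.0
        cls_logits = out[:, 4:]
        total = total + cls_gain * _bce_with_logits(cls_logits, target)
        if not a["b"]:
            continue
        bi = np.array(a["b"]); gyi = np.array(a["gy"]); gxi = np.array(a["gx"])
        stride = strides[s]
        tx = out[bi, np.zeros_like(bi), gyi, gxi]
        ty = out[bi, np.ones_like(bi), gyi, gxi]
        tw = out[bi, np.full_like(bi, 2), gyi, gxi]
        th = out[bi, np.full_like(bi, 3), gyi, gxi]
        px = (ag.sigmoid(tx) * 2.0 - 0.5 + gxi) * stride
        py = (ag.sigmoid(ty) * 2.0 - 0.5 + gyi) * stride
        pw = ag.exp(ag.clip(tw, -4.0, 4.0)) * (2.0 * stride)
        ph = ag.exp(ag.clip(th, -4.0, 4.0)) * (2.0 * stride)
        gt = np.array(a["box"], float)
        pred_box = L.Box(px, py, pw, ph)
        gt_box = L.Box(gt[:, 0], gt[:, 1], gt[:, 2], gt[:, 3])
        box_loss = L.inner_ciou_loss(pred_box, gt_box, ratio, variant=variant)
        total = total + box_gain * box_loss.sum() / max(n_gt, 1)
    return total


def smoke_train(model: Model, images: np.ndarray, labels: list, epochs: int = 2,
                batch_size: int = 4, lr: float = 0.01, momentum: float = 0.937,
                weight_decay: float = 0.001, schedule: L.RatioSchedule | None = None,
                seed: int = 0) -> list[float]:
    """Short CPU training loop; returns the mean loss of each epoch.

    ``images``: (N, 1 or 3, S, S) float array in [0, 1]; ``labels``: per-image
    (M, 5) arrays [class, cx, cy, w, h] normalized. The auxiliary-box ratio
    follows ``schedule`` across the total step horizon.
    """
    n = images.shape[0]
    steps_per_epoch = int(np.ceil(n / batch_size))
    schedule = schedule or L.RatioSchedule(horizon=max(epochs * steps_per_epoch - 1, 1))
    opt = nl.SGD(model.parameters(), lr=lr, momentum=momentum,
                 weight_decay=weight_decay)
    rng = np.random.default_rng(seed)
    model.train()
    side = images.shape[-1]
    epoch_losses = []
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            batch = Tensor(images[idx])
            gts = [labels[i] for i in idx]
            outs = model(batch)
            loss = detection_loss(outs, gts, side, model.nc,
                                  ratio=schedule.at(step))
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
            step += 1
        epoch_losses.append(float(np.mean(losses)))
    return epoch_losses


# ---------------------------------------------------------------------------
# inference decoding
# ---------------------------------------------------------------------------


def _nms(boxes: np.ndarray, scores: np.ndarray, thr: float = 0.5) -> list[int]:
    from .metrics import box_iou_matrix

    order = np.lexsort((np.arange(len(scores)), -scores))
    keep: list[int] = []
    for i in order:
        if all(box_iou_matrix(boxes[i:i + 1], boxes[j:j + 1])[0, 0] < thr
               for j in keep):
            keep.append(int(i))
    return keep


def decode_predictions(raw_outputs, input_side: int, nc: int,
                       conf_threshold: float = 0.25, iou_nms: float = 0.5
                       ) -> list[np.ndarray]:
    """Raw Detect maps -> per-image (K, 6) arrays [class, conf, cx, cy, w, h].

    Box coordinates are returned in pixels of the input frame. Confidence is
    the sigmoid class score; per-class greedy NMS follows thresholding.
    """
    from scipy.special import expit

    B = raw_outputs[0].data.shape[0]
    results = []
    for b in range(B):
        rows = []
        for out in raw_outputs:
            arr = out.data[b]
            Hs = arr.shape[1]
            stride = input_side // Hs
            gy, gx = np.mgrid[0:Hs, 0:Hs]
            px = (expit(arr[0]) * 2 - 0.5 + gx) * stride
            py = (expit(arr[1]) * 2 - 0.5 + gy) * stride
            pw = np.exp(np.clip(arr[2], -4, 4)) * 2 * stride
            ph = np.exp(np.clip(arr[3], -4, 4)) * 2 * stride
            probs = expit(arr[4:4 + nc])
            cls = probs.argmax(axis=0)
            conf = probs.max(axis=0)
            sel = conf >= conf_threshold
            if sel.any():
                rows.append(np.stack([cls[sel], conf[sel], px[sel], py[sel],
                                      pw[sel], ph[sel]], axis=1))
        if not rows:
            results.append(np.zeros((0, 6)))
            continue
        dets = np.concatenate(rows, axis=0)
        kept = []
        for c in np.unique(dets[:, 0]):
            dc = dets[dets[:, 0] == c]
            keep = _nms(dc[:, 2:6], dc[:, 1], iou_nms)
            kept.append(dc[keep])
        results.append(np.concatenate(kept, axis=0))
    return results
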