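"""IoU-family bounding-box regression losses with auxiliary inner boxes.

The Inner-IoU idea: evaluate the overlap not on the boxes themselves but on
auxiliary boxes sharing each box's center with both sides scaled by a factor
``ratio``. Early in training a ratio > 1 enlarges the effective intersection
region (useful at low IoU / heavy occlusion); as training proceeds the ratio
is shrunk below 1, sharpening sensitivity to fine localization differences.
The combined regression loss used here is::

    L_inner_ciou = L_ciou + IoU - IoU_inner(ratio)

where ``L_ciou`` is the complete-IoU loss (1 - IoU + center-distance and
aspect-ratio penalties). At ratio = 1 the last two terms cancel and the loss
reduces to plain CIoU. The aspect term uses the standard completion
``v = (4/pi^2) (arctan(w_gt/h_gt) - arctan(w/h))^2`` with
``alpha = v / ((1 - IoU) + v)`` treated as a constant for gradients.

All functions accept python scalars, numpy arrays (broadcasting elementwise)
or autograd tensors (differentiable) for the box coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import core as _ag

__all__ = [
    "Box",
    "InnerBox",
    "RatioSchedule",
    "inner_box",
    "iou",
    "inner_iou",
    "ciou_loss",
    "inner_ciou_loss",
    "ratio_at",
]

_EPS = 1e-12


def _is_t(*xs) -> bool:
    return any(isinstance(x, _ag.Tensor) for x in xs)


def _min(a, b):
    return _ag.minimum(a, b) if _is_t(a, b) else np.minimum(a, b)


def _max(a, b):
    return _ag.maximum(a, b) if _is_t(a, b) else np.maximum(a, b)


def _relu0(x):
    return _ag.maximum(x, 0.0) if _is_t(x) else np.maximum(x, 0.0)


def _atan(x):
    return _ag.arctan(x) if _is_t(x) else np.arctan(x)


def _detach(x):
    return x.data if isinstance(x, _ag.Tensor) else x


@dataclass(frozen=True)
class Box:
    """Center/size box; units are arbitrary but shared between operands."""

    x_c: float
    y_c: float
    w: float
    h: float

    def validate(self) -> "Box":
        if not (np.all(np.asarray(_detach(self.w)) > 0)
                and np.all(np.asarray(_detach(self.h)) > 0)):
            raise ValueError(f"degenerate box {self}: sides must be positive")
        return self


@dataclass(frozen=True)
class InnerBox:
    """Edge coordinates of an auxiliary (ratio-scaled) box."""

    b_l: float
    b_r: float
    b_t: float
    b_b: float


@dataclass(frozen=True)
class RatioSchedule:
    """Linear auxiliary-box scale schedule over a training horizon.

    Starts at ``r_start`` (typically > 1: enlarged auxiliary boxes widen the
    effective regression basin) and decays to ``r_end`` (< 1: sharpened
    localization) by ``horizon`` steps. Constant when the endpoints agree.
    """

    r_start: float = 1.25
    r_end: float = 0.75
    horizon: int = 500

    def __post_init__(self):
        if not (self.r_start >= self.r_end > 0):
            raise ValueError("require r_start >= r_end > 0")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")

    def at(self, step: int) -> float:
        return ratio_at(self, step)


def ratio_at(schedule: RatioSchedule, step: int) -> float:
    """Linearly interpolated ratio at ``step``, clamped to the horizon."""
    t = min(max(step, 0), schedule.horizon) / schedule.horizon
    return schedule.r_start + (schedule.r_end - schedule.r_start) * t


def inner_box(box: Box, ratio: float) -> InnerBox:
    """Auxiliary box: same center, both sides scaled by ``ratio``."""
    if ratio <= 0:
        raise ValueError(f"ratio {ratio} must be positive")
    box.validate()
    return InnerBox(
        b_l=box.x_c - box.w * ratio / 2,
        b_r=box.x_c + box.w * ratio / 2,
        b_t=box.y_c - box.h * ratio / 2,
        b_b=box.y_c + box.h * ratio / 2,
    )


def iou(pred: Box, gt: Box):
    """Plain intersection-over-union of two center/size boxes."""
    return inner_iou(pred, gt, ratio=1.0)


def inner_iou(pred: Box, gt: Box, ratio: float):
    """IoU of the ratio-scaled auxiliary boxes, in [0, 1].

    Each side of the intersection is clamped at zero before multiplying, so
    disjoint auxiliary boxes yield 0 rather than a product of negatives.
    """
    p, g = inner_box(pred, ratio), inner_box(gt, ratio)
    iw = _relu0(_min(g.b_r, p.b_r) - _max(g.b_l, p.b_l))
    ih = _relu0(_min(g.b_b, p.b_b) - _max(g.b_t, p.b_t))
    inter = iw * ih
    union = (gt.w * gt.h) * ratio**2 + (pred.w * pred.h) * ratio**2 - inter
    return inter / (union + _EPS)


def ciou_loss(pred: Box, gt: Box):
    """Complete-IoU loss: 1 - IoU + rho^2/c^2 + alpha*v.

    ``rho`` is the center distance, ``c`` the diagonal of the smallest
    enclosing box, ``v`` the aspect-ratio consistency term and ``alpha`` its
    adaptive weight (constant with respect to gradients).
    """
    pred.validate()
    gt.validate()
    u = iou(pred, gt)
    rho2 = (pred.x_c - gt.x_c) ** 2 + (pred.y_c - gt.y_c) ** 2
    cw = _max(pred.x_c + pred.w / 2, gt.x_c + gt.w / 2) - _min(
        pred.x_c - pred.w / 2, gt.x_c - gt.w / 2)
    ch = _max(pred.y_c + pred.h / 2, gt.y_c + gt.h / 2) - _min(
        pred.y_c - pred.h / 2, gt.y_c - gt.h / 2)
    c2 = cw**2 + ch**2
    v = (4.0 / np.pi**2) * (_atan(gt.w / gt.h) - _atan(pred.w / pred.h)) ** 2
    # alpha is computed from detached values: standard CIoU treats it as a
    # constant so the aspect term does not feed back through the IoU.
    v_c = _detach(v)
    alpha = v_c / ((1.0 - _detach(u)) + v_c + _EPS)
    return 1.0 - u + rho2 / (c2 + _EPS) + alpha * v


def inner_ciou_loss(pred: Box, gt: Box, ratio: float, variant: str = "paper"):
    """Inner-CIoU regression loss.

    ``variant="paper"``: ``L_ciou + IoU - IoU_inner(ratio)`` as printed; at
    ratio = 1 the two IoU terms cancel and the value equals ``ciou_loss``.
    ``variant="reference"``: ``(1 - IoU_inner(ratio))`` plus the CIoU
    distance and aspect penalties. The two forms are algebraically identical
    (``L_ciou + IoU = 1 + penalties``); both spellings are kept so either can
    be named in configuration.
    """
    if variant == "paper":
        return ciou_loss(pred, gt) + iou(pred, gt) - inner_iou(pred, gt, ratio)
    if variant == "reference":
        return (ciou_loss(pred, gt) - (1.0 - iou(pred, gt))
                + (1.0 - inner_iou(pred, gt, ratio)))
    raise ValueError(f"unknown variant {variant!r}")
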