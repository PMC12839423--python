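"""Inner-IoU / CIoU losses against hand values and rasterization oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from droughtvision.losses import (
    Box,
    RatioSchedule,
    ciou_loss,
    inner_box,
    inner_ciou_loss,
    inner_iou,
    iou,
    ratio_at,
)


def iou_xyxy_oracle(b1: Box, b2: Box, ratio: float = 1.0) -> float:
    """Independent interval-overlap IoU of ratio-scaled boxes."""
    def edges(b):
        w, h = b.w * ratio, b.h * ratio
        return b.x_c - w / 2, b.x_c + w / 2, b.y_c - h / 2, b.y_c + h / 2

    l1, r1, t1, b1_ = edges(b1)
    l2, r2, t2, b2_ = edges(b2)
    iw = max(0.0, min(r1, r2) - max(l1, l2))
    ih = max(0.0, min(b1_, b2_) - max(t1, t2))
    inter = iw * ih
    union = (r1 - l1) * (b1_ - t1) + (r2 - l2) * (b2_ - t2) - inter
    return inter / union


def raster_iou(b1: Box, b2: Box, res: int = 512) -> float:
    """Pixel-rasterization IoU on a res^2 grid spanning both boxes."""
    xs = [b.x_c - b.w / 2 for b in (b1, b2)] + [b.x_c + b.w / 2 for b in (b1, b2)]
    ys = [b.y_c - b.h / 2 for b in (b1, b2)] + [b.y_c + b.h / 2 for b in (b1, b2)]
    x0, x1, y0, y1 = min(xs), max(xs), min(ys), max(ys)
    gx = np.linspace(x0, x1, res)
    gy = np.linspace(y0, y1, res)
    X, Y = np.meshgrid(gx, gy)

    def mask(b):
        return ((np.abs(X - b.x_c) <= b.w / 2) & (np.abs(Y - b.y_c) <= b.h / 2))

    m1, m2 = mask(b1), mask(b2)
    union = (m1 | m2).sum()
    return (m1 & m2).sum() / union if union else 0.0


class TestInnerBox:
    def test_ratio_one_is_identity(self):
        b = Box(3.0, -1.0, 2.0, 5.0)
        ib = inner_box(b, 1.0)
        assert (ib.b_l, ib.b_r) == (b.x_c - b.w / 2, b.x_c + b.w / 2)
        assert (ib.b_t, ib.b_b) == (b.y_c - b.h / 2, b.y_c + b.h / 2)

    def test_hand_substitution(self):
        ib = inner_box(Box(10, 10, 4, 2), 0.5)
        assert (ib.b_l, ib.b_r, ib.b_t, ib.b_b) == (9, 11, 9.5, 10.5)

    def test_area_scales_with_ratio_squared(self, rng):
        for _ in range(200):
            b = Box(*rng.uniform(-5, 5, 2), *rng.uniform(0.1, 4, 2))
            ratio = rng.uniform(0.2, 1.8)
            ib = inner_box(b, ratio)
            area = (ib.b_r - ib.b_l) * (ib.b_b - ib.b_t)
            assert area == pytest.approx(b.w * b.h * ratio**2, rel=1e-12)

    def test_rejects_nonpositive_ratio(self):
        with pytest.raises(ValueError):
            inner_box(Box(0, 0, 1, 1), 0.0)


class TestInnerIoU:
    def test_identical_boxes_any_ratio(self):
        b = Box(1, 2, 3, 4)
        for ratio in (0.5, 1.0, 1.5):
            assert inner_iou(b, b, ratio) == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_boxes_zero(self):
        assert inner_iou(Box(0, 0, 1, 1), Box(10, 10, 1, 1), 1.0) == 0.0
        # the clamp matters: unclamped Eq. would give a positive product
        assert inner_iou(Box(0, 0, 1, 1), Box(10, 10, 1, 1), 0.5) == 0.0

    def test_hand_case_third(self):
        assert inner_iou(Box(0, 0, 2, 2), Box(1, 0, 2, 2), 1.0) == pytest.approx(
            1 / 3, abs=1e-9)

    def test_ratio_one_equals_iou_exhaustive_grid(self):
        """inner_iou(., ., 1) == IoU on an exhaustive small-grid box sweep."""
        centers = range(4)
        sizes = (1, 2, 3)
        for x1 in centers:
            for y1 in centers:
                for w1 in sizes:
                    for h1 in sizes:
                        b1 = Box(x1, y1, w1, h1)
                        b2 = Box(2, 1, 2, 2)
                        want = iou_xyxy_oracle(b1, b2)
                        assert inner_iou(b1, b2, 1.0) == pytest.approx(want, abs=1e-9)
                        assert iou(b1, b2) == pytest.approx(want, abs=1e-9)

    def test_scaled_ratio_matches_oracle(self, rng):
        for _ in range(200):
            b1 = Box(*rng.uniform(-2, 2, 2), *rng.uniform(0.5, 3, 2))
            b2 = Box(*rng.uniform(-2, 2, 2), *rng.uniform(0.5, 3, 2))
            ratio = rng.uniform(0.3, 1.7)
            assert inner_iou(b1, b2, ratio) == pytest.approx(
                iou_xyxy_oracle(b1, b2, ratio), abs=1e-9)

    def test_monotone_in_center_distance(self):
        base = Box(0, 0, 2, 2)
        vals = [inner_iou(Box(d, 0, 2, 2), base, 0.8) for d in np.linspace(0, 4, 50)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_agrees_with_rasterization(self):
        b1, b2 = Box(0, 0, 2, 2), Box(0.7, 0.4, 1.5, 2.5)
        assert inner_iou(b1, b2, 1.0) == pytest.approx(raster_iou(b1, b2), abs=0.01)


class TestCIoU:
    def test_identical_boxes_zero(self):
        b = Box(2, 3, 4, 1)
        assert ciou_loss(b, b) == pytest.approx(0.0, abs=1e-9)

    def test_concentric_same_aspect_reduces_to_one_minus_iou(self):
        pred, gt = Box(0, 0, 1, 1), Box(0, 0, 2, 2)
        # distance and aspect terms vanish; IoU = 1/4
        assert ciou_loss(pred, gt) == pytest.approx(0.75, abs=1e-9)

    def test_hand_case(self):
        # IoU = 1/3, rho^2 = 1, enclosing box 3 x 2 so c^2 = 13, v = 0
        got = ciou_loss(Box(0, 0, 2, 2), Box(1, 0, 2, 2))
        assert got == pytest.approx(2 / 3 + 1 / 13, abs=1e-9)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            ciou_loss(Box(0, 0, 0, 1), Box(0, 0, 1, 1))


class TestInnerCIoU:
    def test_identical_boxes_zero_any_ratio(self):
        b = Box(5, 5, 2, 3)
        for ratio in (0.5, 1.0, 1.25):
            assert inner_ciou_loss(b, b, ratio) == pytest.approx(0.0, abs=1e-9)

    def test_ratio_one_equals_ciou(self, rng):
        for _ in range(100):
            p = Box(*rng.uniform(-2, 2, 2), *rng.uniform(0.5, 3, 2))
            g = Box(*rng.uniform(-2, 2, 2), *rng.uniform(0.5, 3, 2))
            assert inner_ciou_loss(p, g, 1.0) == pytest.approx(
                ciou_loss(p, g), abs=1e-9)

    def test_hand_composition(self):
        p, g = Box(0, 0, 2, 2), Box(1, 0, 2, 2)
        want = ciou_loss(p, g) + 1 / 3 - iou_xyxy_oracle(p, g, 0.5)
        assert inner_ciou_loss(p, g, 0.5) == pytest.approx(want, abs=1e-9)

    def test_variants_agree_algebraically(self, rng):
        for _ in range(50):
            p = Box(*rng.uniform(-2, 2, 2), *rng.uniform(0.5, 3, 2))
            g = Box(*rng.uniform(-2, 2, 2), *rng.uniform(0.5, 3, 2))
            r = rng.uniform(0.3, 1.7)
            assert inner_ciou_loss(p, g, r, "paper") == pytest.approx(
                inner_ciou_loss(p, g, r, "reference"), abs=1e-9)

    def test_non_negative_for_ratio_at_most_one(self, rng):
        for _ in range(500):
            p = Box(*rng.uniform(-3, 3, 2), *rng.uniform(0.2, 4, 2))
            g = Box(*rng.uniform(-3, 3, 2), *rng.uniform(0.2, 4, 2))
            ratio = rng.uniform(0.2, 1.0)
            assert inner_ciou_loss(p, g, ratio) >= -1e-12


_coord = st.floats(-5, 5, allow_nan=False)
_size = st.floats(0.1, 4, allow_nan=False)


@settings(derandomize=True, max_examples=200, deadline=None)
@given(_coord, _coord, _size, _size, _coord, _coord, _size, _size,
       st.floats(0.1, 2, allow_nan=False))
def test_inner_iou_bounded_and_symmetric(x1, y1, w1, h1, x2, y2, w2, h2, ratio):
    """inner_iou lies in [0, 1] and is symmetric in its box arguments."""
    a, b = Box(x1, y1, w1, h1), Box(x2, y2, w2, h2)
    v = inner_iou(a, b, ratio)
    assert -1e-12 <= v <= 1 + 1e-12
    assert v == pytest.approx(inner_iou(b, a, ratio), abs=1e-12)


class TestRatioSchedule:
    def test_endpoints_and_midpoint(self):
        s = RatioSchedule(1.25, 0.75, horizon=100)
        assert ratio_at(s, 0) == 1.25
        assert ratio_at(s, 100) == 0.75
        assert ratio_at(s, 50) == pytest.approx(1.0)

    def test_clamps_outside_horizon(self):
        s = RatioSchedule(1.2, 0.8, horizon=10)
        assert ratio_at(s, -5) == 1.2
        assert ratio_at(s, 25) == 0.8

    def test_constant_schedule(self):
        s = RatioSchedule(1.0, 1.0, horizon=10)
        assert all(ratio_at(s, t) == 1.0 for t in range(11))

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            RatioSchedule(0.5, 1.0)
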