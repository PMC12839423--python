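"""Compound-Eye Apposition Concatenation (CEAC).

Inspired by the apposition compound eye — many ommatidia sampling a scene
in parallel — CEAC tiles ``x**2`` input images into one square mosaic so a
single-pass detector processes them together, then reverse-maps mosaic-frame
detections back into each sub-image's own normalized coordinate system.

Coordinate conventions
----------------------
* Labels follow the YOLO text convention: ``class cx cy w h`` with all four
  box coordinates normalized to [0, 1]; pixel origin is the top-left corner,
  x rightward, y downward, continuous (no half-pixel offset).
* Denormalization to mosaic pixels: ``a_abs = a * W``, ``b_abs = b * H``,
  ``w_abs = w * W``, ``h_abs = h * H``.
* Re-normalization into tile (i, j) with top-left (c_start, d_start)::

      a = (a_abs - c_start) / W_tile      b = (b_abs - d_start) / H_tile
      w = w_abs / W_tile                  h = h_abs / H_tile

* A box belongs to the tile containing its center; tiles are half-open
  intervals ``[start, start + size)`` so a center exactly on a seam goes to
  the right/bottom neighbour. Boxes straddling a seam are clipped to the
  assigned tile and dropped when the clipped area falls below a retention
  fraction of the original (default 10%).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "NormalizedLabel",
    "PixelBox",
    "MosaicLayout",
    "DetectionRecord",
    "TileDetection",
    "InvalidGeometryError",
    "TileAssignmentError",
    "denormalize",
    "normalize",
    "renormalize_to_tile",
    "tile_label_to_mosaic",
    "compose_mosaic",
    "split_detections",
]


class InvalidGeometryError(ValueError):
    """Non-positive canvas/tile dimensions or malformed boxes."""


class TileAssignmentError(ValueError):
    """A box center that lies outside every tile of the layout."""


@dataclass(frozen=True)
class NormalizedLabel:
    """A YOLO-convention box: class id plus center/size as image fractions."""

    class_id: int
    a: float  # center x fraction
    b: float  # center y fraction
    w: float  # width fraction
    h: float  # height fraction

    def validate(self, tol: float = 1e-9) -> "NormalizedLabel":
        if self.class_id < 0:
            raise ValueError(f"negative class id {self.class_id}")
        for name, v in (("a", self.a), ("b", self.b), ("w", self.w), ("h", self.h)):
            if not (-tol <= v <= 1.0 + tol):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.w <= 0 or self.h <= 0:
            raise ValueError("box width/height must be positive")
        for edge in (self.a - self.w / 2, self.a + self.w / 2,
                     self.b - self.h / 2, self.b + self.h / 2):
            if not (-tol <= edge <= 1.0 + tol):
                raise ValueError("box extends outside the unit square")
        return self


@dataclass(frozen=True)
class PixelBox:
    """Center/size box in pixel units of some frame."""

    a_abs: float
    b_abs: float
    w_abs: float
    h_abs: float

    def validate(self) -> "PixelBox":
        if min(self.a_abs, self.b_abs) < 0 or self.w_abs <= 0 or self.h_abs <= 0:
            raise InvalidGeometryError(f"malformed pixel box {self}")
        return self

    @property
    def area(self) -> float:
        return self.w_abs * self.h_abs


@dataclass(frozen=True)
class MosaicLayout:
    """Geometric contract between mosaic composition and splitting.

    ``x`` tiles per side, gap-free equal tiling: ``W_tile * x == W_orig`` and
    ``H_tile * x == H_orig``; tile (i, j) (row i, column j, row-major) has its
    top-left corner at ``(c_start, d_start) = (j * W_tile, i * H_tile)``.
    """

    x: int
    W_orig: int
    H_orig: int
    W_tile: int = field(default=0)
    H_tile: int = field(default=0)

    def __post_init__(self):
        if self.x < 1:
            raise InvalidGeometryError(f"grid size x={self.x} must be >= 1")
        if self.W_orig <= 0 or self.H_orig <= 0:
            raise InvalidGeometryError("canvas dimensions must be positive")
        if self.W_tile == 0:
            object.__setattr__(self, "W_tile", self.W_orig // self.x)
        if self.H_tile == 0:
            object.__setattr__(self, "H_tile", self.H_orig // self.x)
        if self.W_tile * self.x != self.W_orig or self.H_tile * self.x != self.H_orig:
            raise InvalidGeometryError(
                f"tiles {self.W_tile}x{self.H_tile} x {self.x} do not tile "
                f"{self.W_orig}x{self.H_orig} exactly"
            )

    @property
    def n_tiles(self) -> int:
        return self.x * self.x

    def origin(self, i: int, j: int) -> tuple[float, float]:
        """Top-left (c_start, d_start) of tile at row i, column j."""
        if not (0 <= i < self.x and 0 <= j < self.x):
            raise TileAssignmentError(f"tile ({i},{j}) outside {self.x}x{self.x} grid")
        return float(j * self.W_tile), float(i * self.H_tile)

    def tile_of(self, a_abs: float, b_abs: float) -> tuple[int, int]:
        """Tile containing a point; seams resolve to the larger index."""
        if not (0 <= a_abs <= self.W_orig and 0 <= b_abs <= self.H_orig):
            raise TileAssignmentError(
                f"point ({a_abs}, {b_abs}) outside {self.W_orig}x{self.H_orig} canvas"
            )
        j = min(int(a_abs // self.W_tile), self.x - 1)
        i = min(int(b_abs // self.H_tile), self.x - 1)
        return i, j

    def to_dict(self) -> dict:
        return {"x": self.x, "W_orig": self.W_orig, "H_orig": self.H_orig,
                "W_tile": self.W_tile, "H_tile": self.H_tile}

    @classmethod
    def from_dict(cls, d: dict) -> "MosaicLayout":
        return cls(**{k: int(d[k]) for k in ("x", "W_orig", "H_orig", "W_tile", "H_tile")})


@dataclass(frozen=True)
class DetectionRecord:
    """A detection in mosaic pixel coordinates."""

    class_id: int
    confidence: float
    box: PixelBox
    frame: str = "mosaic"

    def validate(self) -> "DetectionRecord":
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")
        self.box.validate()
        return self


@dataclass(frozen=True)
class TileDetection:
    """A detection re-expressed in one tile's normalized frame."""

    tile: tuple[int, int]
    confidence: float
    label: NormalizedLabel


# ---------------------------------------------------------------------------
# coordinate transforms
# ---------------------------------------------------------------------------


def denormalize(label: NormalizedLabel, canvas_w: float, canvas_h: float) -> PixelBox:
    """Normalized label -> absolute pixel box on a canvas."""
    if canvas_w <= 0 or canvas_h <= 0:
        raise InvalidGeometryError(f"canvas {canvas_w}x{canvas_h} must be positive")
    return PixelBox(
        a_abs=label.a * canvas_w,
        b_abs=label.b * canvas_h,
        w_abs=label.w * canvas_w,
        h_abs=label.h * canvas_h,
    )


def normalize(box: PixelBox, class_id: int, canvas_w: float, canvas_h: float) -> NormalizedLabel:
    """Absolute pixel box -> normalized label (inverse of :func:`denormalize`)."""
    if canvas_w <= 0 or canvas_h <= 0:
        raise InvalidGeometryError(f"canvas {canvas_w}x{canvas_h} must be positive")
    return NormalizedLabel(
        class_id=class_id,
        a=box.a_abs / canvas_w,
        b=box.b_abs / canvas_h,
        w=box.w_abs / canvas_w,
        h=box.h_abs / canvas_h,
    )


def _clip_unit(a: float, b: float, w: float, h: float):
    """Clip a center/size box to the unit square; return None if empty."""
    left = max(a - w / 2, 0.0)
    right = min(a + w / 2, 1.0)
    top = max(b - h / 2, 0.0)
    bottom = min(b + h / 2, 1.0)
    if right <= left or bottom <= top:
        return None
    return ((left + right) / 2, (top + bottom) / 2, right - left, bottom - top)


def renormalize_to_tile(box: PixelBox, layout: MosaicLayout,
                        tile: tuple[int, int] | None = None, class_id: int = 0,
                        clip: bool = True) -> tuple[tuple[int, int], NormalizedLabel]:
    """Re-express a mosaic-frame pixel box in one tile's normalized frame.

    The tile defaults to the one containing the box center; passing a tile
    whose interior does not contain the center raises
    :class:`TileAssignmentError`.
    """
    box.validate()
    auto = layout.tile_of(box.a_abs, box.b_abs)
    if tile is None:
        tile = auto
    elif tile != auto:
        raise TileAssignmentError(
            f"box center ({box.a_abs}, {box.b_abs}) lies in tile {auto}, not {tile}"
        )
    c_start, d_start = layout.origin(*tile)
    a = (box.a_abs - c_start) / layout.W_tile
    b = (box.b_abs - d_start) / layout.H_tile
    w = box.w_abs / layout.W_tile
    h = box.h_abs / layout.H_tile
    if clip:
        clipped = _clip_unit(a, b, w, h)
        if clipped is None:  # degenerate after clipping (center on a seam edge)
            raise TileAssignmentError("box clips to zero area inside its tile")
        a, b, w, h = clipped
    return tile, NormalizedLabel(class_id=class_id, a=a, b=b, w=w, h=h)


def tile_label_to_mosaic(label: NormalizedLabel, layout: MosaicLayout,
                         tile: tuple[int, int]) -> NormalizedLabel:
    """Inverse map: a tile-frame normalized label -> mosaic-frame normalized."""
    i, j = tile
    layout.origin(i, j)  # bounds check
    return NormalizedLabel(
        class_id=label.class_id,
        a=(j + label.a) / layout.x,
        b=(i + label.b) / layout.x,
        w=label.w / layout.x,
        h=label.h / layout.x,
    )


# ---------------------------------------------------------------------------
# mosaic composition / detection splitting
# ---------------------------------------------------------------------------


def _resize(img: np.ndarray, h: int, w: int) -> np.ndarray:
    if img.shape[0] == h and img.shape[1] == w:
        return img
    from skimage.transform import resize

    out = resize(img, (h, w) + img.shape[2:], order=1, preserve_range=True,
                 anti_aliasing=img.shape[0] > h)
    return out.astype(img.dtype)


def compose_mosaic(items: Sequence[tuple[np.ndarray, Sequence[NormalizedLabel]]],
                   x: int, canvas_size: tuple[int, int] | None = None
                   ) -> tuple[np.ndarray, list[NormalizedLabel], MosaicLayout]:
    """Tile ``x**2`` (image, labels) pairs into one mosaic.

    Tile (i, j) receives item ``i*x + j`` (row-major). Every input label is
    carried to the mosaic frame by the inverse of the tile re-normalization,
    so the label count is conserved exactly. Inputs that do not match the
    tile dimensions are resized (tiles are always equal-sized and gap-free).
    """
    if x < 1:
        raise InvalidGeometryError(f"grid size x={x} must be >= 1")
    items = list(items)
    if len(items) != x * x:
        raise InvalidGeometryError(f"expected {x * x} items for x={x}, got {len(items)}")
    h0, w0 = items[0][0].shape[:2]
    for img, _ in items:
        if img.shape[:2] != (h0, w0):
            raise InvalidGeometryError("all input images must share dimensions")
        if img.ndim != items[0][0].ndim:
            raise InvalidGeometryError("mixed channel layouts")
    if canvas_size is None:
        H_orig, W_orig = h0 * x, w0 * x
    else:
        W_orig, H_orig = canvas_size
        if W_orig % x or H_orig % x:
            raise InvalidGeometryError(f"canvas {canvas_size} not divisible by x={x}")
    layout = MosaicLayout(x=x, W_orig=W_orig, H_orig=H_orig)
    extra = items[0][0].shape[2:]
    mosaic = np.zeros((H_orig, W_orig) + extra, dtype=items[0][0].dtype)
    mosaic_labels: list[NormalizedLabel] = []
    for idx, (img, labels) in enumerate(items):
        i, j = divmod(idx, x)
        tile_img = _resize(img, layout.H_tile, layout.W_tile)
        c0, d0 = layout.origin(i, j)
        mosaic[int(d0):int(d0) + layout.H_tile, int(c0):int(c0) + layout.W_tile] = tile_img
        for lab in labels:
            mosaic_labels.append(tile_label_to_mosaic(lab.validate(), layout, (i, j)))
    return mosaic, mosaic_labels, layout


def split_detections(dets: Sequence[DetectionRecord], layout: MosaicLayout,
                     retention: float = 0.1
                     ) -> dict[tuple[int, int], list[TileDetection]]:
    """Back-map mosaic-frame detections into per-tile normalized frames.

    Each detection goes to the tile containing its center, is clipped to the
    tile, and is dropped when the clipped area retains less than
    ``retention`` of the original box area.
    """
    out: dict[tuple[int, int], list[TileDetection]] = {
        (i, j): [] for i in range(layout.x) for j in range(layout.x)
    }
    for det in dets:
        det.validate()
        tile = layout.tile_of(det.box.a_abs, det.box.b_abs)
        try:
            _, label = renormalize_to_tile(det.box, layout, tile, det.class_id, clip=True)
        except TileAssignmentError:
            continue  # clipped away entirely
        tile_area_px = (label.w * layout.W_tile) * (label.h * layout.H_tile)
        if tile_area_px < retention * det.box.area:
            continue
        out[tile].append(TileDetection(tile=tile, confidence=det.confidence, label=label))
    return out
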