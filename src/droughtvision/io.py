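"""Readers/writers for the YOLO plain-text label convention.

Label files carry one ``class cx cy w h`` row per object; prediction files
carry ``class conf cx cy w h``. All box values are fractions of the image
dimensions.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image

from .ceac import NormalizedLabel

__all__ = [
    "read_labels",
    "write_labels",
    "read_predictions",
    "write_predictions",
    "load_image",
    "save_image",
]


def read_labels(path: str | Path) -> list[NormalizedLabel]:
    labels = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 5:
            raise ValueError(f"{path}:{ln}: expected 5 fields, got {len(parts)}")
        cid, a, b, w, h = int(parts[0]), *map(float, parts[1:])
        labels.append(NormalizedLabel(cid, a, b, w, h).validate(tol=1e-6))
    return labels


def write_labels(path: str | Path, labels: Iterable[NormalizedLabel]) -> None:
    lines = [f"{l.class_id} {l.a:.9f} {l.b:.9f} {l.w:.9f} {l.h:.9f}" for l in labels]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_predictions(path: str | Path) -> list[tuple[float, NormalizedLabel]]:
    """Rows of ``class conf cx cy w h`` -> (confidence, label) pairs."""
    preds = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 6:
            raise ValueError(f"{path}:{ln}: expected 6 fields, got {len(parts)}")
        cid = int(parts[0])
        conf, a, b, w, h = map(float, parts[1:])
        preds.append((conf, NormalizedLabel(cid, a, b, w, h)))
    return preds


def write_predictions(path: str | Path,
                      preds: Sequence[tuple[float, NormalizedLabel]]) -> None:
    lines = [
        f"{l.class_id} {c:.6f} {l.a:.9f} {l.b:.9f} {l.w:.9f} {l.h:.9f}"
        for c, l in preds
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def load_image(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path))


def save_image(path: str | Path, img: np.ndarray) -> None:
    if img.dtype != np.uint8:
        img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    Image.fromarray(img).save(path)
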