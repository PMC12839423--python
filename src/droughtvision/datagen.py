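"""Synthetic Fv/Fm drought scenes, the augmentation suite and dataset builds.

The generator emulates chlorophyll-fluorescence (Fv/Fm) maps of potted tea
seedlings under four drought grades. Fv/Fm — the maximum photochemical
quantum efficiency of photosystem II — declines monotonically with drought
severity, so scenes are grayscale canvases of elliptical "leaf" blobs whose
interior intensity is drawn around a grade-specific mean (defaults 0.80 /
0.68 / 0.55 / 0.40 for levels 1-4) over a dim background, with tight
axis-aligned YOLO boxes labelled by the grade class.

Drought grading follows the soil-relative-humidity intervals::

    W >= 60%        level 1  (no drought)
    50% <= W < 60%  level 2  (mild)
    40% <= W < 50%  level 3  (moderate)
    30% <= W < 40%  level 4  (severe)

Values below 30% fall outside the grading scale and raise an error rather
than clamping to the severest grade.

Dataset construction is split-then-augment: originals are divided into
train/test/val FIRST and each original is expanded into (1 + variants)
images inside its own split, so no source image leaks across splits. With
324 originals, a 20% validation hold-out, an 8:2 train:test split of the
remainder and 12 variants per original, the splits come to 2691/676/845
(4212 images in total).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from .ceac import NormalizedLabel
from . import io as dio

__all__ = [
    "CLASS_NAMES",
    "DroughtGrade",
    "GRADES",
    "OutOfScaleError",
    "grade_from_humidity",
    "SceneSpec",
    "generate_scene",
    "AugmentOp",
    "AUGMENT_KINDS",
    "augment",
    "d4_apply_labels",
    "d4_inverse",
    "build_dataset",
]

CLASS_NAMES = ("no_drought", "mild_drought", "moderate_drought", "severe_drought")


class OutOfScaleError(ValueError):
    """Soil relative humidity below the grading scale (W < 30%)."""


@dataclass(frozen=True)
class DroughtGrade:
    severity: str
    level: int           # 1..4
    w_low: float         # inclusive lower bound of the humidity interval, %
    w_high: float | None  # exclusive upper bound; None = unbounded above

    @property
    def class_id(self) -> int:
        return self.level - 1


GRADES = (
    DroughtGrade("No Drought", 1, 60.0, None),
    DroughtGrade("Mild Drought", 2, 50.0, 60.0),
    DroughtGrade("Moderate Drought", 3, 40.0, 50.0),
    DroughtGrade("Severe Drought", 4, 30.0, 40.0),
)


def grade_from_humidity(w: float) -> DroughtGrade:
    """Map soil relative humidity (percent) to a drought grade.

    Intervals are closed below, open above; W = 60 is grade 1.
    """
    if not (0.0 <= w <= 100.0):
        raise ValueError(f"soil relative humidity {w}% outside [0, 100]")
    if w < 30.0:
        raise OutOfScaleError(
            f"W={w}% is below the 30% floor of the grading scale"
        )
    for g in GRADES:
        if w >= g.w_low and (g.w_high is None or w < g.w_high):
            return g
    raise AssertionError("unreachable: intervals partition [30, 100]")


# ---------------------------------------------------------------------------
# scene synthesis
# ---------------------------------------------------------------------------

# Fv/Fm-like interior means per level; strictly decreasing with severity.
DEFAULT_GRADE_MEANS = {1: 0.80, 2: 0.68, 3: 0.55, 4: 0.40}


@dataclass(frozen=True)
class SceneSpec:
    side: int = 640
    leaf_count: tuple[int, int] = (2, 6)       # inclusive range per scene
    grade_means: dict = field(default_factory=lambda: dict(DEFAULT_GRADE_MEANS))
    grade_spread: float = 0.04                 # sd of per-leaf mean intensity
    background: float = 0.05
    noise_sigma: float = 0.015
    leaf_axes_frac: tuple[float, float] = (0.05, 0.12)  # semi-axes / side

    def validate(self) -> "SceneSpec":
        means = [self.grade_means[k] for k in sorted(self.grade_means)]
        if any(not 0 <= m <= 1 for m in means):
            raise ValueError("grade intensity means must lie in [0, 1]")
        if any(a <= b for a, b in zip(means, means[1:])):
            raise ValueError("grade means must strictly decrease with level")
        if self.side < 16 or self.leaf_count[0] < 1:
            raise ValueError("degenerate scene spec")
        return self


def generate_scene(spec: SceneSpec, grade: DroughtGrade, seed: int
                   ) -> tuple[np.ndarray, list[NormalizedLabel]]:
    """Render one grayscale Fv/Fm-style scene with YOLO labels.

    Returns a uint8 (side, side) image and the list of tight boxes (one per
    leaf blob, class = grade level - 1). Bit-identical for equal seeds.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    n = spec.side
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    img = np.full((n, n), spec.background)
    # gentle illumination gradient, as flat-field imperfections would give
    gx, gy = rng.uniform(-0.02, 0.02, 2)
    img += gx * (xx / n - 0.5) + gy * (yy / n - 0.5)
    labels: list[NormalizedLabel] = []
    k = int(rng.integers(spec.leaf_count[0], spec.leaf_count[1] + 1))
    lo, hi = spec.leaf_axes_frac
    for _ in range(k):
        ax = rng.uniform(lo, hi) * n   # semi-axis, px
        ay = rng.uniform(lo, hi) * n
        cx = rng.uniform(ax + 1, n - ax - 1)
        cy = rng.uniform(ay + 1, n - ay - 1)
        mean = np.clip(rng.normal(spec.grade_means[grade.level], spec.grade_spread),
                       0.02, 0.98)
        mask = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0
        # radial falloff toward the leaf margin, as real Fv/Fm maps show
        rad = np.sqrt(((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2)
        blob = mean * (1.0 - 0.25 * rad**2)
        img = np.where(mask, np.maximum(img, blob), img)
        labels.append(NormalizedLabel(
            class_id=grade.class_id,
            a=cx / n, b=cy / n, w=2 * ax / n, h=2 * ay / n,
        ).validate(tol=1e-9))
    img += rng.normal(0.0, spec.noise_sigma, img.shape)
    img8 = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
    return img8, labels


# ---------------------------------------------------------------------------
# augmentation suite
# ---------------------------------------------------------------------------

AUGMENT_KINDS = ("hsv", "mean_blur", "gaussian_blur", "median_blur",
                 "cutout", "d4", "brightness")

CUTOUT_COUNT_RANGE = (1, 6)
CUTOUT_AREA_RANGE = (0.05, 0.40)


@dataclass(frozen=True)
class AugmentOp:
    kind: str
    params: dict = field(default_factory=dict)

    def validate(self) -> "AugmentOp":
        if self.kind not in AUGMENT_KINDS:
            raise ValueError(f"unknown augmentation kind {self.kind!r}")
        if self.kind == "d4" and "element" in self.params:
            if self.params["element"] not in range(8):
                raise ValueError("d4 element must be one of 0..7")
        if self.kind == "cutout":
            n = self.params.get("count")
            if n is not None and not (CUTOUT_COUNT_RANGE[0] <= n <= CUTOUT_COUNT_RANGE[1]):
                raise ValueError("cutout count must lie in 1..6")
            f = self.params.get("area_fraction")
            if f is not None and not (CUTOUT_AREA_RANGE[0] <= f <= CUTOUT_AREA_RANGE[1]):
                raise ValueError("cutout area fraction must lie in [0.05, 0.40]")
        return self


def _d4_point(a: float, b: float, element: int) -> tuple[float, float, bool]:
    """Apply group element (flip-then-rotations) to a unit-square point.

    Element = r + 4*m: optional horizontal mirror (m) followed by r
    counter-clockwise quarter turns. Returns (a', b', swapped_axes).
    """
    r, m = element % 4, element // 4
    if m:
        a = 1.0 - a
    swapped = False
    for _ in range(r):
        a, b = b, 1.0 - a  # 90 deg CCW
        swapped = not swapped
    return a, b, swapped


def d4_apply_labels(labels, element: int):
    out = []
    for lab in labels:
        a, b, swapped = _d4_point(lab.a, lab.b, element)
        w, h = (lab.h, lab.w) if swapped else (lab.w, lab.h)
        out.append(NormalizedLabel(lab.class_id, a, b, w, h))
    return out


def _d4_image(img: np.ndarray, element: int) -> np.ndarray:
    r, m = element % 4, element // 4
    if m:
        img = img[:, ::-1]
    return np.rot90(img, r)


def d4_inverse(element: int) -> int:
    """Group inverse, found by composing the point maps."""
    for cand in range(8):
        a, b, _ = _d4_point(0.3, 0.2, element)
        a2, b2, _ = _d4_point(a, b, cand)
        if abs(a2 - 0.3) < 1e-12 and abs(b2 - 0.2) < 1e-12:
            # verify on a second, asymmetric probe
            a, b, _ = _d4_point(0.9, 0.1, element)
            a2, b2, _ = _d4_point(a, b, cand)
            if abs(a2 - 0.9) < 1e-12 and abs(b2 - 0.1) < 1e-12:
                return cand
    raise AssertionError("unreachable: D4 is a group")


def _cutout(img: np.ndarray, rng: np.random.Generator, count: int,
            frac: float) -> np.ndarray:
    """Zero out ``count`` rectangles occluding ``frac`` of the image.

    Rectangle sides are quantized to pixels, so the last patch's height is
    nudged until the summed area lands inside the admissible [5%, 40%] band;
    placement avoids overlap (rejection sampling) so the painted union equals
    the summed patch area whenever a free spot exists.
    """
    H, W = img.shape
    lo = int(np.ceil(CUTOUT_AREA_RANGE[0] * H * W))
    hi = int(np.floor(CUTOUT_AREA_RANGE[1] * H * W))
    target = int(round(frac * H * W))
    dims = []
    remaining = target
    for i in range(count):
        goal = max(1, remaining // (count - i))
        aspect = rng.uniform(0.5, 2.0)
        pw = int(np.clip(round(np.sqrt(goal * aspect)), 1, W))
        ph = int(np.clip(round(goal / pw), 1, H))
        dims.append([pw, ph])
        remaining -= pw * ph
    total = sum(pw * ph for pw, ph in dims)
    pw_last = dims[-1][0]
    while total < lo and dims[-1][1] < H:
        dims[-1][1] += 1
        total += pw_last
    while total > hi and dims[-1][1] > 1:
        dims[-1][1] -= 1
        total -= pw_last
    out = img.copy()
    mask = np.zeros((H, W), dtype=bool)
    for pw, ph in dims:
        for _ in range(200):
            x0 = int(rng.integers(0, W - pw + 1))
            y0 = int(rng.integers(0, H - ph + 1))
            if not mask[y0:y0 + ph, x0:x0 + pw].any():
                break
        mask[y0:y0 + ph, x0:x0 + pw] = True
        out[y0:y0 + ph, x0:x0 + pw] = 0.0
    return out


def _pseudo_color(gray: np.ndarray) -> np.ndarray:
    """Map [0,1] gray to a green-to-red false-color rendering (H, W, 3)."""
    g = np.clip(gray, 0, 1)
    return np.stack([1.0 - g, g, 0.15 * np.ones_like(g)], axis=-1)


def augment(image: np.ndarray, labels, op: AugmentOp, seed: int
            ) -> tuple[np.ndarray, list[NormalizedLabel]]:
    """Apply one augmentation; photometric ops leave labels untouched.

    ``image`` is uint8 grayscale (H, W). Unpinned op parameters are drawn
    from a generator seeded with ``seed``.
    """
    op.validate()
    rng = np.random.default_rng(seed)
    labels = list(labels)
    img = image.astype(float) / 255.0
    kind = op.kind

    if kind == "d4":
        element = op.params.get("element", int(rng.integers(0, 8)))
        out = _d4_image(image, element).copy()
        return out, d4_apply_labels(labels, element)

    if kind == "hsv":
        # Fv/Fm maps are single-channel; HSV jitter operates on a pseudo-color
        # rendering and converts back to luminance.
        from skimage.color import hsv2rgb, rgb2gray, rgb2hsv

        rgb = _pseudo_color(img)
        hsv = rgb2hsv(rgb)
        hsv[..., 0] = (hsv[..., 0] + rng.uniform(-0.03, 0.03)) % 1.0
        hsv[..., 1] = np.clip(hsv[..., 1] * rng.uniform(0.7, 1.3), 0, 1)
        hsv[..., 2] = np.clip(hsv[..., 2] * rng.uniform(0.8, 1.2), 0, 1)
        out = rgb2gray(hsv2rgb(hsv))
    elif kind == "mean_blur":
        k = op.params.get("kernel", int(rng.choice([3, 5, 7])))
        out = ndi.uniform_filter(img, size=k, mode="reflect")
    elif kind == "gaussian_blur":
        sigma = op.params.get("sigma", float(rng.uniform(0.5, 1.5)))
        out = ndi.gaussian_filter(img, sigma=sigma, mode="reflect")
    elif kind == "median_blur":
        k = op.params.get("kernel", int(rng.choice([3, 5])))
        out = ndi.median_filter(img, size=k, mode="reflect")
    elif kind == "brightness":
        gain = op.params.get("gain", float(rng.uniform(0.7, 1.3)))
        out = np.clip(img * gain, 0, 1)
    elif kind == "cutout":
        count = op.params.get(
            "count", int(rng.integers(CUTOUT_COUNT_RANGE[0], CUTOUT_COUNT_RANGE[1] + 1)))
        frac = op.params.get("area_fraction", float(rng.uniform(*CUTOUT_AREA_RANGE)))
        out = _cutout(img, rng, count, frac)
    else:  # pragma: no cover - guarded by validate()
        raise AssertionError(kind)

    return np.clip(np.round(out * 255.0), 0, 255).astype(np.uint8), labels


def _sample_op(rng: np.random.Generator) -> AugmentOp:
    return AugmentOp(kind=str(rng.choice(AUGMENT_KINDS)))


# ---------------------------------------------------------------------------
# dataset construction (split first, then augment)
# ---------------------------------------------------------------------------


def build_dataset(n_originals: int = 324, val_frac: float = 0.2,
                  train_test_ratio: tuple[int, int] = (8, 2),
                  per_image_variants: int = 12, seed: int = 0,
                  out_dir: str | Path | None = None,
                  scene_spec: SceneSpec | None = None) -> dict:
    """Plan (and optionally materialize) a split-then-augment dataset.

    Originals are split into val (``val_frac``) and a remainder divided
    train:test by ``train_test_ratio`` BEFORE augmentation; each original
    then contributes (1 + per_image_variants) images to its own split. The
    returned manifest records every file's source image, grade and
    augmentation so leakage-freedom can be asserted mechanically. When
    ``out_dir`` is given the YOLO tree (images/ + labels/ per split, dataset
    YAML, manifest JSON) is written with synthetic scenes; otherwise only the
    manifest is produced.
    """
    if n_originals < len(GRADES):
        raise ValueError("need at least one original per grade")
    if not (0.0 < val_frac < 1.0):
        raise ValueError("val_frac must lie in (0, 1)")
    if per_image_variants < 0:
        raise ValueError("per_image_variants must be non-negative")
    rng = np.random.default_rng(seed)

    # round-robin grade assignment, then a seeded shuffle
    levels = np.array([GRADES[i % 4].level for i in range(n_originals)])
    rng.shuffle(levels)

    order = rng.permutation(n_originals)
    n_val = int(round(n_originals * val_frac))
    rest = n_originals - n_val
    n_train = int(round(rest * train_test_ratio[0] / sum(train_test_ratio)))
    n_test = rest - n_train
    if min(n_val, n_train, n_test) == 0:
        raise ValueError("a split came out empty; adjust sizes")
    split_of = {}
    for pos, idx in enumerate(order):
        split_of[int(idx)] = ("val" if pos < n_val
                              else "train" if pos < n_val + n_train else "test")

    entries = []
    for idx in range(n_originals):
        grade = GRADES[int(levels[idx]) - 1]
        split = split_of[idx]
        stem = f"scene_{idx:04d}"
        entries.append({"file": f"{stem}", "split": split, "source": stem,
                        "grade": grade.level, "op": None,
                        "seed": int(seed * 100003 + idx)})
        for v in range(per_image_variants):
            op = _sample_op(rng)
            entries.append({
                "file": f"{stem}_aug{v:02d}", "split": split, "source": stem,
                "grade": grade.level, "op": op.kind,
                "seed": int((seed * 100003 + idx) * 31 + v + 1) % (2**31),
            })

    counts = {s: sum(1 for e in entries if e["split"] == s)
              for s in ("train", "test", "val")}
    manifest = {
        "n_originals": n_originals,
        "val_frac": val_frac,
        "train_test_ratio": list(train_test_ratio),
        "per_image_variants": per_image_variants,
        "seed": seed,
        "counts": counts,
        "total": len(entries),
        "class_names": list(CLASS_NAMES),
        "entries": entries,
    }

    if out_dir is not None:
        spec = (scene_spec or SceneSpec()).validate()
        out = Path(out_dir)
        for sub in ("images", "labels"):
            for split in ("train", "test", "val"):
                (out / sub / split).mkdir(parents=True, exist_ok=True)
        rendered: dict[str, tuple[np.ndarray, list]] = {}
        for e in entries:
            split = e["split"]
            if e["op"] is None:
                grade = GRADES[e["grade"] - 1]
                img, labels = generate_scene(spec, grade, e["seed"])
                rendered[e["source"]] = (img, labels)
            else:
                img0, labels0 = rendered[e["source"]]
                img, labels = augment(img0, labels0, AugmentOp(e["op"]), e["seed"])
            dio.save_image(out / "images" / split / f"{e['file']}.png", img)
            dio.write_labels(out / "labels" / split / f"{e['file']}.txt", labels)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        yaml_doc = (
            f"path: {out.resolve()}\n"
            "train: images/train\nval: images/val\ntest: images/test\n"
            f"nc: {len(CLASS_NAMES)}\n"
            "names:\n" + "".join(f"  {i}: {n}\n" for i, n in enumerate(CLASS_NAMES))
        )
        (out / "dataset.yaml").write_text(yaml_doc)

    return manifest
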