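"""Bounding-box geometry for single-shot multibox detection.

Coordinates are 0-based pixels with origin at the top-left; boxes are
half-open intervals [xmin, xmax) x [ymin, ymax).  Offset coding between a
ground-truth box and a default (anchor) box uses the standard center/size
parameterization (dcx/w, dcy/h, log width ratio, log height ratio) scaled by
the variances (0.1, 0.1, 0.2, 0.2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import BoxValidityError, ConfigurationError
from .stages import StageLabel

OFFSET_VARIANCES = (0.1, 0.1, 0.2, 0.2)


@dataclass(frozen=True)
class BoundingBox:
    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self):
        coords = (self.xmin, self.ymin, self.xmax, self.ymax)
        if not all(math.isfinite(c) for c in coords):
            raise BoxValidityError(f"non-finite box coordinates {coords}")
        if min(coords) < 0:
            raise BoxValidityError(f"negative box coordinates {coords}")
        if self.xmax <= self.xmin or self.ymax <= self.ymin:
            raise BoxValidityError(f"degenerate box {coords}")

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.xmin + self.xmax), 0.5 * (self.ymin + self.ymax))

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.xmin, self.ymin, self.xmax, self.ymax)


@dataclass(frozen=True)
class Detection:
    """A scored, staged detection box. Stage is always a lesion stage."""

    box: BoundingBox
    stage: StageLabel
    score: float

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0):
            raise BoxValidityError(f"detection score {self.score} outside [0, 1]")
        if self.stage is StageLabel.NORMAL:
            raise BoxValidityError("normal never labels a detection box")


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint, 1 when identical."""
    ix = max(0.0, min(a.xmax, b.xmax) - max(a.xmin, b.xmin))
    iy = max(0.0, min(a.ymax, b.ymax) - max(a.ymin, b.ymin))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


def iou_matrix(boxes_a: Sequence[BoundingBox], boxes_b: Sequence[BoundingBox]) -> np.ndarray:
    """Pairwise IoU, shape (len(a), len(b))."""
    if not boxes_a or not boxes_b:
        return np.zeros((len(boxes_a), len(boxes_b)))
    A = np.array([b.as_tuple() for b in boxes_a])
    B = np.array([b.as_tuple() for b in boxes_b])
    ix = np.clip(np.minimum(A[:, None, 2], B[None, :, 2]) - np.maximum(A[:, None, 0], B[None, :, 0]), 0, None)
    iy = np.clip(np.minimum(A[:, None, 3], B[None, :, 3]) - np.maximum(A[:, None, 1], B[None, :, 1]), 0, None)
    inter = ix * iy
    area_a = (A[:, 2] - A[:, 0]) * (A[:, 3] - A[:, 1])
    area_b = (B[:, 2] - B[:, 0]) * (B[:, 3] - B[:, 1])
    return inter / (area_a[:, None] + area_b[None, :] - inter)


# ---------------------------------------------------------------------------
# offset coding


def encode_offsets(gt: BoundingBox, default: BoundingBox) -> np.ndarray:
    """Encode a ground-truth box relative to a default box (variance-scaled)."""
    gcx, gcy = gt.center
    dcx, dcy = default.center
    vx, vy, vw, vh = OFFSET_VARIANCES
    return np.array([
        (gcx - dcx) / default.width / vx,
        (gcy - dcy) / default.height / vy,
        math.log(gt.width / default.width) / vw,
        math.log(gt.height / default.height) / vh,
    ])


def decode_offsets(offsets: np.ndarray, default: BoundingBox) -> BoundingBox:
    """Invert :func:`encode_offsets`."""
    tx, ty, tw, th = np.asarray(offsets, dtype=float)
    vx, vy, vw, vh = OFFSET_VARIANCES
    dcx, dcy = default.center
    cx = tx * vx * default.width + dcx
    cy = ty * vy * default.height + dcy
    w = math.exp(tw * vw) * default.width
    h = math.exp(th * vh) * default.height
    return BoundingBox(max(0.0, cx - w / 2), max(0.0, cy - h / 2), cx + w / 2, cy + h / 2)


# ---------------------------------------------------------------------------
# non-maximum suppression


def nms(dets: Sequence[Detection], iou_threshold: float = 0.45) -> list[Detection]:
    """Greedy per-stage NMS: walk detections by descending score (index
    tie-break) and drop any same-stage box overlapping a kept one at
    IoU >= threshold.  Kept detections come back in that scan order."""
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].score, i))
    kept: list[Detection] = []
    for i in order:
        d = dets[i]
        if any(k.stage is d.stage and iou(k.box, d.box) >= iou_threshold for k in kept):
            continue
        kept.append(d)
    return kept


# ---------------------------------------------------------------------------
# default (anchor) boxes


@dataclass(frozen=True)
class FeatureMapSpec:
    """One feature map's anchor layout: an n x n grid of cells, a base scale
    (box side as a fraction of image size), aspect ratios, and optionally an
    extra scale used for a second square box (geometric-mean scale in the
    canonical 300x300 layout)."""

    grid: int
    scale: float
    aspect_ratios: tuple[float, ...] = (1.0, 2.0, 0.5)
    extra_scale: float | None = None

    @property
    def boxes_per_cell(self) -> int:
        return len(self.aspect_ratios) + (1 if self.extra_scale is not None else 0)


@dataclass(frozen=True)
class DefaultBox:
    box: BoundingBox
    feature_map_index: int
    scale: float
    aspect_ratio: float


@dataclass
class DefaultBoxSet:
    boxes: list[DefaultBox]
    image_size: tuple[int, int]  # (width, height)

    def __len__(self) -> int:
        return len(self.boxes)

    @property
    def bounding_boxes(self) -> list[BoundingBox]:
        return [d.box for d in self.boxes]


def canonical_300_spec() -> list[FeatureMapSpec]:
    """The canonical 300x300 six-map layout (8732 default boxes)."""
    scales = [0.1, 0.2, 0.375, 0.55, 0.725, 0.9]
    next_scales = scales[1:] + [1.05]
    grids = [38, 19, 10, 5, 3, 1]
    ratios: list[tuple[float, ...]] = [
        (1.0, 2.0, 0.5),
        (1.0, 2.0, 0.5, 3.0, 1 / 3),
        (1.0, 2.0, 0.5, 3.0, 1 / 3),
        (1.0, 2.0, 0.5, 3.0, 1 / 3),
        (1.0, 2.0, 0.5),
        (1.0, 2.0, 0.5),
    ]
    return [FeatureMapSpec(grid=g, scale=s, aspect_ratios=r,
                           extra_scale=math.sqrt(s * ns))
            for g, s, ns, r in zip(grids, scales, next_scales, ratios)]


def small_test_spec() -> list[FeatureMapSpec]:
    """A compact three-map layout for fast synthetic scenes."""
    return [
        FeatureMapSpec(grid=8, scale=0.15, aspect_ratios=(1.0, 2.0, 0.5), extra_scale=0.21),
        FeatureMapSpec(grid=4, scale=0.3, aspect_ratios=(1.0, 2.0, 0.5), extra_scale=0.42),
        FeatureMapSpec(grid=2, scale=0.6, aspect_ratios=(1.0, 2.0, 0.5), extra_scale=0.75),
    ]


def generate_default_boxes(image_size: tuple[int, int],
                           feature_maps: Iterable[FeatureMapSpec]) -> DefaultBoxSet:
    """Tile default boxes on each feature map's cell centers, clipped to bounds."""
    feature_maps = list(feature_maps)
    if not feature_maps:
        raise ConfigurationError("feature map spec is empty")
    width, height = image_size
    out: list[DefaultBox] = []
    for mi, fm in enumerate(feature_maps):
        step_x = width / fm.grid
        step_y = height / fm.grid
        per_cell: list[tuple[float, float]] = []  # (scale, aspect)
        for ar in fm.aspect_ratios:
            per_cell.append((fm.scale, ar))
        if fm.extra_scale is not None:
            per_cell.append((fm.extra_scale, 1.0))
        for row in range(fm.grid):
            for col in range(fm.grid):
                cx = (col + 0.5) * step_x
                cy = (row + 0.5) * step_y
                for scale, ar in per_cell:
                    w = scale * width * math.sqrt(ar)
                    h = scale * height / math.sqrt(ar)
                    box = BoundingBox(
                        max(0.0, cx - w / 2), max(0.0, cy - h / 2),
                        min(float(width), cx + w / 2), min(float(height), cy + h / 2))
                    out.append(DefaultBox(box=box, feature_map_index=mi,
                                          scale=scale, aspect_ratio=ar))
    return DefaultBoxSet(boxes=out, image_size=(width, height))
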