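"""Stage-colored detection overlays.

Convention: low-grade dysplasia draws a blue box, high-grade dysplasia a
light blue-gray box, invasive cancer an orange box; ground-truth boxes are
green.  A normal call draws nothing.  The named colors are fixed here as RGB
constants since only the names are standardized.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from PIL import Image, ImageDraw

from .boxes import BoundingBox, Detection
from .stages import StageLabel

STAGE_COLORS: dict[StageLabel, tuple[int, int, int]] = {
    StageLabel.LOW_GRADE_DYSPLASIA: (0, 0, 255),        # blue
    StageLabel.HIGH_GRADE_DYSPLASIA: (176, 196, 222),   # light blue-gray
    StageLabel.INVASIVE_CANCER: (255, 165, 0),          # orange
}
GROUND_TRUTH_COLOR = (0, 255, 0)  # green


def _to_uint8(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.dtype != np.uint8:
        img = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
    return img


def _clip_box(box: BoundingBox, width: int, height: int) -> BoundingBox:
    if box.xmin >= width or box.ymin >= height or box.xmax > width or box.ymax > height:
        warnings.warn(f"box {box.as_tuple()} extends outside {width}x{height}; clipping")
    return BoundingBox(min(box.xmin, width - 1), min(box.ymin, height - 1),
                       min(box.xmax, width), min(box.ymax, height))


def _draw_rect(draw: ImageDraw.ImageDraw, box: BoundingBox,
               color: tuple[int, int, int], label: str | None) -> None:
    # PIL rectangles are inclusive of both corners; half-open boxes end at max-1
    x0, y0 = int(round(box.xmin)), int(round(box.ymin))
    x1, y1 = int(round(box.xmax)) - 1, int(round(box.ymax)) - 1
    draw.rectangle([x0, y0, x1, y1], outline=color, width=1)
    if label:
        draw.text((x0 + 2, max(0, y0 - 10)), label, fill=color)


def render_overlay(image: np.ndarray,
                   dets: Sequence[Detection],
                   gts: Sequence[tuple[BoundingBox, StageLabel]] | None = None,
                   draw_labels: bool = True) -> np.ndarray:
    """Draw stage-colored detection boxes (and green ground-truth boxes).

    Returns a uint8 (H, W, 3) array.  With no detections and no ground truths
    the output is pixel-identical to the input.
    """
    img = _to_uint8(image)
    if not dets and not gts:
        return img.copy()
    pil = Image.fromarray(img)
    draw = ImageDraw.Draw(pil)
    h, w = img.shape[:2]
    for box, stage in (gts or []):
        _draw_rect(draw, _clip_box(box, w, h), GROUND_TRUTH_COLOR,
                   "truth" if draw_labels else None)
    for det in dets:
        _draw_rect(draw, _clip_box(det.box, w, h), STAGE_COLORS[det.stage],
                   det.stage.value if draw_labels else None)
    return np.asarray(pil)
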