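"""Matching strategy, multibox loss and image-level staging.

The matching rule mirrors single-shot detector training: first, every
ground-truth box claims its highest-IoU default box (so each lesion always has
at least one positive anchor, even when all overlaps are poor); second, any
remaining default whose best IoU against some ground truth reaches the
threshold (0.5 by default) is reclassified positive as well.  The training
loss is

    L(x, c, l, g) = (1/N) * (Lconf(x, c) + alpha * Lloc(x, l, g))

with N the positive count; when N = 0 the loss is defined as 0.  Lconf is
softmax cross-entropy over the positives plus the hard-negative subset
(3 negatives per positive by default), Lloc a smooth-L1 over the positives'
variance-scaled offsets.  The trained convolutional network itself is out of
scope here: any object satisfying the ``Scorer`` contract (per-default class
confidences + offsets) can drive the head, and a deterministic ground-truth
stub is provided for pipeline tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np

from .boxes import (
    BoundingBox,
    DefaultBoxSet,
    Detection,
    decode_offsets,
    encode_offsets,
    iou_matrix,
    nms,
)
from .errors import ConfigurationError, DimensionError
from .stages import LESION_STAGES, STAGE_ORDER, StageLabel

#: Class index layout for confidence vectors: 0 = background, then lesion stages.
N_CLASSES = 1 + len(LESION_STAGES)
BACKGROUND = 0


def stage_class_index(stage: StageLabel) -> int:
    return LESION_STAGES.index(stage) + 1


# ---------------------------------------------------------------------------
# matching


@dataclass
class MatchAssignment:
    """Per-default assignment: gt index for positives, -1 for negatives."""

    gt_index: np.ndarray  # (n_defaults,) int, -1 = negative

    @property
    def positive_mask(self) -> np.ndarray:
        return self.gt_index >= 0

    @property
    def n_positives(self) -> int:
        return int(np.count_nonzero(self.positive_mask))


def match_boxes(defaults: DefaultBoxSet,
                gts: Sequence[tuple[BoundingBox, StageLabel]],
                threshold: float = 0.5) -> MatchAssignment:
    """Assign each default box to a ground truth or to background.

    Step 1: each ground truth's argmax-IoU default becomes positive (IoU ties
    break to the lowest default index).  Step 2: every other default whose
    best IoU against any ground truth is >= threshold becomes positive for its
    argmax ground truth.  Everything else is negative.
    """
    if len(defaults) == 0:
        raise ConfigurationError("default box set is empty")
    if not (0.0 < threshold < 1.0):
        raise ConfigurationError(f"match threshold must lie in (0, 1), got {threshold}")
    assignment = np.full(len(defaults), -1, dtype=int)
    if not gts:
        return MatchAssignment(gt_index=assignment)

    ious = iou_matrix(defaults.bounding_boxes, [b for b, _ in gts])  # (D, G)
    # step 1: argmax default per ground truth (np.argmax takes the lowest index on ties)
    for g in range(len(gts)):
        assignment[int(np.argmax(ious[:, g]))] = g
    # step 2: threshold reclassification for the rest
    best_gt = np.argmax(ious, axis=1)
    best_iou = ious[np.arange(len(defaults)), best_gt]
    eligible = (assignment < 0) & (best_iou >= threshold)
    assignment[eligible] = best_gt[eligible]
    return MatchAssignment(gt_index=assignment)


# ---------------------------------------------------------------------------
# loss


@dataclass(frozen=True)
class LossBreakdown:
    total: float
    confidence: float
    localization: float
    n_positives: int


def _log_softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=-1, keepdims=True)
    return shifted - np.log(np.exp(shifted).sum(axis=-1, keepdims=True))


def smooth_l1(x: np.ndarray) -> np.ndarray:
    """Huber-style smooth L1: 0.5 x^2 for |x| < 1 else |x| - 0.5."""
    ax = np.abs(x)
    return np.where(ax < 1.0, 0.5 * x ** 2, ax - 0.5)


def select_hard_negatives(per_default_conf_loss: np.ndarray,
                          assignment: MatchAssignment,
                          ratio: float = 3.0) -> np.ndarray:
    """Indices of the ceil(ratio*N) highest-loss negatives (all if fewer).

    Deterministic: equal losses keep the lowest default indices first.
    """
    if ratio <= 0:
        raise ConfigurationError(f"negative ratio must be positive, got {ratio}")
    loss = np.asarray(per_default_conf_loss, dtype=float)
    neg_idx = np.flatnonzero(~assignment.positive_mask)
    quota = math.ceil(ratio * assignment.n_positives)
    if len(neg_idx) <= quota:
        return neg_idx
    order = sorted(neg_idx, key=lambda i: (-loss[i], i))
    return np.array(order[:quota], dtype=int)


def multibox_loss(confidences: np.ndarray,
                  predicted_offsets: np.ndarray,
                  assignment: MatchAssignment,
                  gts: Sequence[tuple[BoundingBox, StageLabel]],
                  defaults: DefaultBoxSet,
                  alpha: float = 1.0,
                  negative_ratio: float = 3.0) -> LossBreakdown:
    """Evaluate the multibox training loss.

    ``confidences`` is (D, n_classes) raw logits, ``predicted_offsets``
    (D, 4).  Returns the breakdown with total = (Lconf + alpha*Lloc)/N, and
    (0, 0, 0) when N = 0.
    """
    if alpha < 0:
        raise ConfigurationError(f"alpha must be nonnegative, got {alpha}")
    conf = np.asarray(confidences, dtype=float)
    offs = np.asarray(predicted_offsets, dtype=float)
    D = len(defaults)
    if conf.shape != (D, N_CLASSES) or offs.shape != (D, 4):
        raise DimensionError(
            f"expected confidences ({D}, {N_CLASSES}) and offsets ({D}, 4), "
            f"got {conf.shape} and {offs.shape}")

    n_pos = assignment.n_positives
    if n_pos == 0:
        return LossBreakdown(total=0.0, confidence=0.0, localization=0.0, n_positives=0)

    target = np.zeros(D, dtype=int)
    pos = assignment.positive_mask
    for i in np.flatnonzero(pos):
        target[i] = stage_class_index(gts[assignment.gt_index[i]][1])
    log_probs = _log_softmax(conf)
    per_default = -log_probs[np.arange(D), target]

    hard_negs = select_hard_negatives(per_default, assignment, negative_ratio)
    l_conf = float(per_default[pos].sum() + per_default[hard_negs].sum())

    l_loc = 0.0
    for i in np.flatnonzero(pos):
        gt_box = gts[assignment.gt_index[i]][0]
        encoded = encode_offsets(gt_box, defaults.boxes[i].box)
        l_loc += float(smooth_l1(offs[i] - encoded).sum())

    total = (l_conf + alpha * l_loc) / n_pos
    return LossBreakdown(total=total, confidence=l_conf, localization=l_loc,
                         n_positives=n_pos)


# ---------------------------------------------------------------------------
# scoring contract and the deterministic stub


class Scorer(Protocol):
    """Anything that maps an image/cube to per-default confidences + offsets."""

    def score(self, data: np.ndarray, defaults: DefaultBoxSet) -> tuple[np.ndarray, np.ndarray]:
        """Return (confidences (D, n_classes) logits, offsets (D, 4))."""
        ...


class GroundTruthStubScorer:
    """Deterministic stand-in for the trained detection network.

    Emits confident logits and exact encoded offsets at each ground truth's
    argmax default box, background elsewhere.  With ``confusion_rate`` > 0 the
    emitted stage is, with that probability, replaced by a different lesion
    stage drawn from the seeded generator — used to exercise the evaluation
    chain with a known error rate.
    """

    def __init__(self, gts: Sequence[tuple[BoundingBox, StageLabel]],
                 confusion_rate: float = 0.0, seed: int = 0,
                 logit_margin: float = 8.0):
        if not (0.0 <= confusion_rate <= 1.0):
            raise ConfigurationError("confusion_rate must lie in [0, 1]")
        self.gts = list(gts)
        self.confusion_rate = confusion_rate
        self.rng = np.random.default_rng(seed)
        self.logit_margin = logit_margin

    def score(self, data: np.ndarray, defaults: DefaultBoxSet) -> tuple[np.ndarray, np.ndarray]:
        D = len(defaults)
        conf = np.zeros((D, N_CLASSES))
        conf[:, BACKGROUND] = self.logit_margin
        offsets = np.zeros((D, 4))
        if self.gts:
            ious = iou_matrix(defaults.bounding_boxes, [b for b, _ in self.gts])
            for g, (box, stage) in enumerate(self.gts):
                if self.confusion_rate > 0 and self.rng.random() < self.confusion_rate:
                    others = [s for s in LESION_STAGES if s is not stage]
                    stage = others[int(self.rng.integers(len(others)))]
                i = int(np.argmax(ious[:, g]))
                conf[i] = 0.0
                conf[i, stage_class_index(stage)] = self.logit_margin
                offsets[i] = encode_offsets(box, defaults.boxes[i].box)
        return conf, offsets


def softmax(logits: np.ndarray) -> np.ndarray:
    e = np.exp(logits - logits.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def decode_detections(confidences: np.ndarray, offsets: np.ndarray,
                      defaults: DefaultBoxSet,
                      score_threshold: float = 0.1,
                      nms_iou: float = 0.45) -> list[Detection]:
    """Turn raw head outputs into NMS-filtered detections."""
    probs = softmax(np.asarray(confidences, dtype=float))
    dets: list[Detection] = []
    for i, db in enumerate(defaults.boxes):
        cls = int(np.argmax(probs[i]))
        if cls == BACKGROUND:
            continue
        score = float(probs[i, cls])
        if score < score_threshold:
            continue
        box = decode_offsets(offsets[i], db.box)
        dets.append(Detection(box=box, stage=LESION_STAGES[cls - 1], score=score))
    return nms(dets, nms_iou)


def image_level_call(dets: Sequence[Detection], score_floor: float = 0.5) -> StageLabel:
    """Collapse detections into one image-level stage.

    Normal when nothing reaches the score floor; otherwise the stage of the
    highest-scoring surviving detection, ties breaking to the more severe
    stage.
    """
    surviving = [d for d in dets if d.score >= score_floor]
    if not surviving:
        return StageLabel.NORMAL
    best = max(surviving, key=lambda d: (d.score, STAGE_ORDER.index(d.stage)))
    return best.stage
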