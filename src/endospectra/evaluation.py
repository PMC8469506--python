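"""4-stage diagnostic evaluation: confusion matrices and agreement metrics.

A :class:`ConfusionMatrix4` counts image-level calls with rows = predicted
stage, columns = true stage, in the canonical order (normal, low-grade
dysplasia, high-grade dysplasia, invasive cancer).  From it the module derives
per-stage sensitivity (recall), precision and F1, overall accuracy, and
Cohen's kappa

    kappa = (p_o - p_e) / (1 - p_e),
    p_o = trace/total,  p_e = sum_i rowsum_i * colsum_i / total^2.

Reporting conventions (chosen to be internally consistent across the bundled
published reference matrices): percentages round half-up to integers, kappa to
two decimals, and the reported F1 is the harmonic mean of the *rounded*
sensitivity and precision (the unrounded harmonic mean is also returned).
Undefined metrics (zero denominators) raise, and render as "NA" in tables —
never as 0.

Four reference confusion matrices from a published esophagoscopy evaluation
(WLI/NBI endoscopy, RGB vs reconstructed-spectrum input, 4 stages) ship as
package fixtures; note the bundled ``nbi_spectrum`` matrix is reproduced
exactly as printed even though its column sums are inconsistent with the
source's stated per-stage test counts.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, DimensionError, UndefinedMetricError
from .stages import STAGE_ORDER, StageLabel

FIXTURE_NAMES = ("wli_rgb", "nbi_rgb", "wli_spectrum", "nbi_spectrum")


def round_half_up(value: float, decimals: int = 0) -> float:
    """Round half away from zero at `decimals` places (what the tables use)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix4:
    """4x4 integer counts; rows = predicted stage, columns = true stage."""

    counts: np.ndarray
    modality: str = ""          # "wli" | "nbi" | ""
    representation: str = ""    # "rgb" | "spectrum" | ""

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.shape != (4, 4):
            raise DimensionError(f"confusion matrix must be 4x4, got {counts.shape}")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.round(counts)) or np.any(counts < 0):
                raise DataError("confusion matrix entries must be nonnegative integers")
            counts = counts.astype(int)
        self.counts = counts.astype(int)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def trace(self) -> int:
        return int(np.trace(self.counts))

    def row_sum(self, stage: StageLabel) -> int:
        return int(self.counts[STAGE_ORDER.index(stage), :].sum())

    def col_sum(self, stage: StageLabel) -> int:
        return int(self.counts[:, STAGE_ORDER.index(stage)].sum())


def confusion_from_calls(pairs: Iterable[tuple[StageLabel | str, StageLabel | str]],
                         modality: str = "", representation: str = "") -> ConfusionMatrix4:
    """Tally (true, predicted) stage pairs into a confusion matrix."""
    counts = np.zeros((4, 4), dtype=int)
    n = 0
    for true, pred in pairs:
        t = StageLabel.from_string(true)
        p = StageLabel.from_string(pred)
        counts[STAGE_ORDER.index(p), STAGE_ORDER.index(t)] += 1
        n += 1
    if n == 0:
        raise DataError("no (true, predicted) pairs supplied")
    return ConfusionMatrix4(counts=counts, modality=modality, representation=representation)


def pairs_from_confusion(m: ConfusionMatrix4) -> list[tuple[StageLabel, StageLabel]]:
    """Reconstruct a list of (true, predicted) pairs realizing the matrix."""
    pairs: list[tuple[StageLabel, StageLabel]] = []
    for i, pred in enumerate(STAGE_ORDER):
        for j, true in enumerate(STAGE_ORDER):
            pairs.extend([(true, pred)] * int(m.counts[i, j]))
    return pairs


# ---------------------------------------------------------------------------
# metrics


def sensitivity(m: ConfusionMatrix4, stage: StageLabel) -> float:
    """Per-stage recall in percent: diagonal / column sum * 100 (unrounded)."""
    col = m.col_sum(stage)
    if col == 0:
        raise UndefinedMetricError(f"no true cases of {stage.value}; sensitivity undefined")
    i = STAGE_ORDER.index(stage)
    return 100.0 * m.counts[i, i] / col


def precision(m: ConfusionMatrix4, stage: StageLabel) -> float:
    """Per-stage precision in percent: diagonal / row sum * 100 (unrounded)."""
    row = m.row_sum(stage)
    if row == 0:
        raise UndefinedMetricError(f"no predictions of {stage.value}; precision undefined")
    i = STAGE_ORDER.index(stage)
    return 100.0 * m.counts[i, i] / row


def f1(m: ConfusionMatrix4, stage: StageLabel) -> float:
    """Unrounded harmonic mean of sensitivity and precision, in percent."""
    s = sensitivity(m, stage)
    p = precision(m, stage)
    if s + p == 0:
        return 0.0
    return 2 * s * p / (s + p)


def f1_reported(m: ConfusionMatrix4, stage: StageLabel) -> int:
    """Reported F1: harmonic mean of the ROUNDED sensitivity/precision, rounded."""
    s = round_half_up(sensitivity(m, stage))
    p = round_half_up(precision(m, stage))
    if s + p == 0:
        return 0
    return int(round_half_up(2 * s * p / (s + p)))


def accuracy(m: ConfusionMatrix4) -> float:
    """Overall accuracy in percent: trace / total * 100 (unrounded)."""
    if m.total == 0:
        raise UndefinedMetricError("empty confusion matrix; accuracy undefined")
    return 100.0 * m.trace / m.total


def cohen_kappa(m: ConfusionMatrix4) -> float:
    """Chance-corrected agreement between predicted and true stages (unrounded)."""
    total = m.total
    if total == 0:
        raise UndefinedMetricError("empty confusion matrix; kappa undefined")
    p_o = m.trace / total
    row = m.counts.sum(axis=1).astype(float)
    col = m.counts.sum(axis=0).astype(float)
    p_e = float(row @ col) / total ** 2
    if p_e == 1.0:
        raise UndefinedMetricError("expected agreement is 1; kappa undefined")
    return (p_o - p_e) / (1.0 - p_e)


@dataclass
class MetricsTable:
    """All per-stage and overall metrics, rounded for reporting and unrounded."""

    per_stage: dict[str, dict[str, float | int | None]]
    accuracy_pct: int | None
    kappa: float | None
    accuracy_unrounded: float | None
    kappa_unrounded: float | None
    modality: str = ""
    representation: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for stage in STAGE_ORDER:
            d = self.per_stage[stage.value]
            rows.append({"stage": stage.value,
                         "sensitivity_pct": d["sensitivity"],
                         "precision_pct": d["precision"],
                         "f1_pct": d["f1"]})
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps({
            "modality": self.modality,
            "representation": self.representation,
            "per_stage": self.per_stage,
            "accuracy_pct": self.accuracy_pct,
            "kappa": self.kappa,
            "accuracy_unrounded": self.accuracy_unrounded,
            "kappa_unrounded": self.kappa_unrounded,
        }, indent=2)


def metrics_table(m: ConfusionMatrix4) -> MetricsTable:
    """Assemble the full metric set; undefined cells become None ("NA")."""
    per_stage: dict[str, dict[str, float | int | None]] = {}
    for stage in STAGE_ORDER:
        cell: dict[str, float | int | None] = {}
        try:
            s = sensitivity(m, stage)
            cell["sensitivity"] = int(round_half_up(s))
            cell["sensitivity_unrounded"] = s
        except UndefinedMetricError:
            cell["sensitivity"] = None
            cell["sensitivity_unrounded"] = None
        try:
            p = precision(m, stage)
            cell["precision"] = int(round_half_up(p))
            cell["precision_unrounded"] = p
        except UndefinedMetricError:
            cell["precision"] = None
            cell["precision_unrounded"] = None
        if cell["sensitivity"] is None or cell["precision"] is None:
            cell["f1"] = None
            cell["f1_unrounded"] = None
        else:
            cell["f1"] = f1_reported(m, stage)
            cell["f1_unrounded"] = f1(m, stage)
        per_stage[stage.value] = cell
    try:
        acc: float | None = accuracy(m)
    except UndefinedMetricError:
        acc = None
    try:
        kap: float | None = cohen_kappa(m)
    except UndefinedMetricError:
        kap = None
    return MetricsTable(per_stage=per_stage,
                        accuracy_pct=None if acc is None else int(round_half_up(acc)),
                        kappa=None if kap is None else round_half_up(kap, 2),
                        accuracy_unrounded=acc,
                        kappa_unrounded=kap,
                        modality=m.modality,
                        representation=m.representation)


# ---------------------------------------------------------------------------
# CSV I/O and bundled fixtures


def matrix_to_csv(m: ConfusionMatrix4) -> str:
    lines = ["predicted\\true," + ",".join(s.value for s in STAGE_ORDER)]
    for i, stage in enumerate(STAGE_ORDER):
        lines.append(stage.value + "," + ",".join(str(c) for c in m.counts[i]))
    return "\n".join(lines) + "\n"


def matrix_from_csv(text: str, modality: str = "", representation: str = "") -> ConfusionMatrix4:
    df = pd.read_csv(_io.StringIO(text), index_col=0)
    expected = [s.value for s in STAGE_ORDER]
    if list(df.columns) != expected or list(df.index) != expected:
        raise DataError("confusion CSV must have the four stages as header row and column")
    return ConfusionMatrix4(counts=df.to_numpy(), modality=modality,
                            representation=representation)


def load_fixture_matrix(name: str) -> ConfusionMatrix4:
    """Load one of the bundled reference matrices: wli_rgb, nbi_rgb,
    wli_spectrum, nbi_spectrum."""
    if name not in FIXTURE_NAMES:
        raise DataError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
    text = resources.files("endospectra.fixtures").joinpath(f"{name}.csv").read_text()
    modality, representation = name.split("_")
    return matrix_from_csv(text, modality=modality, representation=representation)
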