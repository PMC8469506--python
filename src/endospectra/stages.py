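"""The four diagnostic severity stages.

``NORMAL`` denotes healthy tissue; it is an image-level call only and never
appears as a ground-truth lesion-box label (normal = absence of lesions).
Severity is ordered normal < low-grade dysplasia < high-grade dysplasia <
invasive cancer; ties in image-level calls break toward the more severe stage.
"""

from __future__ import annotations

import enum

from .errors import LabelError


class StageLabel(enum.Enum):
    NORMAL = "normal"
    LOW_GRADE_DYSPLASIA = "low_grade_dysplasia"
    HIGH_GRADE_DYSPLASIA = "high_grade_dysplasia"
    INVASIVE_CANCER = "invasive_cancer"

    @property
    def severity(self) -> int:
        return STAGE_ORDER.index(self)

    @classmethod
    def from_string(cls, value: "str | StageLabel") -> "StageLabel":
        if isinstance(value, cls):
            return value
        try:
            return cls(value)
        except ValueError:
            raise LabelError(f"unknown stage label: {value!r}") from None


#: Canonical ordering used by confusion matrices and severity tie-breaks.
STAGE_ORDER: tuple[StageLabel, ...] = (
    StageLabel.NORMAL,
    StageLabel.LOW_GRADE_DYSPLASIA,
    StageLabel.HIGH_GRADE_DYSPLASIA,
    StageLabel.INVASIVE_CANCER,
)

#: Stages a lesion box may carry (everything except normal).
LESION_STAGES: tuple[StageLabel, ...] = STAGE_ORDER[1:]
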