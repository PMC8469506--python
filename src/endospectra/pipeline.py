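"""Pipeline orchestration: convert -> pca -> detect -> evaluate.

A :class:`PipelineConfig` fixes the modality (WLI or NBI — trained and
calibrated separately, as in the clinical chain), the input representation
(raw RGB, reconstructed 401-band spectrum, or PCA scores), the detection
thresholds and the seeds.  ``run_synthetic_evaluation`` runs the whole chain
on a balanced synthetic test set with the deterministic ground-truth stub in
place of the trained network; reruns with the same config are bit-identical.
Training hyperparameters of the original network (batch size 32, learning
rate 5e-4, 80,000 steps) are recorded here as config defaults only — nothing
in this package trains a network.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, field_validator

from . import synth
from .boxes import generate_default_boxes, small_test_spec
from .detector import GroundTruthStubScorer, decode_detections, image_level_call
from .errors import ConfigurationError
from .evaluation import (
    ConfusionMatrix4,
    MetricsTable,
    confusion_from_calls,
    load_fixture_matrix,
    metrics_table,
)
from .pca import fit_pca, transform
from .spectral import FeatureExpansionSpec, apply_conversion, fit_conversion_matrix
from .stages import STAGE_ORDER
from .synth import camera_for, capture_color_target, make_color_target

logger = logging.getLogger("endospectra")

REPRESENTATIONS = ("rgb", "spectrum", "pca")


class PipelineConfig(BaseModel):
    """Full configuration of one evaluation run."""

    modality: str = "wli"
    representation: str = "spectrum"
    expansion_degree: int = 3
    ridge: float = 1e-6
    transfer: str = "srgb"
    match_threshold: float = 0.5
    nms_threshold: float = 0.45
    score_floor: float = 0.5
    alpha: float = 1.0
    negative_ratio: float = 3.0
    pca_k: int = 3
    seed: int = 1
    n_per_stage: int = 8
    scene_size: int = 96
    stub_confusion_rate: float = 0.0
    # recorded for provenance only; never exercised here
    train_batch_size: int = 32
    train_learning_rate: float = 5e-4
    train_steps: int = 80_000

    @field_validator("modality")
    @classmethod
    def _modality(cls, v: str) -> str:
        if v not in ("wli", "nbi"):
            raise ValueError(f"modality must be 'wli' or 'nbi', got {v!r}")
        return v

    @field_validator("representation")
    @classmethod
    def _representation(cls, v: str) -> str:
        if v not in REPRESENTATIONS:
            raise ValueError(f"representation must be one of {REPRESENTATIONS}, got {v!r}")
        return v

    @field_validator("match_threshold", "nms_threshold", "score_floor")
    @classmethod
    def _unit_interval(cls, v: float) -> float:
        if not (0.0 < v < 1.0):
            raise ValueError(f"thresholds must lie in (0, 1), got {v}")
        return v

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config_file(path: str | Path) -> PipelineConfig:
    """Parse the flat `key = value` config format (comments start with #)."""
    values: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigurationError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        values[key] = value
    return PipelineConfig(**values)


@dataclass
class PipelineResult:
    config: PipelineConfig
    confusion: ConfusionMatrix4
    metrics: MetricsTable
    calls: list[tuple[str, str]]  # (true, predicted) stage values
    config_hash: str


def run_synthetic_evaluation(config: PipelineConfig) -> PipelineResult:
    """Generate a balanced synthetic test set, run the detection chain with the
    ground-truth stub scorer, and evaluate the image-level calls.

    When the representation is "spectrum" or "pca", the scenes are first
    reconstructed through a conversion matrix fitted on the synthetic color
    target (and reduced by PCA for "pca") so every stage of the chain runs;
    the stub scorer itself is representation-agnostic.
    """
    t0 = time.monotonic()
    camera = camera_for(config.modality)
    tissue = synth.TissueSpectrumModel(seed=config.seed)
    scenes = synth.make_test_set(config.n_per_stage, config.seed, camera,
                                 tissue=tissue, size=config.scene_size)
    logger.info("stage=synth config=%s n_scenes=%d", config.config_hash(), len(scenes))

    matrix = None
    basis = None
    if config.representation in ("spectrum", "pca"):
        target = make_color_target(config.seed)
        rgbs = capture_color_target(target, camera)
        matrix = fit_conversion_matrix(
            rgbs, target, FeatureExpansionSpec(degree=config.expansion_degree),
            ridge=config.ridge, transfer=config.transfer, rgb_is_linear=False,
            modality=config.modality)
        logger.info("stage=convert matrix_hash=%s mean_fit_rmse=%.5f",
                    matrix.content_hash, float(matrix.fit_rmse_per_patch.mean()))
    if config.representation == "pca":
        means = synth.make_stage_spectra(tissue)
        basis = fit_pca(np.stack([means[s] for s in STAGE_ORDER]
                                 + [means[s] + 0.01 * i for i, s in enumerate(STAGE_ORDER)]),
                        k=config.pca_k)

    defaults = generate_default_boxes((config.scene_size, config.scene_size),
                                      small_test_spec())
    calls: list[tuple[str, str]] = []
    for i, ts in enumerate(scenes):
        data: np.ndarray = ts.rendered.rgb
        if matrix is not None:
            cube = apply_conversion(ts.rendered.rgb, matrix)
            data = cube.values
            if basis is not None:
                data = transform(basis, cube.values)
        scorer = GroundTruthStubScorer(ts.rendered.boxes,
                                       confusion_rate=config.stub_confusion_rate,
                                       seed=config.seed * 100_003 + i)
        conf, offs = scorer.score(data, defaults)
        dets = decode_detections(conf, offs, defaults, nms_iou=config.nms_threshold)
        call = image_level_call(dets, score_floor=config.score_floor)
        calls.append((ts.true_stage.value, call.value))

    confusion = confusion_from_calls(calls, modality=config.modality,
                                     representation=config.representation)
    metrics = metrics_table(confusion)
    logger.info("stage=evaluate accuracy=%s kappa=%s wall=%.2fs",
                metrics.accuracy_pct, metrics.kappa, time.monotonic() - t0)
    return PipelineResult(config=config, confusion=confusion, metrics=metrics,
                          calls=calls, config_hash=config.config_hash())


@dataclass
class ComparisonReport:
    """Side-by-side metrics for two representations of the same modality."""

    modality: str
    baseline: MetricsTable
    comparison: MetricsTable

    @property
    def accuracy_delta(self) -> int:
        return self.comparison.accuracy_pct - self.baseline.accuracy_pct

    @property
    def kappa_delta(self) -> float:
        return round(self.comparison.kappa - self.baseline.kappa, 2)

    def to_json(self) -> str:
        return json.dumps({
            "modality": self.modality,
            "baseline_representation": self.baseline.representation,
            "comparison_representation": self.comparison.representation,
            "baseline_accuracy_pct": self.baseline.accuracy_pct,
            "comparison_accuracy_pct": self.comparison.accuracy_pct,
            "accuracy_delta_pct_points": self.accuracy_delta,
            "baseline_kappa": self.baseline.kappa,
            "comparison_kappa": self.comparison.kappa,
            "kappa_delta": self.kappa_delta,
        }, indent=2)


def compare_representations(config_a: PipelineConfig, config_b: PipelineConfig) -> ComparisonReport:
    """Run two configs that differ only in representation; report deltas."""
    da, db = config_a.model_dump(), config_b.model_dump()
    differing = {k for k in da if da[k] != db[k]}
    if differing != {"representation"}:
        raise ConfigurationError(
            f"configs must differ only in 'representation'; differing fields: {sorted(differing)}")
    ra = run_synthetic_evaluation(config_a)
    rb = run_synthetic_evaluation(config_b)
    return ComparisonReport(modality=config_a.modality, baseline=ra.metrics,
                            comparison=rb.metrics)


def compare_fixture_matrices(modality: str) -> ComparisonReport:
    """Compare the bundled reference matrices (rgb vs spectrum) for a modality."""
    base = metrics_table(load_fixture_matrix(f"{modality}_rgb"))
    comp = metrics_table(load_fixture_matrix(f"{modality}_spectrum"))
    return ComparisonReport(modality=modality, baseline=base, comparison=comp)
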