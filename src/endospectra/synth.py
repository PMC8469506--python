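"""Synthetic endoscopic scenes with full spectral ground truth.

The clinical image sets behind the published evaluation are not available, so
this module generates everything the rest of the package needs to be exercised
end to end: smooth per-stage tissue reflectance spectra whose low-dimensional
structure separates the four severity stages, WLI and NBI camera models
(three sensitivity curves + a nonlinear transfer), rendered scenes with
elliptical lesions and tight ground-truth boxes, and a rendered 24-patch color
target paired with its reference spectra.

All synthetic reflectances — tissue stages and color-target patches alike —
are nonnegative combinations of one shared smooth basis of three broad
Gaussian bumps spanning 380-780 nm.  Real surface reflectances are well
described by low-dimensional smooth linear models, and a three-channel camera
can only ever pin down three spectral degrees of freedom: a shared rank-3
family is exactly the prior under which the color-target-calibrated
RGB-to-401-band regression is well posed, which is the premise the clinical
chain rests on.  Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .boxes import BoundingBox
from .errors import ConfigurationError, GridError
from .grid import DEFAULT_GRID, N_BANDS, WavelengthGrid
from .spectral import ColorTargetReference, SRGB_TRANSFER, apply_transfer, spectrum_rmse
from .stages import LESION_STAGES, STAGE_ORDER, StageLabel

# ---------------------------------------------------------------------------
# the shared smooth reflectance basis

N_BASIS = 3
_BASIS_CENTERS = np.array([430.0, 550.0, 670.0])  # nm
_BASIS_SIGMA = 65.0  # nm


def reflectance_basis(grid: WavelengthGrid = DEFAULT_GRID) -> np.ndarray:
    """(3, 401) broad smooth Gaussian bumps; every synthetic spectrum is a
    nonnegative combination of these."""
    lam = grid.wavelengths
    return np.exp(-0.5 * ((lam[None, :] - _BASIS_CENTERS[:, None]) / _BASIS_SIGMA) ** 2)


def _combine(weights: np.ndarray, basis: np.ndarray) -> np.ndarray:
    return np.clip(weights @ basis, 0.0, 1.0)


# ---------------------------------------------------------------------------
# camera models


@dataclass(frozen=True)
class CameraModel:
    """Three spectral sensitivity curves plus a nonlinear transfer.

    Curves are normalized to unit area (1 nm steps), so a flat reflectance of
    1.0 at exposure e yields linear channel values of e before clipping.
    """

    sensitivities: np.ndarray  # (3, 401), nonnegative
    transfer: str = SRGB_TRANSFER
    exposure: float = 0.9
    modality: str = "wli"
    grid: WavelengthGrid = field(default_factory=lambda: DEFAULT_GRID)

    def __post_init__(self):
        s = np.asarray(self.sensitivities, dtype=float)
        if s.shape != (3, N_BANDS):
            raise ConfigurationError(f"sensitivities must be (3, {N_BANDS}), got {s.shape}")
        if np.any(s < 0):
            raise ConfigurationError("sensitivities must be nonnegative")
        object.__setattr__(self, "sensitivities", s)
        if self.modality == "nbi":
            for i in range(3):
                if _mass_window_width(s[i], self.grid) > 60.0:
                    raise ConfigurationError(
                        f"nbi channel {i} spreads >90% of its mass over more than 60 nm")

    def render_linear(self, spectra: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map reflectance spectra (..., 401) to linear channels (..., 3).

        Returns (linear values clipped to [0,1], mask of clipped entries).
        """
        linear = self.exposure * (spectra @ self.sensitivities.T)
        clipped = (linear < 0.0) | (linear > 1.0)
        return np.clip(linear, 0.0, 1.0), clipped

    def render(self, spectra: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Full rendering: transfer(clip(exposure * integral sens*refl))."""
        linear, clipped = self.render_linear(spectra)
        return apply_transfer(linear, self.transfer), clipped


def _mass_window_width(curve: np.ndarray, grid: WavelengthGrid, mass: float = 0.9) -> float:
    """Width (nm) of the shortest window holding `mass` of the curve's area."""
    total = curve.sum()
    if total == 0:
        return 0.0
    c = np.concatenate([[0.0], np.cumsum(curve)]) / total
    lam = grid.wavelengths
    best = math.inf
    j = 0
    for i in range(len(curve)):
        while j <= len(curve) and c[min(j, len(curve))] - c[i] < mass:
            j += 1
        if j > len(curve):
            break
        best = min(best, lam[j - 1] - lam[i])
    return best


def _gaussian_curve(center: float, sigma: float, gain: float = 1.0,
                    grid: WavelengthGrid = DEFAULT_GRID) -> np.ndarray:
    lam = grid.wavelengths
    g = np.exp(-0.5 * ((lam - center) / sigma) ** 2)
    return gain * g / g.sum()


def wli_camera(exposure: float = 0.9, transfer: str = SRGB_TRANSFER) -> CameraModel:
    """Broadband white-light camera: wide R/G/B Gaussians at 610/545/465 nm."""
    sens = np.stack([
        _gaussian_curve(610.0, 55.0),
        _gaussian_curve(545.0, 50.0),
        _gaussian_curve(465.0, 45.0),
    ])
    return CameraModel(sensitivities=sens, transfer=transfer,
                       exposure=exposure, modality="wli")


def nbi_camera(exposure: float = 0.9, transfer: str = SRGB_TRANSFER) -> CameraModel:
    """Narrow-band camera: illumination concentrated near 415 and 540 nm (the
    hemoglobin absorption bands used clinically).  The red channel reuses the
    415 nm band at reduced gain, giving the characteristic NBI false color."""
    sens = np.stack([
        _gaussian_curve(415.0, 12.0, gain=0.6),
        _gaussian_curve(540.0, 12.0),
        _gaussian_curve(415.0, 12.0),
    ])
    return CameraModel(sensitivities=sens, transfer=transfer,
                       exposure=exposure, modality="nbi")


def camera_for(modality: str, exposure: float = 0.9) -> CameraModel:
    if modality == "wli":
        return wli_camera(exposure)
    if modality == "nbi":
        return nbi_camera(exposure)
    raise ConfigurationError(f"unknown modality {modality!r}; expected 'wli' or 'nbi'")


# ---------------------------------------------------------------------------
# tissue spectra


#: Per-stage base weights on the (blue, green, red) basis bumps; each mean is
#: a sum of 2-3 bumps and the mixes are mutually distinct.  Healthy mucosa
#: reflects broadly with a red cast; advancing dysplasia darkens and shifts
#: the balance.
_STAGE_WEIGHTS: dict[StageLabel, tuple[float, float, float]] = {
    StageLabel.NORMAL: (0.25, 0.45, 0.55),
    StageLabel.LOW_GRADE_DYSPLASIA: (0.0, 0.40, 0.45),
    StageLabel.HIGH_GRADE_DYSPLASIA: (0.15, 0.20, 0.40),
    StageLabel.INVASIVE_CANCER: (0.10, 0.30, 0.0),
}


@dataclass(frozen=True)
class TissueSpectrumModel:
    """Per-stage mean reflectance generator plus the pixel-level variation model.

    Pixel spectra are stage mean + (smooth spatial field) * amplitude + iid
    Gaussian band noise, clipped to [0, 1.5].
    """

    smooth_amplitude: float = 0.03   # reflectance units, spatial low-frequency field
    noise_sd: float = 0.01           # reflectance units, per (pixel, band)
    seed: int = 1
    grid: WavelengthGrid = field(default_factory=lambda: DEFAULT_GRID)


def make_stage_spectra(model: TissueSpectrumModel) -> dict[StageLabel, np.ndarray]:
    """Deterministic per-stage mean spectra (each a sum of 2-4 smooth bumps).

    Raises when the stage means fail the separation invariant
    (pairwise RMSE > 3 * noise sd) — i.e. when the requested noise level makes
    the stages statistically indistinct.
    """
    rng = np.random.default_rng(model.seed)
    basis = reflectance_basis(model.grid)
    means: dict[StageLabel, np.ndarray] = {}
    for stage in STAGE_ORDER:
        base = np.array(_STAGE_WEIGHTS[stage])
        weights = base * (1.0 + 0.1 * rng.uniform(-1, 1, size=N_BASIS))
        means[stage] = _combine(weights, basis)
    floor = 3.0 * model.noise_sd
    stages = list(means)
    for i in range(len(stages)):
        for j in range(i + 1, len(stages)):
            d = spectrum_rmse(means[stages[i]], means[stages[j]])
            if d <= floor:
                raise ConfigurationError(
                    f"stage means {stages[i].value}/{stages[j].value} separated by "
                    f"RMSE {d:.4f} <= 3*noise_sd {floor:.4f}")
    return means


# ---------------------------------------------------------------------------
# color target


def make_color_target(seed: int = 1, grid: WavelengthGrid = DEFAULT_GRID) -> ColorTargetReference:
    """A synthetic 24-patch color target: smooth, mutually distinct reflectances
    (pairwise RMSE > 0.03) drawn from the shared basis.  Deterministic per seed.

    This is a synthetic stand-in for measured color-checker reflectances,
    which are licensed and not bundled; users may load their own via CSV.
    """
    rng = np.random.default_rng(seed)
    basis = reflectance_basis(grid)
    spectra = np.empty((24, N_BANDS))
    for p in range(24):
        for _attempt in range(60):
            weights = rng.uniform(0.05, 0.70, size=N_BASIS)
            # a third of the patches drop one bump for saturated colors
            if rng.random() < 0.33:
                weights[int(rng.integers(N_BASIS))] = 0.0
            cand = _combine(weights, basis)
            if all(spectrum_rmse(cand, spectra[q]) > 0.03 for q in range(p)):
                spectra[p] = cand
                break
        else:
            raise ConfigurationError("could not draw 24 mutually distinct patches")
    ids = tuple(f"patch_{i + 1:02d}" for i in range(24))
    return ColorTargetReference(patch_ids=ids, spectra=spectra, grid=grid)


def capture_color_target(target: ColorTargetReference, camera: CameraModel) -> np.ndarray:
    """Render each flat patch through the camera (no noise): (24, 3) encoded RGB."""
    if target.grid != camera.grid:
        raise GridError("color target and camera are on different wavelength grids")
    rgb, _ = camera.render(target.spectra)
    return rgb


# ---------------------------------------------------------------------------
# scenes


@dataclass(frozen=True)
class Lesion:
    center: tuple[float, float]  # (x, y) pixels
    axes: tuple[float, float]    # semi-axes (a, b) pixels
    angle: float                 # radians, counterclockwise
    stage: StageLabel

    def __post_init__(self):
        if self.stage not in LESION_STAGES:
            raise ConfigurationError("lesion stage must be a non-normal stage")
        if min(self.axes) <= 0:
            raise ConfigurationError("lesion semi-axes must be positive")

    def bounding_box(self) -> BoundingBox:
        """Tight axis-aligned box of the rotated ellipse."""
        a, b = self.axes
        c, s = math.cos(self.angle), math.sin(self.angle)
        hw = math.sqrt((a * c) ** 2 + (b * s) ** 2)
        hh = math.sqrt((a * s) ** 2 + (b * c) ** 2)
        cx, cy = self.center
        return BoundingBox(cx - hw, cy - hh, cx + hw, cy + hh)


@dataclass(frozen=True)
class SceneSpec:
    width: int = 128
    height: int = 128
    lesions: tuple[Lesion, ...] = ()
    seed: int = 1

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ConfigurationError("scene dimensions must be positive")
        for lesion in self.lesions:
            try:
                bb = lesion.bounding_box()
            except Exception as exc:
                raise ConfigurationError(
                    f"lesion at {lesion.center} extends outside the "
                    f"{self.width}x{self.height} image") from exc
            if bb.xmin < 0 or bb.ymin < 0 or bb.xmax > self.width or bb.ymax > self.height:
                raise ConfigurationError(
                    f"lesion at {lesion.center} extends outside the {self.width}x{self.height} image")


@dataclass
class RenderedScene:
    """A rendered scene with its full ground truth."""

    rgb: np.ndarray                  # (H, W, 3) encoded, [0, 1]
    true_spectra: np.ndarray         # (H, W, 401) reflectance
    boxes: list[tuple[BoundingBox, StageLabel]]
    stage_map: np.ndarray            # (H, W) int index into STAGE_ORDER
    clipped_mask: np.ndarray         # (H, W) True where any channel clipped
    modality: str


def _smooth_field(height: int, width: int, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency spatial field in [-1, 1] from an upsampled coarse grid."""
    coarse = rng.standard_normal((5, 5))
    fld = ndimage.zoom(coarse, (height / 5, width / 5), order=3)[:height, :width]
    peak = np.max(np.abs(fld))
    return fld / peak if peak > 0 else fld


def render_rgb(scene: SceneSpec, tissue: TissueSpectrumModel,
               camera: CameraModel) -> RenderedScene:
    """Render a scene: per-pixel true spectrum = stage mean + smooth field +
    noise; channels = transfer(clip(exposure * integral sens * spectrum))."""
    if tissue.grid != camera.grid:
        raise GridError("tissue model and camera are on different wavelength grids")
    means = make_stage_spectra(tissue)
    rng = np.random.default_rng(scene.seed)
    h, w = scene.height, scene.width

    stage_map = np.zeros((h, w), dtype=int)  # 0 = normal background
    ys, xs = np.mgrid[0:h, 0:w]
    for lesion in scene.lesions:
        dx = xs - lesion.center[0]
        dy = ys - lesion.center[1]
        c, s = math.cos(lesion.angle), math.sin(lesion.angle)
        u = (dx * c + dy * s) / lesion.axes[0]
        v = (-dx * s + dy * c) / lesion.axes[1]
        stage_map[u ** 2 + v ** 2 <= 1.0] = STAGE_ORDER.index(lesion.stage)

    mean_stack = np.stack([means[s] for s in STAGE_ORDER]).astype(np.float32)
    spectra = mean_stack[stage_map]  # (H, W, 401)
    fld = _smooth_field(h, w, rng).astype(np.float32)
    spectra = spectra + tissue.smooth_amplitude * fld[:, :, None]
    if tissue.noise_sd > 0:
        spectra = spectra + rng.normal(0.0, tissue.noise_sd, spectra.shape).astype(np.float32)
    spectra = np.clip(spectra, 0.0, 1.5)

    rgb, clipped = camera.render(spectra)
    boxes = [(l.bounding_box(), l.stage) for l in scene.lesions]
    return RenderedScene(rgb=rgb, true_spectra=spectra, boxes=boxes,
                         stage_map=stage_map, clipped_mask=clipped.any(axis=-1),
                         modality=camera.modality)


# ---------------------------------------------------------------------------
# augmentation


_AUGMENT_OPS = ("hflip", "vflip", "rot90", "rot180", "rot270")


def apply_augmentation(image: np.ndarray,
                       boxes: list[tuple[BoundingBox, StageLabel]],
                       op: str) -> tuple[np.ndarray, list[tuple[BoundingBox, StageLabel]]]:
    """Apply one flip/rotation to an (H, W, ...) image and its boxes."""
    h, w = image.shape[:2]
    if op == "hflip":
        img = np.flip(image, axis=1).copy()
        new = [(BoundingBox(w - b.xmax, b.ymin, w - b.xmin, b.ymax), s) for b, s in boxes]
    elif op == "vflip":
        img = np.flip(image, axis=0).copy()
        new = [(BoundingBox(b.xmin, h - b.ymax, b.xmax, h - b.ymin), s) for b, s in boxes]
    elif op == "rot90":  # 90 degrees clockwise
        img = np.rot90(image, k=-1).copy()
        new = [(BoundingBox(h - b.ymax, b.xmin, h - b.ymin, b.xmax), s) for b, s in boxes]
    elif op == "rot180":
        img = np.rot90(image, k=2).copy()
        new = [(BoundingBox(w - b.xmax, h - b.ymax, w - b.xmin, h - b.ymin), s) for b, s in boxes]
    elif op == "rot270":  # 270 degrees clockwise
        img = np.rot90(image, k=1).copy()
        new = [(BoundingBox(b.ymin, w - b.xmax, b.ymax, w - b.xmin), s) for b, s in boxes]
    else:
        raise ConfigurationError(f"unsupported augmentation op {op!r}; expected one of {_AUGMENT_OPS}")
    return img, new


def augment(image: np.ndarray, boxes: list[tuple[BoundingBox, StageLabel]],
            ops: list[str]) -> list[tuple[np.ndarray, list[tuple[BoundingBox, StageLabel]]]]:
    """The original plus one augmented copy per requested op."""
    out = [(image, boxes)]
    for op in ops:
        out.append(apply_augmentation(image, boxes, op))
    return out


# ---------------------------------------------------------------------------
# balanced test sets


@dataclass
class TestScene:
    scene: SceneSpec
    rendered: RenderedScene
    true_stage: StageLabel


def make_test_set(n_per_stage: int, seed: int, camera: CameraModel,
                  tissue: TissueSpectrumModel | None = None,
                  size: int = 96) -> list[TestScene]:
    """A balanced set: n normal (lesion-free) scenes and n single-lesion scenes
    per lesion stage, each with full ground truth."""
    if n_per_stage < 1:
        raise ConfigurationError("n_per_stage must be >= 1")
    if tissue is None:
        tissue = TissueSpectrumModel(seed=seed)
    rng = np.random.default_rng(seed)
    out: list[TestScene] = []
    for stage in STAGE_ORDER:
        for i in range(n_per_stage):
            scene_seed = int(rng.integers(2 ** 31 - 1))
            if stage is StageLabel.NORMAL:
                lesions: tuple[Lesion, ...] = ()
            else:
                a = float(rng.uniform(0.12, 0.22)) * size
                b = float(rng.uniform(0.10, 0.18)) * size
                margin = math.hypot(max(a, b), max(a, b)) + 1
                cx = float(rng.uniform(margin, size - margin))
                cy = float(rng.uniform(margin, size - margin))
                lesions = (Lesion(center=(cx, cy), axes=(a, b),
                                  angle=float(rng.uniform(0, math.pi)), stage=stage),)
            spec = SceneSpec(width=size, height=size, lesions=lesions, seed=scene_seed)
            out.append(TestScene(scene=spec, rendered=render_rgb(spec, tissue, camera),
                                 true_stage=stage))
    return out
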