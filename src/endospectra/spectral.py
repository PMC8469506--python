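"""RGB -> 401-band spectral reconstruction from a 24-patch color target.

The conversion module is built once per endoscope/modality from a paired
observation of a standard 24-patch color target: the camera's 24 RGB triplets
on one side, the spectrometer's 24 reference reflectance spectra (380-780 nm,
1 nm) on the other.  A multivariate polynomial regression maps expanded,
linearized RGB features to all 401 bands; applying the fitted matrix per pixel
turns an ordinary endoscopic image into a spectral cube.

With only 24 training samples the default expansion is degree 3 (20 monomial
features) with a tiny ridge penalty (1e-6) for numerical stability.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    DimensionError,
    GridError,
    RangeError,
)
from .grid import DEFAULT_GRID, N_BANDS, WavelengthGrid, check_same_grid, validate_spectrum

SRGB_TRANSFER = "srgb"
GAMMA_TRANSFER = "gamma"
IDENTITY_TRANSFER = "identity"
_TRANSFERS = (SRGB_TRANSFER, GAMMA_TRANSFER, IDENTITY_TRANSFER)
_CHANNEL_NAMES = ("red", "green", "blue")


# ---------------------------------------------------------------------------
# transfer functions


def linearize_rgb(rgb: Sequence[float] | np.ndarray, transfer: str = SRGB_TRANSFER,
                  gamma: float = 2.2) -> np.ndarray:
    """Invert a display/camera transfer curve, mapping encoded [0,1] RGB to linear.

    ``transfer`` is one of ``"srgb"`` (the standard piecewise curve),
    ``"gamma"`` (pure power law with exponent ``gamma``) or ``"identity"``.
    Works on a single triplet or any (..., 3) array.
    """
    arr = np.asarray(rgb, dtype=float)
    if arr.shape[-1] != 3:
        raise DimensionError(f"expected RGB triplets with last axis 3, got shape {arr.shape}")
    for ch in range(3):
        channel = arr[..., ch]
        if np.any(channel < 0) or np.any(channel > 1) or not np.all(np.isfinite(channel)):
            raise RangeError(f"{_CHANNEL_NAMES[ch]} channel outside [0, 1]")
    if transfer == IDENTITY_TRANSFER:
        return arr.copy()
    if transfer == SRGB_TRANSFER:
        return np.where(arr <= 0.04045, arr / 12.92, ((arr + 0.055) / 1.055) ** 2.4)
    if transfer == GAMMA_TRANSFER:
        return arr ** gamma
    raise ConfigurationError(f"unknown transfer {transfer!r}; expected one of {_TRANSFERS}")


def apply_transfer(linear: np.ndarray, transfer: str = SRGB_TRANSFER, gamma: float = 2.2) -> np.ndarray:
    """Forward transfer (encoding), the inverse of :func:`linearize_rgb`."""
    arr = np.clip(np.asarray(linear, dtype=float), 0.0, 1.0)
    if transfer == IDENTITY_TRANSFER:
        return arr
    if transfer == SRGB_TRANSFER:
        return np.where(arr <= 0.0031308, arr * 12.92, 1.055 * arr ** (1.0 / 2.4) - 0.055)
    if transfer == GAMMA_TRANSFER:
        return arr ** (1.0 / gamma)
    raise ConfigurationError(f"unknown transfer {transfer!r}; expected one of {_TRANSFERS}")


# ---------------------------------------------------------------------------
# feature expansion


@dataclass(frozen=True)
class FeatureExpansionSpec:
    """Polynomial feature expansion of a linear RGB triplet.

    Features are all monomials r^a g^b b^c with a+b+c <= degree, the constant
    term first, then ordered by total degree and within a degree by
    lexicographically descending exponent tuple (so degree 1 reads 1, r, g, b).
    """

    degree: int = 3
    includes_constant: bool = True

    def __post_init__(self):
        if self.degree < 1:
            raise ConfigurationError(f"expansion degree must be >= 1, got {self.degree}")
        if not self.includes_constant:
            raise ConfigurationError("expansions without a constant term are not supported")

    @property
    def exponents(self) -> list[tuple[int, int, int]]:
        out: list[tuple[int, int, int]] = []
        for d in range(self.degree + 1):
            for a in range(d, -1, -1):
                for b in range(d - a, -1, -1):
                    out.append((a, b, d - a - b))
        return out

    @property
    def n_features(self) -> int:
        # number of monomials in 3 variables up to `degree`: C(degree+3, 3)
        d = self.degree
        return (d + 1) * (d + 2) * (d + 3) // 6


def expand_features(linear_rgb: Sequence[float] | np.ndarray,
                    spec: FeatureExpansionSpec) -> np.ndarray:
    """Expand linear RGB into the monomial feature vector defined by ``spec``.

    Accepts a triplet or any (..., 3) array; returns (..., n_features).
    """
    arr = np.asarray(linear_rgb, dtype=float)
    if arr.shape[-1] != 3:
        raise DimensionError(f"expected RGB with last axis 3, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise RangeError("linear RGB contains non-finite values")
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    feats = [r ** a * g ** bb * b ** c for (a, bb, c) in spec.exponents]
    return np.stack(feats, axis=-1)


# ---------------------------------------------------------------------------
# color target reference


@dataclass(frozen=True)
class ColorTargetReference:
    """Reference reflectance spectra of the 24-patch color target."""

    patch_ids: tuple[str, ...]
    spectra: np.ndarray  # (24, 401)
    grid: WavelengthGrid = field(default_factory=lambda: DEFAULT_GRID)

    def __post_init__(self):
        spectra = np.asarray(self.spectra, dtype=float)
        if len(self.patch_ids) != 24 or spectra.shape != (24, N_BANDS):
            raise DimensionError(
                f"color target needs exactly 24 patches x {N_BANDS} bands, got {spectra.shape}")
        if len(set(self.patch_ids)) != 24:
            raise ConfigurationError("patch ids must be unique")
        for pid, s in zip(self.patch_ids, spectra):
            validate_spectrum(s, name=f"patch {pid}")
        object.__setattr__(self, "spectra", spectra)


# ---------------------------------------------------------------------------
# conversion matrix


@dataclass(frozen=True)
class ConversionMatrix:
    """Fitted regression coefficients mapping expanded RGB features to 401 bands."""

    coefficients: np.ndarray  # (n_features, 401)
    expansion: FeatureExpansionSpec
    fit_rmse_per_patch: np.ndarray  # (24,)
    transfer: str = SRGB_TRANSFER
    ridge: float = 0.0
    rank_deficient: bool = False
    modality: str = "wli"

    def __post_init__(self):
        coeff = np.asarray(self.coefficients, dtype=float)
        if coeff.shape != (self.expansion.n_features, N_BANDS):
            raise DimensionError(
                f"coefficients must be {self.expansion.n_features}x{N_BANDS}, got {coeff.shape}")
        if not np.all(np.isfinite(coeff)):
            raise RangeError("conversion matrix contains non-finite coefficients")
        rmse = np.asarray(self.fit_rmse_per_patch, dtype=float)
        if np.any(rmse < 0):
            raise RangeError("fit RMSE must be nonnegative")
        object.__setattr__(self, "coefficients", coeff)
        object.__setattr__(self, "fit_rmse_per_patch", rmse)

    @property
    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.coefficients.tobytes())
        h.update(str(self.expansion.degree).encode())
        h.update(self.transfer.encode())
        return h.hexdigest()[:16]


def fit_conversion_matrix(patch_rgbs: np.ndarray,
                          reference: ColorTargetReference,
                          spec: FeatureExpansionSpec | None = None,
                          *,
                          ridge: float = 1e-6,
                          transfer: str = SRGB_TRANSFER,
                          rgb_is_linear: bool = True,
                          modality: str = "wli") -> ConversionMatrix:
    """Least-squares fit of the feature->spectrum conversion on the 24 patch pairs.

    ``patch_rgbs`` is (24, 3); by default assumed already linearized (set
    ``rgb_is_linear=False`` to linearize through ``transfer`` first).  A ridge
    penalty ``ridge`` (lambda) stabilizes the solve; with ``ridge=0`` a
    rank-deficient design falls back to the minimum-norm solution and the
    returned matrix is flagged ``rank_deficient``.
    """
    if spec is None:
        spec = FeatureExpansionSpec()
    rgbs = np.asarray(patch_rgbs, dtype=float)
    if rgbs.shape != (24, 3):
        raise DimensionError(f"expected 24 RGB triplets, got shape {rgbs.shape}")
    check_same_grid(reference.grid, DEFAULT_GRID)
    linear = rgbs if rgb_is_linear else linearize_rgb(rgbs, transfer)

    X = expand_features(linear, spec)            # (24, F)
    Y = reference.spectra                        # (24, 401)
    rank_deficient = np.linalg.matrix_rank(X) < spec.n_features
    if ridge > 0:
        XtX = X.T @ X + ridge * np.eye(spec.n_features)
        coeff = np.linalg.solve(XtX, X.T @ Y)
    else:
        coeff, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)  # minimum-norm on deficiency

    residual = X @ coeff - Y
    rmse = np.sqrt(np.mean(residual ** 2, axis=1))
    return ConversionMatrix(coefficients=coeff, expansion=spec,
                            fit_rmse_per_patch=rmse, transfer=transfer,
                            ridge=ridge, rank_deficient=rank_deficient,
                            modality=modality)


# ---------------------------------------------------------------------------
# spectral cubes


@dataclass
class SpectralCube:
    """A per-pixel 401-band reflectance image with its wavelength grid."""

    values: np.ndarray  # (H, W, 401), reflectance, >= 0
    grid: WavelengthGrid = field(default_factory=lambda: DEFAULT_GRID)
    modality: str = "wli"
    matrix_hash: str = ""
    clip_fraction: float = 0.0  # fraction of entries clipped up to 0 at reconstruction

    def __post_init__(self):
        vals = np.asarray(self.values)
        if vals.ndim != 3 or vals.shape[2] != N_BANDS:
            raise DimensionError(f"cube must be (H, W, {N_BANDS}), got {vals.shape}")
        if np.any(vals < 0):
            raise RangeError("cube contains negative reflectance")
        self.values = vals

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


def apply_conversion(image: np.ndarray, matrix: ConversionMatrix,
                     transfer: str | None = None) -> SpectralCube:
    """Convert an (H, W, 3) image with channels in [0,1] into a spectral cube.

    Each pixel is linearized, feature-expanded and multiplied by the fitted
    conversion matrix; negative reconstructed reflectance is clipped to 0 and
    the clipped fraction recorded on the cube.
    """
    if transfer is None:
        transfer = matrix.transfer
    elif transfer != matrix.transfer:
        raise ConfigurationError(
            f"transfer {transfer!r} does not match the matrix's {matrix.transfer!r}")
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise DimensionError(f"expected (H, W, 3) image, got shape {img.shape}")
    linear = linearize_rgb(img, transfer)
    feats = expand_features(linear, matrix.expansion)        # (H, W, F)
    cube = feats @ matrix.coefficients                       # (H, W, 401)
    n_clipped = int(np.count_nonzero(cube < 0))
    cube = np.clip(cube, 0.0, None)
    return SpectralCube(values=cube, modality=matrix.modality,
                        matrix_hash=matrix.content_hash,
                        clip_fraction=n_clipped / cube.size)


def spectrum_rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square difference between two spectra on the same grid."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise GridError(f"spectra shapes differ: {a.shape} vs {b.shape}")
    if a.shape[-1] != N_BANDS:
        raise GridError(f"spectra must have {N_BANDS} bands")
    return float(np.sqrt(np.mean((a - b) ** 2, axis=-1)))
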