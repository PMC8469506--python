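"""Wavelength grid and reflectance-spectrum primitives.

Every spectrum in the package lives on a single fixed sampling of the visible
band: 401 points from 380 nm to 780 nm at 1 nm spacing.  Spectra are plain
1-D numpy arrays of unitless reflectance validated against this grid; a small
headroom above 1.0 (up to 1.5) is allowed for specular highlights.
"""

from __future__ import annotations

import numpy as np

from .errors import DimensionError, GridError, RangeError

N_BANDS = 401
WAVELENGTH_MIN_NM = 380.0
WAVELENGTH_MAX_NM = 780.0
REFLECTANCE_CEILING = 1.5  # headroom for specular highlights


class WavelengthGrid:
    """The 401-point, 1 nm sampling of 380-780 nm.

    Instances are interchangeable (the grid is fully determined by its
    endpoints and spacing); equality is value-based.
    """

    __slots__ = ("wavelengths",)

    def __init__(self, wavelengths: np.ndarray | None = None):
        if wavelengths is None:
            wavelengths = np.linspace(WAVELENGTH_MIN_NM, WAVELENGTH_MAX_NM, N_BANDS)
        wavelengths = np.asarray(wavelengths, dtype=float)
        if wavelengths.ndim != 1 or wavelengths.size != N_BANDS:
            raise DimensionError(f"wavelength grid must have {N_BANDS} points, got {wavelengths.size}")
        diffs = np.diff(wavelengths)
        if not (wavelengths[0] == WAVELENGTH_MIN_NM and wavelengths[-1] == WAVELENGTH_MAX_NM):
            raise GridError("grid must span 380-780 nm exactly")
        if not np.allclose(diffs, 1.0, atol=1e-9) or np.any(diffs <= 0):
            raise GridError("grid must be strictly ascending with uniform 1 nm spacing")
        self.wavelengths = wavelengths
        self.wavelengths.setflags(write=False)

    def __len__(self) -> int:
        return N_BANDS

    def __eq__(self, other: object) -> bool:
        return isinstance(other, WavelengthGrid) and np.array_equal(self.wavelengths, other.wavelengths)

    def __hash__(self) -> int:
        return hash((WAVELENGTH_MIN_NM, WAVELENGTH_MAX_NM, N_BANDS))

    def __repr__(self) -> str:
        return f"WavelengthGrid(380-780 nm, {N_BANDS} bands)"


#: The package-wide default grid.
DEFAULT_GRID = WavelengthGrid()


def validate_spectrum(values: np.ndarray, *, name: str = "spectrum") -> np.ndarray:
    """Validate a reflectance spectrum: length 401, values in [0, 1.5].

    Returns the values as a float array.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size != N_BANDS:
        raise DimensionError(f"{name} must have {N_BANDS} values, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise RangeError(f"{name} contains non-finite values")
    if np.any(arr < 0):
        raise RangeError(f"{name} contains negative reflectance")
    if np.any(arr > REFLECTANCE_CEILING):
        raise RangeError(f"{name} exceeds the reflectance ceiling {REFLECTANCE_CEILING}")
    return arr


def check_same_grid(a: WavelengthGrid, b: WavelengthGrid) -> None:
    if a != b:
        raise GridError("wavelength grids do not match")
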