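"""File formats: spectral-cube container, reference/capture CSVs, truth JSON.

The cube container is a single ``.npz`` file holding the (H, W, 401) cube, the
wavelength vector, the modality tag and the conversion-matrix hash; the round
trip is lossless.  Reference spectra CSVs carry a ``wavelength_nm`` column plus
``patch_01..patch_24`` and 401 data rows; patch-capture CSVs carry
``patch_id,r,g,b`` with 8-bit or normalized values (auto-detected by max > 1).
Ground-truth/detection JSON uses
``{image_id, width, height, boxes: [{stage, xmin, ymin, xmax, ymax, score?}]}``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .boxes import BoundingBox, Detection
from .errors import DataError
from .grid import DEFAULT_GRID, N_BANDS, WavelengthGrid
from .pca import PCABasis
from .spectral import ColorTargetReference, SpectralCube
from .stages import StageLabel

# ---------------------------------------------------------------------------
# images


def read_image(path: str | Path) -> np.ndarray:
    """Decode an 8-bit image file to an (H, W, 3) float array in [0, 1]."""
    img = np.asarray(Image.open(path).convert("RGB"))
    return img.astype(float) / 255.0


def write_image(path: str | Path, image: np.ndarray) -> None:
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        arr = np.clip(np.round(arr * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


# ---------------------------------------------------------------------------
# spectral cube container


def save_cube(path: str | Path, cube: SpectralCube) -> None:
    np.savez_compressed(
        path,
        values=cube.values,
        wavelengths=cube.grid.wavelengths,
        modality=np.array(cube.modality),
        matrix_hash=np.array(cube.matrix_hash),
        clip_fraction=np.array(cube.clip_fraction),
    )


def load_cube(path: str | Path) -> SpectralCube:
    with np.load(path, allow_pickle=False) as z:
        return SpectralCube(
            values=z["values"],
            grid=WavelengthGrid(z["wavelengths"]),
            modality=str(z["modality"]),
            matrix_hash=str(z["matrix_hash"]),
            clip_fraction=float(z["clip_fraction"]),
        )


def save_pca_basis(path: str | Path, basis: PCABasis) -> None:
    np.savez_compressed(path, mean_spectrum=basis.mean_spectrum,
                        loadings=basis.loadings,
                        explained_variance=basis.explained_variance,
                        k=np.array(basis.k))


def load_pca_basis(path: str | Path) -> PCABasis:
    with np.load(path, allow_pickle=False) as z:
        return PCABasis(mean_spectrum=z["mean_spectrum"], loadings=z["loadings"],
                        explained_variance=z["explained_variance"], k=int(z["k"]))


# ---------------------------------------------------------------------------
# reference spectra / patch capture CSVs


def write_reference_csv(path: str | Path, target: ColorTargetReference) -> None:
    df = pd.DataFrame({"wavelength_nm": target.grid.wavelengths})
    for pid, spectrum in zip(target.patch_ids, target.spectra):
        df[pid] = spectrum
    df.to_csv(path, index=False)


def read_reference_csv(path: str | Path) -> ColorTargetReference:
    df = pd.read_csv(path)
    if "wavelength_nm" not in df.columns:
        raise DataError(f"{path}: missing 'wavelength_nm' column")
    patch_cols = [c for c in df.columns if c != "wavelength_nm"]
    if len(patch_cols) != 24:
        raise DataError(f"{path}: expected 24 patch columns, found {len(patch_cols)}")
    if len(df) != N_BANDS:
        raise DataError(f"{path}: expected {N_BANDS} rows, found {len(df)}")
    grid = WavelengthGrid(df["wavelength_nm"].to_numpy())
    spectra = df[patch_cols].to_numpy().T
    return ColorTargetReference(patch_ids=tuple(patch_cols), spectra=spectra, grid=grid)


def write_capture_csv(path: str | Path, patch_ids: tuple[str, ...], rgbs: np.ndarray) -> None:
    pd.DataFrame({"patch_id": patch_ids, "r": rgbs[:, 0], "g": rgbs[:, 1],
                  "b": rgbs[:, 2]}).to_csv(path, index=False)


def read_capture_csv(path: str | Path) -> tuple[tuple[str, ...], np.ndarray]:
    """Read 24 patch RGB triplets; 8-bit values (max > 1) are scaled to [0, 1]."""
    df = pd.read_csv(path)
    required = {"patch_id", "r", "g", "b"}
    if not required.issubset(df.columns):
        raise DataError(f"{path}: needs columns {sorted(required)}")
    if len(df) != 24:
        raise DataError(f"{path}: expected 24 patches, found {len(df)}")
    rgbs = df[["r", "g", "b"]].to_numpy(dtype=float)
    if rgbs.max() > 1.0:
        rgbs = rgbs / 255.0
    return tuple(df["patch_id"]), rgbs


# ---------------------------------------------------------------------------
# ground-truth / detection JSON


def boxes_to_json(image_id: str, width: int, height: int,
                  boxes: list[tuple[BoundingBox, StageLabel]] | list[Detection]) -> dict:
    entries = []
    for item in boxes:
        if isinstance(item, Detection):
            box, stage, score = item.box, item.stage, item.score
        else:
            (box, stage), score = item, None
        entry = {"stage": stage.value, "xmin": box.xmin, "ymin": box.ymin,
                 "xmax": box.xmax, "ymax": box.ymax}
        if score is not None:
            entry["score"] = score
        entries.append(entry)
    return {"image_id": image_id, "width": width, "height": height, "boxes": entries}


def json_to_truth(record: dict) -> list[tuple[BoundingBox, StageLabel]]:
    return [(BoundingBox(b["xmin"], b["ymin"], b["xmax"], b["ymax"]),
             StageLabel.from_string(b["stage"])) for b in record["boxes"]]


def json_to_detections(record: dict) -> list[Detection]:
    return [Detection(box=BoundingBox(b["xmin"], b["ymin"], b["xmax"], b["ymax"]),
                      stage=StageLabel.from_string(b["stage"]),
                      score=float(b.get("score", 1.0)))
            for b in record["boxes"]]


def save_records(path: str | Path, records: list[dict]) -> None:
    Path(path).write_text(json.dumps(records, indent=2))


def load_records(path: str | Path) -> list[dict]:
    p = Path(path)
    if not p.exists():
        raise DataError(f"missing input file: {p}")
    return json.loads(p.read_text())
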