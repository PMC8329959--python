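"""Raster and table I/O: NIfTI / 16-bit TIFF images, masks, feature CSVs.

Images are single-slice HU rasters stored as signed 16-bit integers.  NIfTI
carries the pixel spacing in its header; TIFF uses a JSON sidecar
(``<name>.spacing.json``) holding ``{"spacing_mm": <float>}``.  Anisotropic
in-plane spacing is rejected with a clear error rather than silently
resampled.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .texture import ImageSlice, RoiMask, TextureFeatures

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "features_to_frame",
    "write_table",
    "read_table",
]

_NIFTI_EXT = (".nii", ".nii.gz")
_TIFF_EXT = (".tif", ".tiff")


def _is_nifti(path: Path) -> bool:
    return path.name.endswith(_NIFTI_EXT)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".spacing.json")


def _read_raster(path: str | Path) -> tuple[np.ndarray, float]:
    path = Path(path)
    if _is_nifti(path):
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:2]
        if not np.isclose(zooms[0], zooms[1]):
            raise ValueError(
                f"{path.name}: anisotropic in-plane spacing {zooms} not supported"
            )
        data = np.asanyarray(img.dataobj)
        data = np.squeeze(data)
        if data.ndim != 2:
            raise ValueError(f"{path.name}: expected a single 2D slice, got shape {data.shape}")
        return np.asarray(data, dtype=float), float(zooms[0])
    if path.suffix in _TIFF_EXT:
        data = tifffile.imread(str(path))
        if data.ndim != 2:
            raise ValueError(f"{path.name}: expected a single 2D slice, got shape {data.shape}")
        sidecar = _sidecar(path)
        if not sidecar.exists():
            raise FileNotFoundError(f"missing spacing sidecar {sidecar.name}")
        spacing = float(json.loads(sidecar.read_text())["spacing_mm"])
        return np.asarray(data, dtype=float), spacing
    raise ValueError(f"unsupported raster format: {path.name}")


def _write_raster(path: Path, data: np.ndarray, spacing: float, dtype) -> None:
    arr = np.round(data).astype(dtype)
    if _is_nifti(path):
        affine = np.diag([spacing, spacing, 1.0, 1.0])
        img = nib.Nifti1Image(arr, affine)
        img.header.set_zooms((spacing, spacing))
        nib.save(img, str(path))
    elif path.suffix in _TIFF_EXT:
        tifffile.imwrite(str(path), arr)
        _sidecar(path).write_text(json.dumps({"spacing_mm": spacing}))
    else:
        raise ValueError(f"unsupported raster format: {path.name}")


def read_image(path: str | Path) -> ImageSlice:
    data, spacing = _read_raster(path)
    return ImageSlice(data, spacing)


def write_image(path: str | Path, img: ImageSlice) -> None:
    _write_raster(Path(path), img.pixels, img.spacing, np.int16)


def read_mask(path: str | Path) -> RoiMask:
    data, _ = _read_raster(path)
    return RoiMask(data.astype(int))


def write_mask(path: str | Path, mask: RoiMask, spacing: float) -> None:
    _write_raster(Path(path), mask.mask.astype(np.uint8), spacing, np.uint8)


def features_to_frame(
    rows: list[tuple[str, TextureFeatures]],
) -> pd.DataFrame:
    """Long feature table: one row per (subject, SSF scale)."""
    records = []
    for subject_id, feats in rows:
        rec = {"subject_id": subject_id}
        rec.update(feats.as_dict())
        records.append(rec)
    cols = [
        "subject_id", "ssf", "mean", "sd", "mpp", "entropy",
        "skewness", "kurtosis", "n_pixels", "n_positive",
    ]
    return pd.DataFrame(records, columns=cols)


def write_table(df: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    """CSV writer with an optional provenance comment line (``# ...``)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
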