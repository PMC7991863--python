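"""Reading and writing images, masks and the pipeline's tables.

Supported image formats
-----------------------
* single-frame grayscale DICOM (spacing from ``PixelSpacing``);
* NIfTI-1 (spacing from the header zooms; 3-D volumes require an explicit
  ``slice_axis``/``slice_index`` — slice selection is deliberately the
  caller's decision);
* 16-bit grayscale PNG/TIFF with a JSON spacing sidecar
  ``{"pixel_spacing_mm": [row, column]}`` next to the image
  (``image.png`` -> ``image.json``). A raster without a sidecar is an
  error, never a silent default spacing.

Masks are any of the same formats; any nonzero value means "member".

Tables are UTF-8 CSV with a ``.`` decimal separator. The feature table has
a fixed column order (``subject_id``, ``group``, then the features in
report order) and floats are written with 12 significant digits so a
write/read round-trip preserves values to well beyond measurement
precision.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
import pydicom

from .errors import MetadataError, ParameterError, SchemaError, UnsupportedInputError
from .features import FEATURE_NAMES, FeatureVector
from .image import ImageSlice, ROIMask

__all__ = [
    "FeatureRecord",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "write_feature_table",
    "read_feature_table",
    "write_manifest",
    "read_manifest",
    "MANIFEST_COLUMNS",
    "FEATURE_TABLE_COLUMNS",
]

MANIFEST_COLUMNS = ("subject_id", "group", "image_path", "mask_path")
FEATURE_TABLE_COLUMNS = ("subject_id", "group") + FEATURE_NAMES

_RASTER_SUFFIXES = {".png", ".tif", ".tiff"}
_DICOM_SUFFIXES = {".dcm", ".dicom"}
_FLOAT_FORMAT = "%.12g"


@dataclasses.dataclass(frozen=True)
class FeatureRecord:
    """One subject's feature vector plus its identity and group label."""

    subject_id: str
    group_label: str
    features: FeatureVector

    def as_row(self) -> dict[str, object]:
        row: dict[str, object] = {
            "subject_id": self.subject_id,
            "group": self.group_label,
        }
        row.update(self.features.as_dict())
        return row


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _nifti_suffix(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def _read_pixels(
    path: Path,
    format_hint: str | None,
    slice_axis: int | None,
    slice_index: int | None,
) -> tuple[np.ndarray, tuple[float, float] | None]:
    """Return (2-D pixel array, spacing or None-if-unknown)."""
    fmt = format_hint
    if fmt is None:
        if path.suffix.lower() in _DICOM_SUFFIXES:
            fmt = "dicom"
        elif _nifti_suffix(path):
            fmt = "nifti"
        elif path.suffix.lower() in _RASTER_SUFFIXES:
            fmt = "raster"
        else:
            raise UnsupportedInputError(
                f"cannot infer format of {path} (use format_hint)"
            )

    if fmt == "dicom":
        ds = pydicom.dcmread(path)
        if int(getattr(ds, "NumberOfFrames", 1)) > 1:
            raise UnsupportedInputError(f"{path}: multi-frame DICOM")
        if int(getattr(ds, "SamplesPerPixel", 1)) != 1:
            raise UnsupportedInputError(f"{path}: non-grayscale DICOM")
        arr = ds.pixel_array
        spacing_attr = getattr(ds, "PixelSpacing", None)
        if spacing_attr is None:
            raise MetadataError(f"{path}: DICOM has no PixelSpacing")
        spacing = (float(spacing_attr[0]), float(spacing_attr[1]))
        return np.asarray(arr), spacing

    if fmt == "nifti":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        zooms = img.header.get_zooms()
        if data.ndim == 2:
            arr = data
            spacing = (float(zooms[0]), float(zooms[1]))
        elif data.ndim == 3:
            if slice_axis is None or slice_index is None:
                raise UnsupportedInputError(
                    f"{path}: 3-D NIfTI needs slice_axis and slice_index"
                )
            arr = np.take(data, slice_index, axis=slice_axis)
            inplane = [z for ax, z in enumerate(zooms[:3]) if ax != slice_axis]
            spacing = (float(inplane[0]), float(inplane[1]))
        else:
            raise UnsupportedInputError(f"{path}: {data.ndim}-D NIfTI")
        return np.asarray(arr), spacing

    if fmt == "raster":
        arr = np.asarray(iio.imread(path))
        if arr.ndim == 3:
            raise UnsupportedInputError(f"{path}: RGB/multi-channel raster")
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise MetadataError(
                f"{path}: raster image has no spacing sidecar {sidecar.name}"
            )
        meta = json.loads(sidecar.read_text())
        try:
            r, c = meta["pixel_spacing_mm"]
        except (KeyError, TypeError, ValueError) as exc:
            raise MetadataError(
                f"{sidecar}: expected {{'pixel_spacing_mm': [row, col]}}"
            ) from exc
        return arr, (float(r), float(c))

    raise UnsupportedInputError(f"unknown format hint {fmt!r}")


def read_image(
    path: str | Path,
    format_hint: str | None = None,
    slice_axis: int | None = None,
    slice_index: int | None = None,
) -> ImageSlice:
    """Read one grayscale slice with its physical pixel spacing.

    Parameters
    ----------
    path
        Image file; format inferred from the suffix unless ``format_hint``
        (``"dicom"``, ``"nifti"`` or ``"raster"``) is given.
    slice_axis, slice_index
        Required for 3-D NIfTI volumes; which 2-D slice to take.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr, spacing = _read_pixels(path, format_hint, slice_axis, slice_index)
    assert spacing is not None
    return ImageSlice(
        pixels=arr, pixel_spacing_mm=spacing, source_id=str(path)
    )


def write_image(image: ImageSlice, path: str | Path) -> Path:
    """Write an image as a 16-bit raster plus its spacing sidecar.

    The pixel grid must already be integer-valued in ``[0, 65535]``; the
    write/read round-trip is then bit-exact.
    """
    path = Path(path)
    if path.suffix.lower() not in _RASTER_SUFFIXES:
        raise UnsupportedInputError(
            f"write_image writes PNG/TIFF rasters, got {path.suffix!r}"
        )
    px = np.asarray(image.pixels)
    if np.any(px != np.round(px)) or px.min() < 0 or px.max() > 65535:
        raise ParameterError(
            "16-bit raster output needs integer pixels in [0, 65535]"
        )
    iio.imwrite(path, px.astype(np.uint16))
    _sidecar_path(path).write_text(
        json.dumps({"pixel_spacing_mm": list(image.pixel_spacing_mm)})
    )
    return path


def read_mask(
    path: str | Path,
    format_hint: str | None = None,
    slice_axis: int | None = None,
    slice_index: int | None = None,
) -> ROIMask:
    """Read a binary ROI mask; any nonzero pixel is a member.

    Raster masks do not require a spacing sidecar (spacing belongs to the
    image); other formats are read like images.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format_hint
    if fmt is None and path.suffix.lower() in _RASTER_SUFFIXES:
        arr = np.asarray(iio.imread(path))
        if arr.ndim == 3:
            raise UnsupportedInputError(f"{path}: RGB/multi-channel mask")
        return ROIMask(membership=arr)
    arr, _ = _read_pixels(path, fmt, slice_axis, slice_index)
    return ROIMask(membership=arr)


def write_mask(mask: ROIMask, path: str | Path) -> Path:
    """Write a mask as an 8-bit raster (members = 255)."""
    path = Path(path)
    if path.suffix.lower() not in _RASTER_SUFFIXES:
        raise UnsupportedInputError(
            f"write_mask writes PNG/TIFF rasters, got {path.suffix!r}"
        )
    iio.imwrite(path, (mask.membership.astype(np.uint8) * 255))
    return path


def write_feature_table(
    records: Iterable[FeatureRecord], path: str | Path
) -> Path:
    """Write feature records as CSV in the fixed documented column order."""
    rows = [r.as_row() for r in records]
    df = pd.DataFrame(rows, columns=list(FEATURE_TABLE_COLUMNS))
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
    return Path(path)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table, validating the column schema."""
    df = pd.read_csv(path)
    unknown = set(df.columns) - set(FEATURE_TABLE_COLUMNS)
    if unknown:
        raise SchemaError(
            f"{path}: unknown feature-table columns {sorted(unknown)}"
        )
    missing = set(FEATURE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(
            f"{path}: missing feature-table columns {sorted(missing)}"
        )
    return df[list(FEATURE_TABLE_COLUMNS)]


def write_manifest(rows: Sequence[dict[str, str]], path: str | Path) -> Path:
    """Write a cohort manifest (``subject_id,group,image_path,mask_path``)."""
    df = pd.DataFrame(list(rows), columns=list(MANIFEST_COLUMNS))
    df.to_csv(path, index=False)
    return Path(path)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and schema-check a cohort manifest."""
    df = pd.read_csv(path, dtype=str)
    if list(df.columns) != list(MANIFEST_COLUMNS):
        raise SchemaError(
            f"{path}: manifest columns must be {','.join(MANIFEST_COLUMNS)}"
        )
    return df
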