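"""Core in-memory containers: a 2-D image slice with physical pixel
spacing, and a binary region-of-interest mask congruent with it.

Conventions (fixed so congruence checks are meaningful):

* arrays are row-major, 0-based; index ``[i, j]`` is row ``i``, column ``j``;
* pixel centers of image and mask are aligned, i.e. a mask is valid for an
  image iff the two grids have identical shape;
* ``pixel_spacing_mm`` is ``(row_spacing, column_spacing)`` in millimetres,
  matching the DICOM ``PixelSpacing`` order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CongruenceError, ParameterError

__all__ = ["ImageSlice", "ROIMask"]


@dataclass(frozen=True)
class ImageSlice:
    """A single 2-D grayscale slice with physical pixel spacing.

    Parameters
    ----------
    pixels
        2-D array of non-negative, finite gray-level intensities.
    pixel_spacing_mm
        ``(row, column)`` pixel size in mm; both strictly positive.
    source_id
        Free-form provenance string (file path, phantom subject id, ...).
    """

    pixels: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ParameterError("pixels must be a non-empty 2-D array")
        if not np.all(np.isfinite(px)):
            raise ParameterError("pixel intensities must be finite")
        if np.any(px < 0):
            raise ParameterError("pixel intensities must be non-negative")
        sr, sc = self.pixel_spacing_mm
        if not (sr > 0 and sc > 0):
            raise ParameterError(
                f"pixel spacing must be positive, got ({sr}, {sc})"
            )
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "pixel_spacing_mm", (float(sr), float(sc)))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def pixel_area_mm2(self) -> float:
        sr, sc = self.pixel_spacing_mm
        return sr * sc


@dataclass(frozen=True)
class ROIMask:
    """A binary membership grid; any nonzero input value means "member".

    Binarization is idempotent: constructing a mask from an already-boolean
    grid changes nothing.
    """

    membership: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.membership)
        if m.ndim != 2 or m.size == 0:
            raise ParameterError("mask must be a non-empty 2-D array")
        object.__setattr__(self, "membership", m != 0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.membership.shape  # type: ignore[return-value]

    @property
    def pixel_count(self) -> int:
        return int(self.membership.sum())

    def check_congruent(self, image: ImageSlice) -> None:
        """Raise :class:`CongruenceError` unless mask and image grids match."""
        if self.shape != image.shape:
            raise CongruenceError(
                f"mask shape {self.shape} does not match image shape "
                f"{image.shape}"
            )
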