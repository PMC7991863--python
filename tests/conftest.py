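from __future__ import annotations

import numpy as np
import pytest

from histofeat import DistributionSpec, ImageSlice, ROIMask, SubjectSpec


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_image() -> ImageSlice:
    """2x2 image [[1,2],[3,4]] at 1 mm isotropic spacing."""
    return ImageSlice(
        pixels=np.array([[1, 2], [3, 4]], dtype=float),
        pixel_spacing_mm=(1.0, 1.0),
        source_id="tiny",
    )


@pytest.fixture
def full_mask_2x2() -> ROIMask:
    return ROIMask(membership=np.ones((2, 2), dtype=bool))


def make_pixel_image(values: np.ndarray, spacing=(1.0, 1.0)):
    """Wrap a flat pixel list as a 1xN image with a full mask."""
    arr = np.asarray(values, dtype=float).reshape(1, -1)
    image = ImageSlice(pixels=arr, pixel_spacing_mm=spacing, source_id="flat")
    mask = ROIMask(membership=np.ones_like(arr, dtype=bool))
    return image, mask


@pytest.fixture
def gaussian_subject_spec() -> SubjectSpec:
    return SubjectSpec(
        subject_id="g001",
        group_label="control",
        distribution=DistributionSpec("gaussian", 400.0, 50.0),
        roi_area_cm2=5.64,
    )
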