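"""First-order (histogram) texture features of an ROI.

All features here are functions of the ROI's gray-level distribution alone
and are therefore invariant to any spatial rearrangement of the ROI pixels.
The feature set is the classical first-order radiomics panel: mean, SD,
minimum, maximum, median, variance, Shannon entropy, uniformity (energy),
skewness, kurtosis, the three "size percentage" bands of the histogram, and
the physical ROI area.

Conventions
-----------
* Moments are population moments (divide by ``n``); kurtosis is the Pearson
  ratio ``m4 / m2**2`` (a Gaussian scores 3, not 0).
* Entropy is in bits (log base 2) over the normalized histogram; uniformity
  is the sum of squared bin probabilities. Both depend on the binning,
  which defaults to unit-width integer bins and is configurable.
* Size percentages count pixels against the mu +/- sigma thresholds:
  %L strictly below mu - sigma, %U strictly above mu + sigma, and %M the
  remainder, so pixels exactly on a boundary fall in the middle band and
  the three always sum to 100.
* A constant ROI has no standardized moments: skewness and kurtosis are
  reported as NaN by :func:`extract_features` (the scalar functions raise),
  while entropy, uniformity and the size bands take their limit values
  0, 1 and (0, 0, 100).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields

import numpy as np

from .errors import DegenerateInputError, EmptyROIError, ParameterError
from .image import ImageSlice, ROIMask

__all__ = [
    "IntensityHistogram",
    "FeatureVector",
    "FEATURE_NAMES",
    "extract_roi_pixels",
    "parse_binning",
    "build_histogram",
    "basic_stats",
    "entropy",
    "uniformity",
    "skewness",
    "kurtosis",
    "size_percentages",
    "roi_area",
    "extract_features",
]

#: Feature columns in canonical (report) order.
FEATURE_NAMES = (
    "mean_intensity",
    "sd_intensity",
    "min_intensity",
    "max_intensity",
    "median_intensity",
    "variance",
    "entropy",
    "size_pct_lower",
    "size_pct_upper",
    "size_pct_mean",
    "kurtosis",
    "skewness",
    "uniformity",
    "area_cm2",
)

MIN_ROI_PIXELS = 3


@dataclass(frozen=True)
class IntensityHistogram:
    """Binned gray-level counts over the ROI pixels.

    Bins are half-open ``[e_i, e_{i+1})`` except the last, which is closed,
    so every pixel lands in exactly one bin and ``sum(counts) == n_pixels``.
    """

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts, dtype=np.int64)
        if edges.ndim != 1 or counts.ndim != 1 or len(edges) != len(counts) + 1:
            raise ParameterError("need len(bin_edges) == len(counts) + 1")
        if np.any(np.diff(edges) <= 0):
            raise ParameterError("bin edges must be strictly increasing")
        if np.any(counts < 0):
            raise ParameterError("counts must be non-negative")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.n_pixels


@dataclass(frozen=True)
class FeatureVector:
    """The per-subject first-order feature panel.

    ``skewness`` and ``kurtosis`` are NaN for a constant-intensity ROI,
    where the standardized moments are undefined.
    """

    mean_intensity: float
    sd_intensity: float
    min_intensity: float
    max_intensity: float
    median_intensity: float
    variance: float
    entropy: float
    size_pct_lower: float
    size_pct_upper: float
    size_pct_mean: float
    kurtosis: float
    skewness: float
    uniformity: float
    area_cm2: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def extract_roi_pixels(image: ImageSlice, mask: ROIMask) -> np.ndarray:
    """Return the intensities at mask-member positions, multiplicity kept.

    Raises
    ------
    CongruenceError
        If image and mask grids differ.
    EmptyROIError
        If the mask selects fewer than three pixels.
    """
    mask.check_congruent(image)
    n = mask.pixel_count
    if n < MIN_ROI_PIXELS:
        raise EmptyROIError(
            f"ROI has {n} pixels; at least {MIN_ROI_PIXELS} are required"
        )
    return np.asarray(image.pixels)[mask.membership].astype(float)


def parse_binning(text: str) -> str | tuple[str, float]:
    """Parse a binning directive: ``unit``, ``count:<k>`` or ``width:<w>``."""
    if text == "unit":
        return "unit"
    kind, _, arg = text.partition(":")
    if kind == "count" and arg:
        k = int(arg)
        return ("count", k)
    if kind == "width" and arg:
        return ("width", float(arg))
    raise ParameterError(f"unrecognized binning directive: {text!r}")


def build_histogram(
    pixels: np.ndarray, binning: str | tuple[str, float] = "unit"
) -> IntensityHistogram:
    """Bin a pixel collection.

    ``unit``
        One bin per integer gray level spanning ``[floor(min), floor(max)]``.
    ``("count", k)``
        ``k`` equal-width bins over ``[min, max]`` (``k >= 2``).
    ``("width", w)``
        Bins of width ``w > 0`` anchored at ``min``.
    """
    x = np.asarray(pixels, dtype=float).ravel()
    if x.size == 0:
        raise EmptyROIError("cannot bin an empty pixel collection")
    if isinstance(binning, str):
        binning = parse_binning(binning)
    lo, hi = float(x.min()), float(x.max())
    if binning == "unit":
        lo_i, hi_i = math.floor(lo), math.floor(hi)
        edges = np.arange(lo_i, hi_i + 2, dtype=float)
    else:
        kind, arg = binning
        if kind == "count":
            k = int(arg)
            if k < 2:
                raise ParameterError(f"bin count must be >= 2, got {k}")
            edges = np.linspace(lo, hi if hi > lo else lo + 1.0, k + 1)
        elif kind == "width":
            w = float(arg)
            if w <= 0:
                raise ParameterError(f"bin width must be > 0, got {w}")
            nbins = max(1, math.ceil((hi - lo) / w)) if hi > lo else 1
            edges = lo + w * np.arange(nbins + 1, dtype=float)
        else:  # pragma: no cover - parse_binning guards this
            raise ParameterError(f"unknown binning kind {kind!r}")
    counts, _ = np.histogram(x, bins=edges)
    return IntensityHistogram(bin_edges=edges, counts=counts)


def basic_stats(
    pixels: np.ndarray,
) -> tuple[float, float, float, float, float, float]:
    """Return ``(mean, sd, min, max, median, variance)``.

    SD and variance are population (divide-by-n) moments; the median of an
    even-sized collection is the midpoint of the two central order
    statistics.
    """
    x = np.asarray(pixels, dtype=float).ravel()
    if x.size == 0:
        raise EmptyROIError("cannot summarize an empty pixel collection")
    var = float(np.var(x))
    return (
        float(np.mean(x)),
        float(math.sqrt(var)),
        float(np.min(x)),
        float(np.max(x)),
        float(np.median(x)),
        var,
    )


def entropy(hist: IntensityHistogram) -> float:
    """Shannon entropy of the normalized histogram, in bits.

    Zero iff a single bin holds all pixels; at most ``log2`` of the number
    of occupied bins. Empty bins contribute nothing (0 log 0 = 0).
    """
    p = hist.probabilities
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def uniformity(hist: IntensityHistogram) -> float:
    """Uniformity (energy): the sum of squared bin probabilities.

    One iff a single bin holds all pixels; ``1/k`` for mass spread evenly
    over ``k`` bins.
    """
    p = hist.probabilities
    return float(np.sum(p * p))


def _standardized_moment(x: np.ndarray, order: int) -> float:
    x = np.asarray(x, dtype=float).ravel()
    c = x - x.mean()
    m2 = float(np.mean(c * c))
    if m2 == 0.0:
        raise DegenerateInputError(
            "standardized moments are undefined for constant input"
        )
    return float(np.mean(c**order) / m2 ** (order / 2))


def skewness(pixels: np.ndarray) -> float:
    """Third standardized central moment ``m3 / m2**1.5``.

    Positive for a long right tail (the standard sign convention).
    Raises :class:`DegenerateInputError` on constant input.
    """
    return _standardized_moment(pixels, 3)


def kurtosis(pixels: np.ndarray) -> float:
    """Pearson (non-excess) kurtosis ``m4 / m2**2``; a Gaussian scores 3.

    Always at least ``skewness**2 + 1``. Raises
    :class:`DegenerateInputError` on constant input.
    """
    return _standardized_moment(pixels, 4)


def size_percentages(pixels: np.ndarray) -> tuple[float, float, float]:
    """Percentages of pixels below, above and within mu +/- sigma.

    Returns ``(%L, %U, %M)`` with ``%L`` the share strictly below
    ``mean - sd``, ``%U`` strictly above ``mean + sd`` and ``%M`` the rest;
    the three sum to 100 exactly up to floating-point rounding. A constant
    collection returns the degenerate limit ``(0, 0, 100)``.
    """
    x = np.asarray(pixels, dtype=float).ravel()
    if x.size == 0:
        raise EmptyROIError("cannot compute size percentages of empty input")
    mu = float(np.mean(x))
    sd = float(np.std(x))
    if sd == 0.0:
        return (0.0, 0.0, 100.0)
    n = x.size
    lower = 100.0 * np.count_nonzero(x < mu - sd) / n
    upper = 100.0 * np.count_nonzero(x > mu + sd) / n
    return (lower, upper, 100.0 - lower - upper)


def roi_area(mask: ROIMask, pixel_spacing_mm: tuple[float, float]) -> float:
    """Physical ROI area in cm^2: pixel count x row spacing x column
    spacing / 100."""
    sr, sc = pixel_spacing_mm
    if not (sr > 0 and sc > 0):
        raise ParameterError("pixel spacing must be positive")
    return mask.pixel_count * sr * sc / 100.0


def extract_features(
    image: ImageSlice,
    mask: ROIMask,
    binning: str | tuple[str, float] = "unit",
) -> FeatureVector:
    """Compute the full first-order feature panel for one image/mask pair.

    Deterministic for fixed inputs; entropy and uniformity use ``binning``
    (unit-width integer bins by default), all other features are computed
    directly from the pixel values.
    """
    px = extract_roi_pixels(image, mask)
    mean, sd, mn, mx, med, var = basic_stats(px)
    if sd == 0.0:
        ent, uni = 0.0, 1.0
        skew = kurt = float("nan")
    else:
        hist = build_histogram(px, binning)
        ent, uni = entropy(hist), uniformity(hist)
        skew, kurt = skewness(px), kurtosis(px)
    lo, up, mid = size_percentages(px)
    return FeatureVector(
        mean_intensity=mean,
        sd_intensity=sd,
        min_intensity=mn,
        max_intensity=mx,
        median_intensity=med,
        variance=var,
        entropy=ent,
        size_pct_lower=lo,
        size_pct_upper=up,
        size_pct_mean=mid,
        kurtosis=kurt,
        skewness=skew,
        uniformity=uni,
        area_cm2=roi_area(mask, image.pixel_spacing_mm),
    )
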