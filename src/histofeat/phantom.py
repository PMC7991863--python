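"""Synthetic single-slice phantoms with corpus-callosum-like ROIs.

The study design this package targets compares first-order histogram
features of a manually traced midsagittal corpus callosum ROI between two
subject groups. No image data accompanies that design, so this module
generates stand-in cohorts whose ROI intensity *distributions* are
controllable: mean, SD, skewness and Pearson kurtosis of the ROI pixels
can all be dialled to group-typical values (strongly left-skewed, heavy
tailed), and the ROI itself is a C-shaped arc band of prescribed physical
area on a grid with known pixel spacing.

Because every downstream feature is first-order (invariant to spatial
arrangement), ROI pixels are drawn i.i.d. from the requested distribution;
no spatial texture model is attempted, and none is needed for validity of
the downstream statistics.

Distribution families
---------------------
``gaussian``
    Plain normal; skewness/kurtosis targets must be absent.
``skew_normal``
    Azzalini skew-normal matched to (mean, SD, skewness). Its skewness is
    bounded (|skew| < 0.9953) and its kurtosis is determined by its
    skewness, so targets outside that range fall back to the mixture
    family below.
``two_component_mixture``
    Two-component Gaussian mixture whose first four moments are solved
    numerically to match (mean, SD, skewness, kurtosis). This covers the
    strongly skewed, high-kurtosis regime typical of the corpus callosum
    ROI (skewness near -2.5, Pearson kurtosis 10-14), which no single
    skew-normal can reach. Component widths are kept above 0.3 standard
    deviations so the synthetic histogram stays smooth rather than spiky.

Values are clipped to ``[value_floor, value_cap]`` (gray levels are
physically bounded); moment targets should therefore sit well inside the
clip range, as the study-default models do.

All generation is a pure function of (spec, seed).
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.optimize import brentq, least_squares

from .errors import ParameterError
from .image import ImageSlice, ROIMask
from .io import write_image, write_manifest, write_mask

__all__ = [
    "DistributionSpec",
    "SubjectSpec",
    "GroupModel",
    "CohortSpec",
    "control_group_model",
    "case_group_model",
    "study_cohort_spec",
    "generate_roi_mask",
    "sample_intensities",
    "generate_subject",
    "generate_cohort_subjects",
    "generate_cohort",
]

# Default grid geometry: 256 x 256 matrix over a 240 mm field of view.
DEFAULT_GRID = (256, 256)
DEFAULT_SPACING_MM = (240.0 / 256.0, 240.0 / 256.0)

# Background (non-ROI) tissue intensity model. The study design gives no
# background statistics, so these are free, documented choices: a dim,
# nearly uniform surround well separated from ROI intensities.
BACKGROUND_MEAN = 60.0
BACKGROUND_SD = 15.0

# Largest absolute skewness an Azzalini skew-normal can attain.
_SKEWNORM_MAX_SKEW = 0.9952717

_ARC_SPAN_RAD = 1.5 * math.pi  # C-shape: three quarters of a full ring


@dataclasses.dataclass(frozen=True)
class DistributionSpec:
    """Target moments of the ROI intensity distribution (gray levels).

    ``target_kurtosis`` is Pearson (non-excess) kurtosis: a Gaussian
    scores 3. For skewed families with no kurtosis target, the default is
    ``skewness**2 + 3`` (Gaussian excess over the moment bound).
    """

    family: str
    target_mean: float
    target_sd: float
    target_skewness: float | None = None
    target_kurtosis: float | None = None
    value_floor: float = 0.0
    value_cap: float = 4095.0

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "skew_normal", "two_component_mixture"):
            raise ParameterError(f"unknown distribution family {self.family!r}")
        if not self.target_sd > 0:
            raise ParameterError("target_sd must be > 0")
        if not (self.value_floor < self.target_mean < self.value_cap):
            raise ParameterError(
                "need value_floor < target_mean < value_cap, got "
                f"{self.value_floor} / {self.target_mean} / {self.value_cap}"
            )
        if self.value_floor < 0:
            raise ParameterError("value_floor must be >= 0")
        if self.family == "gaussian":
            if self.target_skewness is not None or self.target_kurtosis is not None:
                raise ParameterError(
                    "gaussian family takes no skewness/kurtosis targets"
                )
        else:
            s = self.target_skewness if self.target_skewness is not None else 0.0
            k = self.target_kurtosis
            if k is not None and k < s * s + 1.0:
                raise ParameterError(
                    f"kurtosis {k} is below the moment bound "
                    f"skewness^2 + 1 = {s * s + 1.0:.4f}"
                )


@dataclasses.dataclass(frozen=True)
class SubjectSpec:
    """Everything needed to synthesize one subject's slice and ROI."""

    subject_id: str
    group_label: str
    distribution: DistributionSpec
    roi_area_cm2: float
    grid_size: tuple[int, int] = DEFAULT_GRID
    pixel_spacing_mm: tuple[float, float] = DEFAULT_SPACING_MM

    def __post_init__(self) -> None:
        if not self.roi_area_cm2 > 0:
            raise ParameterError("roi_area_cm2 must be > 0")
        nr, nc = self.grid_size
        sr, sc = self.pixel_spacing_mm
        if self.roi_area_cm2 * 100.0 > nr * nc * sr * sc:
            raise ParameterError(
                f"ROI area {self.roi_area_cm2} cm^2 exceeds the grid area"
            )


@dataclasses.dataclass(frozen=True)
class GroupModel:
    """Population model for one study arm.

    ``distribution`` holds the group-level ROI moments; per-subject target
    means and SDs are drawn around them with the stated between-subject
    SDs (skewness/kurtosis are held at the group values, so the solved
    mixture is shared by all subjects of the arm). ROI areas are drawn
    from a normal with the stated mean/SD.
    """

    distribution: DistributionSpec
    mean_between_sd: float = 0.0
    sd_between_sd: float = 0.0
    area_mean_cm2: float = 5.64
    area_sd_cm2: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_between_sd < 0 or self.sd_between_sd < 0:
            raise ParameterError("between-subject SDs must be >= 0")
        if not self.area_mean_cm2 > 0 or self.area_sd_cm2 < 0:
            raise ParameterError("invalid area distribution")


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """A two-arm cohort: sizes, per-arm models, geometry and a seed."""

    n_control: int
    n_case: int
    control: GroupModel
    case: GroupModel
    grid_size: tuple[int, int] = DEFAULT_GRID
    pixel_spacing_mm: tuple[float, float] = DEFAULT_SPACING_MM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_case < 2:
            raise ParameterError("each arm needs at least 2 subjects")


def control_group_model(
    value_floor: float = 0.0, value_cap: float = 4095.0
) -> GroupModel:
    """Study-default healthy-control arm: mean gray level 336.56 with
    147.21 between-subject SD, within-ROI SD 31.26 (13.76 between),
    skewness -2.50, Pearson kurtosis 13.80, ROI area 5.64 +/- 0.69 cm^2."""
    return GroupModel(
        distribution=DistributionSpec(
            family="two_component_mixture",
            target_mean=336.56,
            target_sd=31.26,
            target_skewness=-2.50,
            target_kurtosis=13.80,
            value_floor=value_floor,
            value_cap=value_cap,
        ),
        mean_between_sd=147.21,
        sd_between_sd=13.76,
        area_mean_cm2=5.64,
        area_sd_cm2=0.69,
    )


def case_group_model(
    value_floor: float = 0.0, value_cap: float = 4095.0
) -> GroupModel:
    """Study-default patient arm: mean gray level 476.10 with 46.09
    between-subject SD, within-ROI SD 75.49 (11.47 between), skewness
    -2.58, Pearson kurtosis 10.34, ROI area 6.07 +/- 0.94 cm^2."""
    return GroupModel(
        distribution=DistributionSpec(
            family="two_component_mixture",
            target_mean=476.10,
            target_sd=75.49,
            target_skewness=-2.58,
            target_kurtosis=10.34,
            value_floor=value_floor,
            value_cap=value_cap,
        ),
        mean_between_sd=46.09,
        sd_between_sd=11.47,
        area_mean_cm2=6.07,
        area_sd_cm2=0.94,
    )


def study_cohort_spec(seed: int = 0) -> CohortSpec:
    """The default study-sized cohort: 20 controls vs 19 cases."""
    return CohortSpec(
        n_control=20,
        n_case=19,
        control=control_group_model(),
        case=case_group_model(),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# moment matching


def _skewnorm_shape(target_skew: float) -> float:
    """Invert the skew-normal skewness formula for the shape parameter."""

    def skew_of(a: float) -> float:
        d = a / math.sqrt(1.0 + a * a)
        num = (4.0 - math.pi) / 2.0 * (d * math.sqrt(2.0 / math.pi)) ** 3
        den = (1.0 - 2.0 * d * d / math.pi) ** 1.5
        return num / den

    s = abs(target_skew)
    if s >= _SKEWNORM_MAX_SKEW:
        raise ParameterError(
            f"skew-normal cannot reach |skewness| = {s:.4f}"
        )
    if s == 0.0:
        return 0.0
    a = brentq(lambda a: skew_of(a) - s, 1e-9, 1e6, xtol=1e-12)
    return math.copysign(a, target_skew)


def _gaussian_raw_moments(m: float, s: float) -> np.ndarray:
    return np.array(
        [
            m,
            m * m + s * s,
            m**3 + 3.0 * m * s * s,
            m**4 + 6.0 * m * m * s * s + 3.0 * s**4,
        ]
    )


def _mixture_std_moments(
    w: float, m1: float, s1: float, s2: float
) -> tuple[float, float, float]:
    """(variance, skewness, kurtosis) of the zero-mean two-component mix."""
    m2c = -w * m1 / (1.0 - w)
    r = w * _gaussian_raw_moments(m1, s1) + (1.0 - w) * _gaussian_raw_moments(
        m2c, s2
    )
    var = r[1]
    return float(var), float(r[2] / var**1.5), float(r[3] / var**2)


_mixture_cache: dict[tuple[float, float], tuple[float, float, float, float, float]] = {}

# Keep mixture components at least this wide (in target-SD units) so the
# solved histogram is smooth; the attainable (skew, kurtosis) region is
# still comfortably larger than the study regime.
_MIN_COMPONENT_SD = 0.3


def _solve_mixture(
    skew: float, kurt: float
) -> tuple[float, float, float, float, float]:
    """Solve (w, m1, s1, m2, s2) of a standardized two-component Gaussian
    mixture with the requested skewness and Pearson kurtosis.

    Deterministic multi-start least squares; results are cached. Raises
    :class:`ParameterError` when no mixture with the width floor attains
    the targets.
    """
    key = (round(skew, 9), round(kurt, 9))
    if key in _mixture_cache:
        return _mixture_cache[key]
    if kurt < skew * skew + 1.0:
        raise ParameterError(
            f"kurtosis {kurt} below the moment bound skew^2 + 1"
        )

    lo_ls = math.log(_MIN_COMPONENT_SD)
    hi_ls = math.log(2.5)

    def residual(p: np.ndarray) -> list[float]:
        w, m1, ls1, ls2 = p
        var, s, k = _mixture_std_moments(w, m1, math.exp(ls1), math.exp(ls2))
        return [var - 1.0, s - skew, (k - kurt) / max(abs(kurt), 1.0)]

    rng = np.random.default_rng(1234567)  # solver-internal, fixed
    best_cost, best = math.inf, None
    for _ in range(60):
        p0 = [
            rng.uniform(0.05, 0.95),
            rng.uniform(-3.0, 3.0),
            rng.uniform(lo_ls, hi_ls),
            rng.uniform(lo_ls, hi_ls),
        ]
        try:
            res = least_squares(
                residual,
                p0,
                bounds=([0.01, -8.0, lo_ls, lo_ls], [0.99, 8.0, hi_ls, hi_ls]),
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
            )
        except Exception:  # pragma: no cover - solver hiccup on one start
            continue
        cost = float(np.sum(np.square(res.fun)))
        if cost < best_cost:
            best_cost, best = cost, res.x
        if best_cost < 1e-22:
            break
    if best is None or best_cost > 1e-12:
        raise ParameterError(
            f"no two-component mixture matches skewness {skew}, "
            f"kurtosis {kurt} (residual {best_cost:.2e})"
        )
    w, m1, ls1, ls2 = (float(v) for v in best)
    s1, s2 = math.exp(ls1), math.exp(ls2)
    m2 = -w * m1 / (1.0 - w)
    sol = (w, m1, s1, m2, s2)
    _mixture_cache[key] = sol
    return sol


def _standardized_sampler(spec: DistributionSpec):
    """Return a function rng, n -> n draws with mean 0, SD 1 and the
    spec's target shape."""
    if spec.family == "gaussian":
        return lambda rng, n: rng.standard_normal(n)

    skew = spec.target_skewness if spec.target_skewness is not None else 0.0
    kurt = spec.target_kurtosis

    if spec.family == "skew_normal" and abs(skew) < _SKEWNORM_MAX_SKEW and kurt is None:
        a = _skewnorm_shape(skew)
        d = a / math.sqrt(1.0 + a * a)
        mu_z = d * math.sqrt(2.0 / math.pi)
        sd_z = math.sqrt(1.0 - mu_z * mu_z)

        def draw_sn(rng: np.random.Generator, n: int) -> np.ndarray:
            z = stats.skewnorm.rvs(a, size=n, random_state=rng)
            return (z - mu_z) / sd_z

        return draw_sn

    # Mixture route: explicit request, a kurtosis target, or a skewness
    # beyond the skew-normal range.
    if kurt is None:
        kurt = skew * skew + 3.0
    w, m1, s1, m2, s2 = _solve_mixture(skew, kurt)

    def draw_mix(rng: np.random.Generator, n: int) -> np.ndarray:
        comp = rng.random(n) < w
        z = np.where(
            comp,
            rng.normal(m1, s1, size=n),
            rng.normal(m2, s2, size=n),
        )
        return z

    return draw_mix


def sample_intensities(
    spec: DistributionSpec,
    n: int,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` i.i.d. gray-level values with the spec's target moments,
    clipped to ``[value_floor, value_cap]``.

    Sample moments converge to the targets as ``n`` grows provided the
    clip bounds are far from the bulk of the distribution.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    z = _standardized_sampler(spec)(rng, int(n))
    x = spec.target_mean + spec.target_sd * z
    return np.clip(x, spec.value_floor, spec.value_cap)


# ---------------------------------------------------------------------------
# geometry


def _connected(mask: np.ndarray) -> bool:
    _, ncomp = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    return ncomp == 1


def _accrete_disk(
    n_target: int,
    grid_size: tuple[int, int],
    center: tuple[float, float],
) -> np.ndarray:
    """Exactly ``n_target`` pixels accreted by distance from a center.

    Every selected pixel has an 8-neighbor strictly closer to the center,
    so the result is a single 8-connected component of exact size.
    """
    nr, nc = grid_size
    rr, cc = np.mgrid[0:nr, 0:nc]
    d = np.hypot(rr - center[0], cc - center[1]).ravel()
    order = np.argsort(d, kind="stable")[:n_target]
    mask = np.zeros(nr * nc, dtype=bool)
    mask[order] = True
    return mask.reshape(nr, nc)


def generate_roi_mask(
    target_area_cm2: float,
    grid_size: tuple[int, int] = DEFAULT_GRID,
    pixel_spacing_mm: tuple[float, float] = DEFAULT_SPACING_MM,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> ROIMask:
    """Generate a C-shaped arc-band ROI of the requested physical area.

    The pixel count is the nearest integer to
    ``target_area_cm2 * 100 / (row_spacing * col_spacing)``, so the
    realized area differs from the target only by sub-pixel rounding. The
    band's orientation and center are randomized (seeded); small targets
    fall back to a compact disk. The returned mask is always a single
    8-connected component.
    """
    nr, nc = grid_size
    sr, sc = pixel_spacing_mm
    if not (sr > 0 and sc > 0) or nr < 1 or nc < 1:
        raise ParameterError("invalid grid or spacing")
    px_area_mm2 = sr * sc
    n_target = round(target_area_cm2 * 100.0 / px_area_mm2)
    if n_target < 1 or target_area_cm2 <= 0:
        raise ParameterError(
            f"target area {target_area_cm2} cm^2 is below one pixel"
        )
    if target_area_cm2 * 100.0 > nr * nc * px_area_mm2:
        raise ParameterError(
            f"target area {target_area_cm2} cm^2 exceeds the grid area"
        )
    n_target = min(n_target, nr * nc)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    jitter = rng.uniform(-0.03, 0.03, size=2) * min(nr, nc)
    center = (nr / 2.0 + jitter[0], nc / 2.0 + jitter[1])
    gap_dir = rng.uniform(0.0, 2.0 * math.pi)

    if n_target >= 60:
        radius = math.sqrt(n_target / (_ARC_SPAN_RAD * 0.35))
        max_radius = 0.45 * min(nr, nc)
        if radius * 1.175 > max_radius:
            radius = max_radius / 1.175
        width = n_target / (_ARC_SPAN_RAD * radius)
        if width / 2.0 < radius:  # band fits: build by |r - R| ordering
            rr, cc = np.mgrid[0:nr, 0:nc]
            dr, dc = rr - center[0], cc - center[1]
            r = np.hypot(dr, dc)
            phi = np.arctan2(dc, dr)
            # angular distance from the gap direction, in [0, pi]
            dphi = np.abs(
                (phi - gap_dir + math.pi) % (2.0 * math.pi) - math.pi
            )
            gap_half = (2.0 * math.pi - _ARC_SPAN_RAD) / 2.0
            score = np.where(dphi >= gap_half, np.abs(r - radius), np.inf)
            flat = score.ravel()
            if np.isfinite(flat[np.argsort(flat, kind="stable")[n_target - 1]]):
                order = np.argsort(flat, kind="stable")[:n_target]
                band = np.zeros(nr * nc, dtype=bool)
                band[order] = True
                band = band.reshape(nr, nc)
                if _connected(band):
                    return ROIMask(membership=band)

    # Fallback (tiny targets, bands that would not fit or not connect):
    # a compact disk of the exact pixel count.
    return ROIMask(membership=_accrete_disk(n_target, grid_size, center))


# ---------------------------------------------------------------------------
# subjects and cohorts


def generate_subject(
    spec: SubjectSpec,
    seed: int | np.random.SeedSequence,
) -> tuple[ImageSlice, ROIMask]:
    """Synthesize one subject: dim background, bright skewed ROI.

    Pixel values are rounded to integers (as stored scanner images are)
    and the grid is carried with the spec's pixel spacing. Bit-identical
    output for identical (spec, seed).
    """
    root = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    mask_ss, bg_ss, roi_ss = root.spawn(3)
    mask = generate_roi_mask(
        spec.roi_area_cm2,
        spec.grid_size,
        spec.pixel_spacing_mm,
        seed=np.random.default_rng(mask_ss),
    )
    bg_rng = np.random.default_rng(bg_ss)
    img = bg_rng.normal(BACKGROUND_MEAN, BACKGROUND_SD, size=spec.grid_size)
    roi_vals = sample_intensities(
        spec.distribution, mask.pixel_count, seed=np.random.default_rng(roi_ss)
    )
    img[mask.membership] = roi_vals
    img = np.clip(np.round(img), 0, 65535)
    image = ImageSlice(
        pixels=img.astype(np.uint16),
        pixel_spacing_mm=spec.pixel_spacing_mm,
        source_id=spec.subject_id,
    )
    return image, mask


def _draw_subject_spec(
    subject_id: str,
    group_label: str,
    model: GroupModel,
    grid_size: tuple[int, int],
    pixel_spacing_mm: tuple[float, float],
    rng: np.random.Generator,
) -> SubjectSpec:
    base = model.distribution
    sd_i = base.target_sd
    if model.sd_between_sd > 0:
        sd_i = float(rng.normal(base.target_sd, model.sd_between_sd))
        sd_i = max(sd_i, 0.1 * base.target_sd, 1.0)
    mean_i = base.target_mean
    if model.mean_between_sd > 0:
        mean_i = float(rng.normal(base.target_mean, model.mean_between_sd))
        # keep the bulk of the subject's distribution inside the clip range
        mean_i = float(
            np.clip(mean_i, base.value_floor + 3.0 * sd_i, base.value_cap - 3.0 * sd_i)
        )
    area = model.area_mean_cm2
    if model.area_sd_cm2 > 0:
        area = float(rng.normal(model.area_mean_cm2, model.area_sd_cm2))
        area = max(area, 0.2 * model.area_mean_cm2)
    dist = dataclasses.replace(base, target_mean=mean_i, target_sd=sd_i)
    return SubjectSpec(
        subject_id=subject_id,
        group_label=group_label,
        distribution=dist,
        roi_area_cm2=area,
        grid_size=grid_size,
        pixel_spacing_mm=pixel_spacing_mm,
    )


def generate_cohort_subjects(
    spec: CohortSpec,
) -> Iterator[tuple[SubjectSpec, ImageSlice, ROIMask]]:
    """Yield every subject of the cohort in memory, controls first.

    Per-subject parameters and seeds derive deterministically from the
    cohort seed, so two runs with the same spec are identical.
    """
    root = np.random.SeedSequence(spec.seed)
    param_ss, subj_ss = root.spawn(2)
    param_rng = np.random.default_rng(param_ss)
    n_total = spec.n_control + spec.n_case
    child_seeds = subj_ss.spawn(n_total)
    plans = [("control", spec.control, i) for i in range(spec.n_control)] + [
        ("case", spec.case, i) for i in range(spec.n_case)
    ]
    for (group, model, i), child in zip(plans, child_seeds):
        sid = f"{group}{i + 1:03d}"
        sspec = _draw_subject_spec(
            sid, group, model, spec.grid_size, spec.pixel_spacing_mm, param_rng
        )
        image, mask = generate_subject(sspec, child)
        yield sspec, image, mask


def generate_cohort(spec: CohortSpec, out_dir: str | Path) -> pd.DataFrame:
    """Write a full cohort to disk and return its manifest.

    Layout: ``<out_dir>/images/<id>.png`` (+ spacing sidecars),
    ``<out_dir>/masks/<id>_mask.png`` and ``<out_dir>/manifest.csv`` with
    columns ``subject_id,group,image_path,mask_path`` (paths relative to
    ``out_dir``).
    """
    out = Path(out_dir)
    try:
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ParameterError(f"cannot create output directory {out}: {exc}")
    rows = []
    for sspec, image, mask in generate_cohort_subjects(spec):
        img_rel = f"images/{sspec.subject_id}.png"
        mask_rel = f"masks/{sspec.subject_id}_mask.png"
        write_image(image, out / img_rel)
        write_mask(mask, out / mask_rel)
        rows.append(
            {
                "subject_id": sspec.subject_id,
                "group": sspec.group_label,
                "image_path": img_rel,
                "mask_path": mask_rel,
            }
        )
    write_manifest(rows, out / "manifest.csv")
    return pd.DataFrame(rows)
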