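"""Independent brute-force reference implementations of every feature.

Deliberately written in plain Python (math.fsum, Counter, sorted lists)
with no numpy vectorization, so they share no code path with the package.
"""

from __future__ import annotations

import math
from collections import Counter


def o_mean(xs) -> float:
    return math.fsum(xs) / len(xs)


def o_central_moment(xs, k: int) -> float:
    mu = o_mean(xs)
    return math.fsum((x - mu) ** k for x in xs) / len(xs)


def o_variance(xs) -> float:
    return o_central_moment(xs, 2)


def o_sd(xs) -> float:
    return math.sqrt(o_variance(xs))


def o_median(xs) -> float:
    s = sorted(xs)
    n = len(s)
    mid = n // 2
    if n % 2:
        return float(s[mid])
    return (s[mid - 1] + s[mid]) / 2.0


def o_skewness(xs) -> float:
    m2 = o_central_moment(xs, 2)
    return o_central_moment(xs, 3) / m2**1.5


def o_kurtosis(xs) -> float:
    m2 = o_central_moment(xs, 2)
    return o_central_moment(xs, 4) / m2**2


def o_unit_bin_probs(xs) -> list[float]:
    """Probabilities of unit-width integer bins (empty bins excluded;
    they contribute nothing to entropy or uniformity)."""
    counts = Counter(math.floor(x) for x in xs)
    n = len(xs)
    return [c / n for c in counts.values()]


def o_entropy(xs) -> float:
    return -math.fsum(p * math.log2(p) for p in o_unit_bin_probs(xs))


def o_uniformity(xs) -> float:
    return math.fsum(p * p for p in o_unit_bin_probs(xs))


def o_size_percentages(xs) -> tuple[float, float, float]:
    mu, sd = o_mean(xs), o_sd(xs)
    if sd == 0.0:
        return (0.0, 0.0, 100.0)
    n = len(xs)
    lower = 100.0 * sum(1 for x in xs if x < mu - sd) / n
    upper = 100.0 * sum(1 for x in xs if x > mu + sd) / n
    return (lower, upper, 100.0 - lower - upper)


def o_roi_area(n_pixels: int, spacing) -> float:
    return n_pixels * spacing[0] * spacing[1] / 100.0


def o_feature_dict(xs, n_pixels: int, spacing) -> dict[str, float]:
    """The full panel, keyed like FeatureVector.as_dict()."""
    sd = o_sd(xs)
    lo, up, mid = o_size_percentages(xs)
    d = {
        "mean_intensity": o_mean(xs),
        "sd_intensity": sd,
        "min_intensity": float(min(xs)),
        "max_intensity": float(max(xs)),
        "median_intensity": o_median(xs),
        "variance": o_variance(xs),
        "entropy": 0.0 if sd == 0.0 else o_entropy(xs),
        "size_pct_lower": lo,
        "size_pct_upper": up,
        "size_pct_mean": mid,
        "kurtosis": float("nan") if sd == 0.0 else o_kurtosis(xs),
        "skewness": float("nan") if sd == 0.0 else o_skewness(xs),
        "uniformity": 1.0 if sd == 0.0 else o_uniformity(xs),
        "area_cm2": o_roi_area(n_pixels, spacing),
    }
    return d
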