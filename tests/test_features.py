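"""Unit and property tests for the first-order feature panel."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracle
from conftest import make_pixel_image
from histofeat import (
    ROIMask,
    basic_stats,
    build_histogram,
    entropy,
    extract_features,
    extract_roi_pixels,
    kurtosis,
    roi_area,
    size_percentages,
    skewness,
    uniformity,
)
from histofeat.errors import (
    CongruenceError,
    DegenerateInputError,
    EmptyROIError,
    ParameterError,
)
from histofeat.features import IntensityHistogram, parse_binning


class TestExtractRoiPixels:
    def test_row_selection(self, tiny_image):
        mask = ROIMask(membership=np.array([[1, 1], [0, 0]]))
        with pytest.raises(EmptyROIError):
            extract_roi_pixels(tiny_image, mask)  # only 2 member pixels

    def test_full_mask_returns_all(self, tiny_image, full_mask_2x2):
        px = extract_roi_pixels(tiny_image, full_mask_2x2)
        assert sorted(px) == [1, 2, 3, 4]

    def test_multiplicity_preserved(self):
        image, mask = make_pixel_image([7, 7, 7, 9])
        assert list(extract_roi_pixels(image, mask)) == [7, 7, 7, 9]

    def test_congruence_error(self, tiny_image):
        mask = ROIMask(membership=np.ones((3, 3)))
        with pytest.raises(CongruenceError):
            extract_roi_pixels(tiny_image, mask)


class TestHistogram:
    def test_unit_binning_integer_levels(self):
        h = build_histogram(np.array([5, 5, 7]), "unit")
        assert list(h.bin_edges) == [5, 6, 7, 8]
        assert list(h.counts) == [2, 0, 1]
        assert h.n_pixels == 3

    def test_constant_pixels_single_bin(self):
        h = build_histogram(np.full(10, 42.0), "unit")
        assert np.count_nonzero(h.counts) == 1

    def test_count_binning_conserves_n(self, rng):
        x = rng.normal(100, 10, size=10_000)
        h = build_histogram(x, ("count", 256))
        assert h.n_pixels == 10_000
        assert len(h.counts) == 256

    @pytest.mark.parametrize("binning", ["count:1", "width:0", "width:-2"])
    def test_bad_binning_parameters(self, binning):
        with pytest.raises(ParameterError):
            build_histogram(np.array([1.0, 2.0]), binning)

    def test_parse_binning_directives(self):
        assert parse_binning("unit") == "unit"
        assert parse_binning("count:64") == ("count", 64)
        assert parse_binning("width:2.5") == ("width", 2.5)
        with pytest.raises(ParameterError):
            parse_binning("quantile:4")

    def test_invalid_histogram_rejected(self):
        with pytest.raises(ParameterError):
            IntensityHistogram(bin_edges=[0, 1], counts=[1, 2])


class TestBasicStats:
    def test_hand_example(self):
        mean, sd, mn, mx, med, var = basic_stats(np.array([1, 2, 3, 4]))
        assert mean == 2.5
        assert var == 1.25
        assert sd == pytest.approx(1.118033988749895, rel=1e-12)
        assert med == 2.5
        assert (mn, mx) == (1, 4)

    def test_constant_input(self):
        mean, sd, mn, mx, med, var = basic_stats(np.full(5, 3.0))
        assert sd == 0 and var == 0
        assert mean == med == mn == mx == 3.0

    def test_variance_is_sd_squared(self, rng):
        x = rng.uniform(0, 1000, size=101)
        _, sd, _, _, _, var = basic_stats(x)
        assert var == pytest.approx(sd**2, rel=1e-12)

    def test_even_n_median_is_midpoint(self):
        assert basic_stats(np.array([1.0, 2.0, 10.0, 20.0]))[4] == 6.0


class TestEntropyUniformity:
    def test_single_bin_limits(self):
        h = build_histogram(np.full(7, 5.0), "unit")
        assert entropy(h) == 0.0
        assert uniformity(h) == 1.0

    @pytest.mark.parametrize("k", [2, 16, 64])
    def test_uniform_counts(self, k):
        h = IntensityHistogram(
            bin_edges=np.arange(k + 1, dtype=float), counts=np.full(k, 5)
        )
        assert entropy(h) == pytest.approx(math.log2(k), rel=1e-12)
        assert uniformity(h) == pytest.approx(1.0 / k, rel=1e-12)

    def test_small_count_example(self):
        h = IntensityHistogram(bin_edges=[0.0, 1, 2, 3], counts=[1, 1, 2])
        assert entropy(h) == pytest.approx(1.5, abs=1e-12)
        assert uniformity(h) == pytest.approx(0.375, abs=1e-12)

    def test_concentration_monotonicity(self):
        """Entropy strictly falls and uniformity strictly rises as the
        same mass occupies fewer bins."""
        prev_h, prev_u = math.inf, 0.0
        for k in (16, 8, 4, 2, 1):
            counts = np.full(k, 48 // k)
            h = IntensityHistogram(
                bin_edges=np.arange(k + 1, dtype=float), counts=counts
            )
            assert entropy(h) < prev_h
            assert uniformity(h) > prev_u
            prev_h, prev_u = entropy(h), uniformity(h)


class TestMoments:
    def test_symmetric_skewness_zero(self):
        assert skewness(np.array([1, 2, 3])) == pytest.approx(0.0, abs=1e-12)

    def test_right_tail_positive(self):
        assert skewness(np.array([0, 0, 0, 1])) == pytest.approx(
            2.0 / math.sqrt(3.0), rel=1e-12
        )

    def test_reflection_flips_sign(self, rng):
        x = rng.gamma(2.0, 10.0, size=500)
        assert skewness(2 * x.mean() - x) == pytest.approx(
            -skewness(x), rel=1e-9
        )

    def test_two_point_kurtosis_minimum(self):
        assert kurtosis(np.array([-1.0, 1.0] * 10)) == pytest.approx(
            1.0, rel=1e-12
        )

    def test_kurtosis_hand_example(self):
        assert kurtosis(np.array([0, 0, 0, 1])) == pytest.approx(
            7.0 / 3.0, rel=1e-12
        )

    def test_constant_input_raises(self):
        for fn in (skewness, kurtosis):
            with pytest.raises(DegenerateInputError):
                fn(np.full(8, 2.0))

    @given(
        st.lists(
            st.floats(0, 4095, allow_nan=False, allow_infinity=False),
            min_size=3,
            max_size=50,
        )
    )
    @settings(deadline=None, derandomize=True)
    def test_kurtosis_moment_bound(self, values):
        x = np.asarray(values)
        if np.std(x) < 1e-6:
            return
        assert kurtosis(x) >= skewness(x) ** 2 + 1.0 - 1e-9


class TestSizePercentages:
    def test_gaussian_bands(self, rng):
        x = rng.standard_normal(200_000)
        lo, up, mid = size_percentages(x)
        assert mid == pytest.approx(68.27, abs=0.5)
        assert lo == pytest.approx(15.87, abs=0.5)
        assert up == pytest.approx(15.87, abs=0.5)

    def test_constant_degenerate(self):
        assert size_percentages(np.full(9, 4.0)) == (0.0, 0.0, 100.0)

    def test_boundary_pixels_count_as_middle(self):
        # two-point data: every value sits exactly at mu +/- sigma
        assert size_percentages(np.array([0.0, 2.0] * 6)) == (0.0, 0.0, 100.0)

    @given(
        st.lists(
            st.floats(0, 4095, allow_nan=False, allow_infinity=False),
            min_size=3,
            max_size=50,
        )
    )
    @settings(deadline=None, derandomize=True)
    def test_conservation(self, values):
        lo, up, mid = size_percentages(np.asarray(values))
        assert lo + up + mid == pytest.approx(100.0, abs=1e-9)


class TestRoiArea:
    def test_study_scale_arithmetic(self):
        mask = ROIMask(membership=np.ones((1, 642)))
        assert roi_area(mask, (0.9375, 0.9375)) == pytest.approx(
            5.642578125, rel=1e-12
        )

    def test_single_pixel(self):
        mask = ROIMask(membership=np.ones((1, 1)))
        assert roi_area(mask, (1.0, 1.0)) == 0.01

    def test_spacing_scaling_law(self):
        mask = ROIMask(membership=np.ones((4, 4)))
        a1 = roi_area(mask, (0.5, 0.5))
        a2 = roi_area(mask, (1.0, 1.0))
        assert a2 == pytest.approx(4 * a1, rel=1e-12)


class TestExtractFeatures:
    def test_three_pixel_worked_example(self):
        image, mask = make_pixel_image([5, 5, 7])
        fv = extract_features(image, mask)
        expected = oracle.o_feature_dict([5, 5, 7], 3, (1.0, 1.0))
        for name, want in expected.items():
            assert getattr(fv, name) == pytest.approx(want, rel=1e-12), name
        # frozen hand values for the non-obvious entries
        assert fv.mean_intensity == pytest.approx(17 / 3, rel=1e-12)
        assert fv.entropy == pytest.approx(0.9182958340544896, rel=1e-12)
        assert fv.uniformity == pytest.approx(5 / 9, rel=1e-12)
        assert fv.skewness == pytest.approx(0.7071067811865476, rel=1e-9)
        assert fv.kurtosis == pytest.approx(1.5, rel=1e-9)

    def test_constant_roi_degenerate_panel(self):
        image, mask = make_pixel_image([9.0] * 12)
        fv = extract_features(image, mask)
        assert fv.entropy == 0.0
        assert fv.uniformity == 1.0
        assert (fv.size_pct_lower, fv.size_pct_upper, fv.size_pct_mean) == (
            0.0,
            0.0,
            100.0,
        )
        assert math.isnan(fv.skewness) and math.isnan(fv.kurtosis)

    def test_permutation_invariance(self, rng):
        values = rng.integers(0, 1024, size=40).astype(float)
        image_a, mask_a = make_pixel_image(values)
        image_b, mask_b = make_pixel_image(rng.permutation(values))
        fa = extract_features(image_a, mask_a).as_dict()
        fb = extract_features(image_b, mask_b).as_dict()
        for name in fa:
            assert fa[name] == pytest.approx(fb[name], rel=1e-12, nan_ok=True)

    @given(
        st.lists(
            st.floats(0, 4095, allow_nan=False, allow_infinity=False),
            min_size=3,
            max_size=50,
        )
    )
    @settings(deadline=None, derandomize=True, max_examples=150)
    def test_oracle_equivalence(self, values):
        """Every feature equals the independent brute-force formulas.

        Values sitting exactly on the mu +/- sigma band boundaries are
        excluded: there the pixel counts are discontinuous and the two
        implementations may legitimately round the threshold to opposite
        sides. The boundary rule itself is pinned in
        TestSizePercentages.test_boundary_pixels_count_as_middle.
        """
        mu, sd = oracle.o_mean(values), oracle.o_sd(values)
        if sd > 0 and any(
            min(abs(v - (mu - sd)), abs(v - (mu + sd))) < 1e-6 * max(sd, 1.0)
            for v in values
        ):
            return
        image, mask = make_pixel_image(values)
        fv = extract_features(image, mask).as_dict()
        want = oracle.o_feature_dict(values, len(values), (1.0, 1.0))
        for name, w in want.items():
            assert fv[name] == pytest.approx(
                w, rel=1e-12, abs=1e-9, nan_ok=True
            ), name
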