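import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafspec import (
    SphereMeasurement,
    SpectralMatrix,
    WavelengthAxis,
    average_leaves,
    compute_absorbance,
    crop,
    normalize_reflectance,
    savgol_smooth,
)
from leafspec.containers import AxisMismatchError, DegenerateReferenceError


def axis(lo, hi, step=1.0):
    return WavelengthAxis.regular(lo, hi, step)


def matrix(values, lo=400, kind="reflectance", ids=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    ids = ids or [f"p{i}" for i in range(values.shape[0])]
    return SpectralMatrix(ids, axis(lo, lo + values.shape[1] - 1), values, kind)


class TestNormalizeReflectance:
    def measurement(self, sample, white, stray, panel):
        n = len(sample)
        return SphereMeasurement(
            axis(400, 400 + n - 1), np.asarray(sample, float),
            np.asarray(white, float), np.asarray(stray, float),
            np.asarray(panel, float),
        )

    def test_white_sample_recovers_panel_reflectance(self):
        m = self.measurement([50, 50], [50, 50], [0, 0], [0.99, 0.99])
        assert np.allclose(normalize_reflectance(m), 0.99)

    def test_dark_sample_gives_zero(self):
        m = self.measurement([3, 4], [50, 60], [3, 4], [0.99, 0.99])
        assert np.allclose(normalize_reflectance(m), 0.0)

    def test_hand_arithmetic_per_band(self):
        # (10-0)/(40-0)*1 = 0.25 ; (20-20)/(40-20)*1 = 0.0
        m = self.measurement([10, 20], [40, 40], [0, 20], [1, 1])
        assert np.allclose(normalize_reflectance(m), [0.25, 0.0])

    def test_zero_denominator_names_band(self):
        m = self.measurement([10, 20], [40, 20], [0, 20], [1, 1])
        with pytest.raises(DegenerateReferenceError, match="401"):
            normalize_reflectance(m)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_common_radiance_rescaling(self, factor):
        sample = np.array([12.0, 30.0, 7.0])
        white = np.array([40.0, 45.0, 50.0])
        stray = np.array([1.0, 2.0, 0.5])
        panel = np.array([0.95, 0.97, 0.99])
        base = normalize_reflectance(self.measurement(sample, white, stray, panel))
        scaled = normalize_reflectance(
            self.measurement(sample * factor, white * factor,
                             stray * factor, panel))
        assert np.allclose(base, scaled, rtol=1e-10)


class TestCrop:
    def test_analysis_range_has_1401_bands(self):
        s = SpectralMatrix(["p"], axis(350, 2500), np.zeros((1, 2151)),
                          "reflectance")
        out = crop(s, 400, 1800)
        assert out.n_bands == 1401
        assert out.axis.values[0] == 400 and out.axis.values[-1] == 1800

    def test_full_range_is_identity(self):
        s = matrix([[0.1, 0.2, 0.3]])
        out = crop(s, 400, 402)
        assert np.array_equal(out.values, s.values)
        assert out.axis == s.axis

    def test_empty_selection_raises(self):
        s = SpectralMatrix(["p"], axis(350, 2500), np.zeros((1, 2151)),
                          "reflectance")
        with pytest.raises(ValueError, match="no band"):
            crop(s, 3000, 3100)

    def test_inverted_range_raises(self):
        with pytest.raises(ValueError):
            crop(matrix([[0.1, 0.2]]), 500, 400)

    def test_nested_crops_equal_single_inner_crop(self):
        rng = np.random.default_rng(0)
        s = SpectralMatrix(["p"], axis(350, 2500),
                          rng.random((1, 2151)), "reflectance")
        twice = crop(crop(s, 400, 1800), 600, 900)
        once = crop(s, 600, 900)
        assert np.array_equal(twice.values, once.values)
        assert twice.axis == once.axis


class TestSavgolSmooth:
    def test_constant_spectrum_unchanged(self):
        s = matrix([np.full(200, 0.37)])
        out = savgol_smooth(s)
        assert np.allclose(out.values, 0.37, atol=1e-12)

    def test_quadratic_preserved_including_edges_both_windows(self):
        wl = axis(400, 1200).values
        y = 1e-7 * wl ** 2 - 3e-4 * wl + 0.3
        s = SpectralMatrix(["p"], WavelengthAxis(wl), y[None, :], "reflectance")
        out = savgol_smooth(s, order=2, window_a_nm=31, window_b_nm=51,
                            boundary_nm=800)
        assert np.abs(out.values[0] - y).max() <= 1e-9

    def test_impulse_response_matches_normal_equations_kernel(self):
        # analytic order-2 SG kernel on 5 points: solve the 5x3 LS problem
        x = np.arange(-2, 3)
        V = np.vander(x, 3, increasing=True)
        kernel = V @ np.linalg.solve(V.T @ V, V.T)  # smoother matrix
        center_weights = kernel[2]  # response of the centre point
        n = 51
        y = np.zeros(n)
        y[25] = 1.0
        s = SpectralMatrix(["p"], axis(400, 400 + n - 1), y[None, :],
                          "reflectance")
        out = savgol_smooth(s, order=2, window_a_nm=5, window_b_nm=5,
                            boundary_nm=1e9)
        assert np.allclose(out.values[0, 23:28], center_weights, atol=1e-12)

    def test_even_window_in_samples_rejected(self):
        s = matrix([np.zeros(100)])
        with pytest.raises(ValueError, match="even"):
            savgol_smooth(s, window_a_nm=30)

    def test_window_longer_than_spectrum_rejected(self):
        s = matrix([np.zeros(21)])
        with pytest.raises(ValueError, match="exceeds"):
            savgol_smooth(s, window_a_nm=31, window_b_nm=31)

    def test_nonuniform_axis_rejected(self):
        ax = WavelengthAxis(np.array([400.0, 401.0, 403.0, 404.0, 405.0,
                                      406.0, 407.0]))
        s = SpectralMatrix(["p"], ax, np.zeros((1, 7)), "reflectance")
        with pytest.raises(ValueError, match="uniform"):
            savgol_smooth(s, window_a_nm=5, window_b_nm=5)


class TestAverageLeaves:
    def test_single_leaf_returned_unchanged(self):
        leaf = np.array([0.1, 0.2, 0.3])
        assert np.array_equal(average_leaves([leaf], "p"), leaf)

    def test_two_leaves_band_mean(self):
        out = average_leaves([np.array([0.2]), np.array([0.4])], "p")
        assert np.allclose(out, 0.3)

    def test_three_leaves_match_bruteforce_sum(self, rng):
        leaves = [rng.random(10) for _ in range(3)]
        brute = (leaves[0] + leaves[1] + leaves[2]) / 3.0
        assert np.allclose(average_leaves(leaves, "p"), brute, atol=1e-15)

    def test_axis_mismatch_raises(self):
        with pytest.raises(AxisMismatchError):
            average_leaves([np.zeros(3), np.zeros(4)], "p")


class TestComputeAbsorbance:
    def test_formula(self):
        r = matrix([[0.3]], kind="reflectance", ids=["a"])
        t = matrix([[0.2]], kind="transmittance", ids=["a"])
        out = compute_absorbance(r, t)
        assert np.allclose(out.absorbance.values, 0.5)
        assert not out.absorbance.out_of_range.any()

    def test_unphysical_sum_flagged_not_clamped(self):
        r = matrix([[0.6]], kind="reflectance", ids=["a"])
        t = matrix([[0.5]], kind="transmittance", ids=["a"])
        out = compute_absorbance(r, t)
        assert np.allclose(out.absorbance.values, -0.1)
        assert out.absorbance.out_of_range.all()

    def test_plant_intersection_and_attrition_record(self):
        r = matrix([[0.3, 0.3]] * 3, kind="reflectance", ids=["a", "b", "c"])
        t = matrix([[0.2, 0.2]] * 3, kind="transmittance", ids=["b", "c", "d"])
        out = compute_absorbance(r, t)
        assert out.absorbance.plant_ids == ["b", "c"]
        assert out.dropped == ["a", "d"]

    def test_empty_intersection_raises(self):
        r = matrix([[0.3]], kind="reflectance", ids=["a"])
        t = matrix([[0.2]], kind="transmittance", ids=["b"])
        with pytest.raises(ValueError, match="no plant"):
            compute_absorbance(r, t)

    def test_energy_conservation_on_synthetic_data(self, default_dataset):
        d = default_dataset
        out = compute_absorbance(d.reflectance, d.transmittance)
        total = (d.reflectance.values + d.transmittance.values
                 + out.absorbance.values)
        assert np.abs(total - 1.0).max() <= 1e-12
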