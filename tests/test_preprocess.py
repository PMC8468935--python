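import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meatspec import (
    CHAIN_PRESETS,
    ChainStep,
    GeneratorConfig,
    PreprocessingChain,
    SpectraSet,
    apply_chain,
    detrend,
    generate_dataset,
    get_preset,
    msc,
    sg_filter,
    snv,
    trim_wavelengths,
)
from meatspec.preprocess import log_inverse
from meatspec.split import concentration_gradient_split


def _set(wavelengths, rows, ids=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    ids = ids or [f"s{i}" for i in range(rows.shape[0])]
    return SpectraSet(wavelengths=np.asarray(wavelengths, float), reflectance=rows,
                      sample_ids=ids)


class TestTrim:
    def test_trim_bounds_are_closed(self):
        grid = 200.0 + 0.6 * np.arange(1501)  # 200 .. 1100
        s = _set(grid, np.ones((2, grid.size)))
        out = trim_wavelengths(s, 400.0, 1000.0)
        assert out.wavelengths.min() >= 400.0 - 1e-9
        assert out.wavelengths.max() <= 1000.0 + 1e-9

    def test_full_range_identity(self, toy_spectra):
        out = trim_wavelengths(toy_spectra, toy_spectra.wavelengths[0],
                               toy_spectra.wavelengths[-1])
        assert np.array_equal(out.reflectance, toy_spectra.reflectance)

    def test_boundary_enumeration(self):
        s = _set([390.0, 400.0, 400.6], [[1.0, 2.0, 3.0]])
        out = trim_wavelengths(s, 400.0, 1000.0)
        assert np.allclose(out.wavelengths, [400.0, 400.6])
        assert np.allclose(out.reflectance, [[2.0, 3.0]])

    def test_empty_result_rejected(self):
        s = _set([390.0, 395.0], [[1.0, 2.0]])
        with pytest.raises(ValueError, match="no wavelengths"):
            trim_wavelengths(s, 400.0, 1000.0)


class TestSnv:
    def test_simple_row(self):
        out = snv(_set([1, 2, 3], [[1.0, 2.0, 3.0]]))
        assert np.allclose(out.reflectance, [[-1.0, 0.0, 1.0]])

    def test_idempotence(self, toy_spectra):
        once = snv(toy_spectra)
        twice = snv(once)
        assert np.allclose(once.reflectance, twice.reflectance, atol=1e-12)

    def test_hand_mean_sd(self):
        row = np.array([2.0, 4.0, 4.0, 4.0, 5.0, 5.0, 7.0, 9.0])
        sd = np.sqrt(np.sum((row - 5.0) ** 2) / 7.0)  # sample sd, by hand
        out = snv(_set(np.arange(8.0), [row]))
        assert np.allclose(out.reflectance[0], (row - 5.0) / sd, atol=1e-12)

    def test_constant_row_names_sample(self):
        s = _set([1, 2, 3], [[1.0, 1.0, 1.0]], ids=["flat"])
        with pytest.raises(ValueError, match="flat"):
            snv(s)

    def test_row_moments_invariant(self, toy_spectra):
        out = snv(toy_spectra).reflectance
        assert np.abs(out.mean(axis=1)).max() < 1e-10
        assert np.abs(out.std(axis=1, ddof=1) - 1).max() < 1e-10


class TestMsc:
    def test_single_spectrum_identity(self):
        row = np.linspace(0.2, 0.8, 11)
        out = msc(_set(np.arange(11.0), [row]))
        assert np.allclose(out.reflectance[0], row, atol=1e-12)

    def test_exact_affine_scatter_removed(self):
        ref = np.linspace(0.2, 0.8, 11)
        x = 3.0 + 2.0 * ref
        out = msc(_set(np.arange(11.0), [x]), reference=ref)
        assert np.allclose(out.reflectance[0], ref, atol=1e-12)

    def test_reference_maps_to_itself(self):
        ref = 0.5 + 0.3 * np.sin(np.linspace(0, 3, 20))
        out = msc(_set(np.arange(20.0), [ref]), reference=ref)
        assert np.allclose(out.reflectance[0], ref, atol=1e-12)

    def test_two_row_closed_form_ols(self):
        rng = np.random.default_rng(0)
        ref = 0.5 + 0.3 * np.sin(np.linspace(0, 3, 30))
        eps = 0.01 * rng.normal(size=30)
        rows = np.vstack([ref + eps, 2.0 * ref - eps])
        s = _set(np.arange(30.0), rows)
        out = msc(s)  # reference = mean spectrum = 1.5 ref
        mean_ref = rows.mean(axis=0)
        for i in range(2):
            b, a = np.polyfit(mean_ref, rows[i], 1)  # independent OLS oracle
            assert np.allclose(out.reflectance[i], (rows[i] - a) / b, atol=1e-10)

    def test_uncorrelated_spectrum_rejected(self):
        ref = np.linspace(0.0, 1.0, 10)
        s = _set(np.arange(10.0), [np.full(10, 0.7)])
        with pytest.raises(ValueError, match="slope"):
            msc(s, reference=ref)

    def test_reference_length_checked(self):
        s = _set(np.arange(10.0), [np.linspace(0, 1, 10)])
        with pytest.raises(ValueError, match="reference length"):
            msc(s, reference=np.ones(5))


class TestDetrend:
    def test_annihilates_linear_row(self):
        grid = np.linspace(400, 1000, 101)
        s = _set(grid, [5.0 + 0.01 * grid])
        out = detrend(s, order=2)
        assert np.abs(out.reflectance).max() < 1e-9

    def test_order_zero_is_mean_centering(self, toy_spectra):
        out = detrend(toy_spectra, order=0)
        expected = toy_spectra.reflectance - toy_spectra.reflectance.mean(
            axis=1, keepdims=True)
        assert np.allclose(out.reflectance, expected, atol=1e-10)

    def test_residual_matches_normal_equations(self):
        grid = np.linspace(400, 1000, 121)
        row = np.sin(grid / 50.0) + 1e-4 * (grid - 700) ** 2
        out = detrend(_set(grid, [row]), order=2)
        # independent normal-equations solve on the raw Vandermonde
        v = np.vander(grid, 3, increasing=True)
        beta = np.linalg.solve(v.T @ v, v.T @ row)
        assert np.allclose(out.reflectance[0], row - v @ beta, atol=1e-8)

    def test_output_orthogonal_to_vandermonde(self, toy_spectra):
        order = 2
        out = detrend(toy_spectra, order=order)
        w = toy_spectra.wavelengths
        t = (w - w.mean()) / (np.ptp(w) / 2)
        v = np.vander(t, order + 1, increasing=True)
        inner = out.reflectance @ v
        scale = np.linalg.norm(out.reflectance) * np.linalg.norm(v)
        assert np.abs(inner).max() / scale < 1e-8


class TestSavitzkyGolay:
    def test_polynomial_exactness_including_edges(self):
        grid = np.linspace(400, 500, 51)
        row = 2.0 - 0.03 * grid + 1e-4 * grid**2
        out = sg_filter(_set(grid, [row]), window=5, polyorder=2, deriv=0)
        assert np.abs(out.reflectance[0] - row).max() < 1e-9

    def test_first_derivative_of_line_is_constant(self):
        grid = np.linspace(0, 10, 21)
        row = 3.0 * grid + 1.0
        out = sg_filter(_set(grid, [row]), window=5, polyorder=2, deriv=1)
        assert np.allclose(out.reflectance[0], 3.0, atol=1e-9)

    def test_classical_central_coefficients(self):
        # window 5, polyorder 2 smoothing coefficients (-3,12,17,12,-3)/35
        row = np.array([1.0, 2.0, 3.0, 10.0, 3.0, 2.0, 1.0])
        coeffs = np.array([-3.0, 12.0, 17.0, 12.0, -3.0]) / 35.0
        expected_center = coeffs @ row[1:6]
        out = sg_filter(_set(np.arange(7.0), [row]), window=5, polyorder=2)
        assert out.reflectance[0, 3] == pytest.approx(expected_center, abs=1e-12)

    def test_second_derivative_of_parabola(self):
        grid = np.linspace(0, 10, 41)
        row = 0.5 * grid**2
        out = sg_filter(_set(grid, [row]), window=7, polyorder=3, deriv=2)
        assert np.allclose(out.reflectance[0], 1.0, atol=1e-8)

    def test_noise_variance_reduction_ratio(self):
        # sum of squared S-G(5,2) coefficients = 0.4857...
        rng = np.random.default_rng(1)
        row = rng.normal(size=1000)
        out = sg_filter(_set(np.arange(1000.0), [row]), window=5, polyorder=2)
        ratio = out.reflectance[0].var() / row.var()
        assert abs(ratio - 0.4857) < 0.05

    def test_nonuniform_grid_rejected_for_derivative(self):
        grid = np.array([1.0, 2.0, 3.0, 5.0, 6.0, 7.0, 8.0])
        s = _set(grid, [np.ones(7)])
        with pytest.raises(ValueError, match="uniform"):
            sg_filter(s, window=5, polyorder=2, deriv=1)

    @pytest.mark.parametrize("window,polyorder,deriv", [(4, 2, 0), (5, 5, 0), (5, 2, 3)])
    def test_invalid_parameters_rejected(self, window, polyorder, deriv):
        s = _set(np.arange(9.0), [np.ones(9)])
        with pytest.raises(ValueError):
            sg_filter(s, window=window, polyorder=polyorder, deriv=deriv)


class TestLogInverse:
    def test_roundtrip_values(self):
        s = _set([1, 2], [[1.0, 0.1]])
        out = log_inverse(s)
        assert np.allclose(out.reflectance, [[0.0, 1.0]])

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            log_inverse(_set([1, 2], [[1.0, 0.0]]))


class TestChains:
    def test_all_presets_exist(self):
        assert set(CHAIN_PRESETS) == {
            "original", "msc", "snv", "sg", "sg_1der", "sg_2der",
            "sg_detrend_msc", "sg_detrend_snv",
        }

    def test_msc_and_snv_mutually_exclusive(self):
        with pytest.raises(ValueError, match="MSC and SNV"):
            PreprocessingChain([ChainStep("msc"), ChainStep("snv")])

    def test_empty_chain_is_identity(self, toy_spectra):
        out, state = apply_chain(toy_spectra, get_preset("original"))
        assert np.array_equal(out.reflectance, toy_spectra.reflectance)
        assert state["steps"] == []

    def test_chain_equals_manual_composition(self, toy_spectra):
        chain = get_preset("sg_detrend_snv")
        out, _ = apply_chain(toy_spectra, chain)
        manual = snv(detrend(sg_filter(toy_spectra, 5, 2, 0), order=2))
        assert np.allclose(out.reflectance, manual.reflectance, atol=1e-12)

    def test_msc_replay_freezes_calibration_reference(self):
        ds = generate_dataset(GeneratorConfig(wavelength_step=10.0, seed=21))
        split = concentration_gradient_split(ds.references["pH"], seed=4)
        cal = ds.spectra.subset(split.calibration_ids)
        pred = ds.spectra.subset(split.prediction_ids)
        chain = get_preset("sg_detrend_msc")

        cal_t, state = apply_chain(cal, chain)
        replayed, _ = apply_chain(pred, chain, fitted_state=state)
        refit, _ = apply_chain(pred, chain)
        assert not np.allclose(replayed.reflectance, refit.reflectance)

        # the frozen reference is the calibration-set mean at the MSC stage
        stage = detrend(sg_filter(cal, 5, 2, 0), order=2)
        stored = np.asarray(state["steps"][2]["reference"])
        assert np.allclose(stored, stage.reflectance.mean(axis=0), atol=1e-12)

    def test_replay_with_wrong_grid_rejected(self, toy_spectra):
        _, state = apply_chain(toy_spectra, get_preset("msc"))
        shrunk = trim_wavelengths(toy_spectra, 420.0, 680.0)
        with pytest.raises(ValueError, match="grid"):
            apply_chain(shrunk, get_preset("msc"), fitted_state=state)

    def test_unknown_step_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ChainStep("fourier")

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError):
            get_preset("osc")


class TestSampleEquivariance:
    @settings(max_examples=20, deadline=None)
    @given(st.permutations(list(range(6))))
    def test_operators_commute_with_sample_permutation(self, perm):
        # build inside (hypothesis cannot take fixtures)
        wavelengths = np.linspace(400.0, 700.0, 31)
        rng = np.random.default_rng(7)
        reflectance = 0.5 + 0.3 * np.sin(wavelengths / 60.0) + 0.05 * rng.normal(
            size=(6, wavelengths.size))
        ids = [f"s{i}" for i in range(6)]
        s = SpectraSet(wavelengths=wavelengths, reflectance=reflectance, sample_ids=ids)
        permuted = s.subset([ids[i] for i in perm])
        for op in (snv, lambda x: detrend(x, 2), lambda x: sg_filter(x, 5, 2, 1)):
            direct = op(permuted).reflectance
            indirect = op(s).reflectance[perm]
            assert np.allclose(direct, indirect, atol=1e-12)

    def test_metadata_untouched(self, toy_spectra):
        out, _ = apply_chain(toy_spectra, get_preset("sg_detrend_snv"))
        pd.testing.assert_frame_equal(out.metadata, toy_spectra.metadata)
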