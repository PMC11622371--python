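import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from specdiff import (
    PeakList,
    PoissonScaler,
    SpectrumSet,
    back_transform_loading,
    mean_center,
    poisson_scale,
    remove_peaks,
)
from specdiff.preprocess import ScalingState, preprocess


def _set(matrix, mz=None):
    matrix = np.asarray(matrix, dtype=float)
    if mz is None:
        mz = np.arange(1.0, matrix.shape[1] + 1)
    return SpectrumSet(PeakList(mz), matrix)


class TestRemovePeaks:
    def test_empty_removal_is_identity(self, toy_spectrumset):
        out = remove_peaks(toy_spectrumset, [])
        assert out is toy_spectrumset

    def test_remaining_columns_bit_identical(self, toy_spectrumset):
        out = remove_peaks(toy_spectrumset, [0])  # drop the saturated peak
        assert out.n_peaks == 4
        np.testing.assert_array_equal(out.intensities,
                                      toy_spectrumset.intensities[:, 1:])
        assert out.meta["removed_peaks"] == (0,)

    def test_removing_every_peak_is_an_error(self, toy_spectrumset):
        with pytest.raises(ValueError, match="every peak"):
            remove_peaks(toy_spectrumset, range(5))

    def test_unknown_id_is_an_error(self, toy_spectrumset):
        with pytest.raises(ValueError, match="unknown peak_id"):
            remove_peaks(toy_spectrumset, [99])


class TestPoissonScale:
    def test_constant_column_scales_to_sqrt(self):
        scaled, _ = poisson_scale(_set([[9.0], [9.0]]))
        np.testing.assert_allclose(scaled, [[3.0], [3.0]])

    def test_two_spectrum_column_divided_by_sqrt_mean(self):
        scaled, state = poisson_scale(_set([[0.0], [8.0]]))
        np.testing.assert_allclose(scaled, [[0.0], [4.0]])
        np.testing.assert_allclose(state.peak_scale, [2.0])

    def test_all_ones_matrix_is_fixed_point(self):
        scaled, state = poisson_scale(_set(np.ones((3, 4))))
        np.testing.assert_allclose(scaled, np.ones((3, 4)))
        np.testing.assert_allclose(state.peak_scale, np.ones(4))

    def test_zero_mean_column_is_hard_error(self):
        with pytest.raises(ValueError, match="zero mean"):
            poisson_scale(_set([[1.0, 0.0], [1.0, 0.0]]))

    @given(arrays(np.float64, (4, 6),
                  elements=st.floats(min_value=0.1, max_value=1e6)))
    def test_scaling_is_invertible(self, m):
        scaled, state = poisson_scale(_set(m))
        np.testing.assert_allclose(scaled * state.peak_scale, m, rtol=1e-10)


class TestMeanCenter:
    def test_already_centered_matrix_unchanged(self):
        m = np.array([[-1.0, 2.0], [1.0, -2.0]])
        state = ScalingState(np.ones(2))
        np.testing.assert_allclose(mean_center(m, state), m)

    def test_single_row_becomes_zero(self):
        state = ScalingState(np.ones(3))
        out = mean_center(np.array([[5.0, -2.0, 7.0]]), state)
        np.testing.assert_array_equal(out, np.zeros((1, 3)))

    def test_column_deviations_from_mean(self):
        state = ScalingState(np.ones(1))
        out = mean_center(np.array([[1.0], [3.0]]), state)
        np.testing.assert_allclose(out, [[-1.0], [1.0]])
        np.testing.assert_allclose(state.peak_mean, [2.0])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mean_center(np.ones((2, 3)), ScalingState(np.ones(2)))


class TestBackTransform:
    def test_unit_factors_reduce_to_renormalization(self):
        state = ScalingState(np.ones(3))
        lv = back_transform_loading([3.0, 0.0, 4.0], state)
        np.testing.assert_allclose(lv.coeffs, [0.6, 0.0, 0.8])

    def test_one_hot_direction_is_preserved(self):
        state = ScalingState(np.array([1.0, 1.0, 2.0]))
        lv = back_transform_loading([0.0, 0.0, 1.0], state)
        np.testing.assert_allclose(lv.coeffs, [0.0, 0.0, 1.0])

    def test_output_has_unit_norm(self, rng):
        state = ScalingState(rng.uniform(0.5, 20.0, size=10))
        lv = back_transform_loading(rng.normal(size=10), state)
        assert np.linalg.norm(lv.coeffs) == pytest.approx(1.0, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="does not match"):
            back_transform_loading([1.0, 2.0], ScalingState(np.ones(3)))

    def test_matches_brute_force_refit_on_rescaled_data(self, rng):
        """Back-transformed PCA loading equals a hand-rolled SVD of the
        explicitly scaled matrix, mapped back by explicit multiplication."""
        counts = rng.poisson(rng.uniform(50, 5000, size=3), size=(6, 3)) * 1.0
        centered, state = preprocess(_set(counts))

        from specdiff import fit_pca

        loading = fit_pca(centered, state).loadings[0].coeffs

        # independent oracle: numpy SVD on a manually scaled/centered copy
        scale = np.sqrt(counts.mean(axis=0))
        manual = counts / scale
        manual -= manual.mean(axis=0)
        _, _, vt = np.linalg.svd(manual, full_matrices=False)
        oracle = vt[0] * scale
        oracle /= np.linalg.norm(oracle)
        assert abs(float(oracle @ loading)) > 1 - 1e-10


class TestPoissonScalerEstimator:
    def test_transform_then_inverse_recovers_input(self, rng):
        X = rng.uniform(1.0, 100.0, size=(5, 7))
        sc = PoissonScaler().fit(X)
        np.testing.assert_allclose(sc.inverse_transform(sc.transform(X)), X,
                                   rtol=1e-10)

    def test_transformed_columns_are_centered(self, rng):
        X = rng.uniform(1.0, 100.0, size=(5, 7))
        Z = PoissonScaler().fit_transform(X)
        np.testing.assert_allclose(Z.mean(axis=0), np.zeros(7), atol=1e-12)

    def test_get_params_roundtrip(self):
        sc = PoissonScaler(row_scale=True)
        assert PoissonScaler(**sc.get_params()).row_scale is True

    def test_state_export_matches_functional_path(self, toy_spectrumset):
        _, state_fn = poisson_scale(toy_spectrumset)
        sc = PoissonScaler().fit(toy_spectrumset.intensities)
        np.testing.assert_allclose(sc.state().peak_scale, state_fn.peak_scale)


def test_pipeline_order_is_remove_scale_center(toy_spectrumset):
    centered, state = preprocess(toy_spectrumset, remove_ids=[0])
    assert state.removed_peaks == (0,)
    assert centered.shape == (4, 4)
    np.testing.assert_allclose(centered.mean(axis=0), np.zeros(4), atol=1e-12)
    # scale factors are sqrt of the retained columns' means
    np.testing.assert_allclose(
        state.peak_scale,
        np.sqrt(toy_spectrumset.intensities[:, 1:].mean(axis=0)),
    )
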