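import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nirquant import preprocess as pp
from nirquant.spectra_io import WavenumberAxis, subset_windows

from conftest import make_spectra


@pytest.fixture
def ax200():
    return WavenumberAxis.regular(5000.0, 5796.0, 4.0)  # 200 points


class TestSnv:
    def test_three_point_row(self, small_axis):
        ax = WavenumberAxis(np.array([5000.0, 5004.0, 5008.0]))
        out = pp.snv(make_spectra(ax, [[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out.absorbance[0], [-1.0, 0.0, 1.0])

    def test_constant_row_error_names_sample(self, small_axis):
        rows = np.vstack([np.arange(len(small_axis)), np.full(len(small_axis), 5.0)])
        with pytest.raises(ValueError, match="S2"):
            pp.snv(make_spectra(small_axis, rows))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_rows_standardised(self, seed):
        rng = np.random.default_rng(seed)
        ax = WavenumberAxis.regular(5000.0, 5796.0, 4.0)
        out = pp.snv(make_spectra(ax, rng.normal(2.0, 3.0, size=(3, 200))))
        np.testing.assert_allclose(out.absorbance.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.absorbance.std(axis=1, ddof=1), 1.0, atol=1e-12)


class TestMsc:
    def test_reference_is_column_mean(self, ax200, rng):
        rows = rng.normal(size=(150, 200))
        np.testing.assert_allclose(
            pp.msc_fit(make_spectra(ax200, rows)), rows.mean(axis=0)
        )

    def test_reference_of_scaled_pair(self, ax200, rng):
        r = rng.normal(size=200)
        ref = pp.msc_fit(make_spectra(ax200, np.vstack([r, 3 * r])))
        np.testing.assert_allclose(ref, 2 * r)

    def test_affine_distortion_removed(self, ax200, rng):
        ref = np.sin(np.linspace(0, 4, 200)) + 2.0
        x = 1.0 + 2.0 * ref
        out = pp.msc_apply(make_spectra(ax200, [x]), ref)
        np.testing.assert_allclose(out.absorbance[0], ref, atol=1e-10)

    def test_reference_itself_fixed(self, ax200, rng):
        ref = rng.normal(size=200)
        out = pp.msc_apply(make_spectra(ax200, [ref]), ref)
        np.testing.assert_allclose(out.absorbance[0], ref, atol=1e-10)

    def test_affine_family_equalised(self, ax200, rng):
        # rows a_i + b_i * s all collapse onto s after correction
        shape = np.cos(np.linspace(0, 3, 200)) + 5.0
        a = rng.normal(0, 0.5, size=6)
        b = rng.uniform(0.5, 2.0, size=6)
        rows = a[:, None] + b[:, None] * shape
        spectra = make_spectra(ax200, rows)
        out = pp.msc_apply(spectra, pp.msc_fit(spectra))
        corrected = out.absorbance
        assert np.ptp(corrected, axis=0).max() < 1e-10

    def test_vanishing_slope_errors(self, ax200, rng):
        ref = np.linspace(1.0, 2.0, 200)
        flat = np.full(200, 3.0)  # zero covariance with ref
        with pytest.raises(ValueError, match="S1"):
            pp.msc_apply(make_spectra(ax200, [flat]), ref)


class TestFiniteDifference:
    def test_linear_ramp_first_derivative(self, ax200):
        x = 3.0 * ax200.values
        out = pp.derivative_fd(make_spectra(ax200, [x]), order=1)
        np.testing.assert_allclose(out.absorbance[0], 3.0, atol=1e-9)

    def test_quadratic_second_derivative(self, ax200):
        x = ax200.values**2
        out = pp.derivative_fd(make_spectra(ax200, [x]), order=2)
        np.testing.assert_allclose(out.absorbance[0], 2.0, atol=1e-6)

    def test_constant_derivative_zero(self, ax200):
        out = pp.derivative_fd(make_spectra(ax200, [np.full(200, 7.0)]), order=1)
        np.testing.assert_allclose(out.absorbance[0], 0.0, atol=1e-12)

    def test_non_uniform_axis_rejected(self):
        ax = WavenumberAxis(np.array([5000.0, 5004.0, 5012.0, 5016.0, 5017.0]))
        with pytest.raises(ValueError, match="too short"):
            pp.derivative_fd(make_spectra(ax, [np.arange(5.0)]), order=1)


class TestSavgol:
    def test_cubic_reproduced_with_deriv0(self, ax200):
        v = ax200.values - ax200.values.mean()
        x = 1.0 + 0.5 * v - 0.01 * v**2 + 1e-4 * v**3
        out = pp.savgol(make_spectra(ax200, [x]), window=11, polyorder=3, deriv=0)
        np.testing.assert_allclose(out.absorbance[0], x, atol=1e-9 * np.abs(x).max())

    def test_window5_order2_weights_match_least_squares_oracle(self):
        # oracle: solve the 5-point quadratic fit directly
        d = np.arange(-2.0, 3.0)
        V = np.vander(d, 3, increasing=True)
        oracle = (np.linalg.pinv(V.T @ V) @ V.T)[0]  # centre-value weights
        np.testing.assert_allclose(oracle, np.array([-3, 12, 17, 12, -3]) / 35)
        ax = WavenumberAxis.regular(5000.0, 5032.0, 4.0)  # 9 points
        impulses = np.eye(9)
        out = pp.savgol(make_spectra(ax, impulses), window=5, polyorder=2, deriv=0)
        # column 4 of the response = weights of each input point at centre 4
        np.testing.assert_allclose(out.absorbance[2:7, 4], oracle, atol=1e-12)

    def test_second_derivative_of_quadratic(self, ax200):
        x = ax200.values**2
        out = pp.savgol(make_spectra(ax200, [x]), window=11, polyorder=3, deriv=2)
        np.testing.assert_allclose(out.absorbance[0], 2.0, rtol=1e-6)

    def test_window_larger_than_axis_rejected(self, small_axis):
        spectra = make_spectra(small_axis, np.zeros((1, len(small_axis))))
        with pytest.raises(ValueError, match="window"):
            pp.savgol(spectra, window=201, polyorder=2)

    def test_invalid_params_rejected(self, ax200):
        spectra = make_spectra(ax200, np.zeros((1, 200)))
        with pytest.raises(ValueError):
            pp.savgol(spectra, window=10, polyorder=3)
        with pytest.raises(ValueError):
            pp.savgol(spectra, window=5, polyorder=2, deriv=3)


class TestNorris:
    def test_ramp_first_derivative_exact(self, ax200):
        m = 0.25
        x = m * ax200.values
        for segment, gap in [(1, 1), (5, 5), (7, 3)]:
            out = pp.norris(make_spectra(ax200, [x]), segment, gap, order=1)
            np.testing.assert_allclose(out.absorbance[0], m, atol=1e-10)

    def test_constant_gives_zero(self, ax200):
        out = pp.norris(make_spectra(ax200, [np.full(200, 4.0)]), 5, 5, order=2)
        np.testing.assert_allclose(out.absorbance[0], 0.0, atol=1e-12)

    def test_segment1_gap1_matches_central_difference(self, ax200, rng):
        spectra = make_spectra(ax200, rng.normal(size=(2, 200)))
        a = pp.norris(spectra, segment=1, gap=1, order=1).absorbance
        b = pp.derivative_fd(spectra, order=1).absorbance
        np.testing.assert_allclose(a[:, 1:-1], b[:, 1:-1], atol=1e-12)

    def test_axis_too_short_rejected(self):
        ax = WavenumberAxis.regular(5000.0, 5036.0, 4.0)  # 10 points
        with pytest.raises(ValueError, match="must be <"):
            pp.norris(make_spectra(ax, np.zeros((1, 10))), segment=5, gap=3)


class TestPipeline:
    def test_snv_on_calibration_rows_centred(self, ax200, rng):
        cal = make_spectra(ax200, rng.normal(2, 1, size=(5, 200)))
        _, out = pp.fit_apply_pipeline([pp.PreprocessStep("snv")], cal, cal)
        np.testing.assert_allclose(out.absorbance.mean(axis=1), 0.0, atol=1e-12)

    def test_msc_pipeline_equalises_affine_family(self, ax200, rng):
        shape = np.cos(np.linspace(0, 3, 200)) + 5.0
        rows = rng.normal(0, 0.3, size=(6, 1)) + rng.uniform(0.5, 2, size=(6, 1)) * shape
        cal = make_spectra(ax200, rows)
        _, out = pp.fit_apply_pipeline([pp.PreprocessStep("msc")], cal, cal)
        assert np.ptp(out.absorbance, axis=0).max() < 1e-10

    def test_pipeline_state_comes_from_calibration(self, ax200, rng):
        cal = make_spectra(ax200, rng.normal(size=(4, 200)), ids=("a", "b", "c", "d"))
        val = make_spectra(ax200, rng.normal(5.0, 1.0, size=(3, 200)))
        pipe, _ = pp.fit_apply_pipeline([pp.PreprocessStep("msc")], cal, val)
        np.testing.assert_allclose(
            pipe.msc_references[0], cal.absorbance.mean(axis=0)
        )  # not val's mean

    def test_unfitted_transform_rejected(self, ax200, rng):
        pipe = pp.PreprocessPipeline([pp.PreprocessStep("snv")])
        with pytest.raises(RuntimeError):
            pipe.transform(make_spectra(ax200, rng.normal(size=(1, 200))))

    def test_derivative_does_not_cross_window_junction(self, axis, rng):
        # a step between two windows must not create a derivative spike
        wn = axis.values
        x = np.where(wn < 7000, 0.0, 10.0)  # windows are far from 7000
        spectra = subset_windows(
            make_spectra(axis, [x]), [[5200, 6700], [7700, 8800]]
        )
        out = pp.derivative_fd(spectra, order=1)
        np.testing.assert_allclose(out.absorbance[0], 0.0, atol=1e-12)

    def test_axis_preserved_by_all_operators(self, ax200, rng):
        spectra = make_spectra(ax200, rng.normal(size=(3, 200)) + 5.0)
        ref = pp.msc_fit(spectra)
        for out in [
            pp.snv(spectra),
            pp.msc_apply(spectra, ref),
            pp.derivative_fd(spectra, 1),
            pp.savgol(spectra),
            pp.norris(spectra),
        ]:
            np.testing.assert_array_equal(out.axis.values, ax200.values)
            assert out.sample_ids == spectra.sample_ids


class TestLabels:
    def test_composite_label_resolution(self):
        steps = pp.pipeline_from_label("MSC + SD + SG")
        assert [s.kind for s in steps] == ["msc", "savgol"]
        assert steps[1].params["deriv"] == 2

    def test_unknown_label_lists_valid_ones(self):
        with pytest.raises(ValueError, match="MSC"):
            pp.pipeline_from_label("OSC + SNV")
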