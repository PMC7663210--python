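import numpy as np
import pytest

from soilspec import (
    PreprocessPipeline,
    SpectrumSet,
    center_apply,
    center_fit,
    msc_apply,
    msc_fit,
    run_pipeline,
    sg_smooth,
)
from soilspec.exceptions import ConfigurationError, CorrectionError, ValidationError
from soilspec.preprocess import ALL_COMBINATIONS


def _ss(matrix, wl=None):
    matrix = np.atleast_2d(matrix)
    wl = np.arange(matrix.shape[1], dtype=float) + 400 if wl is None else wl
    return SpectrumSet(wl, matrix, [f"s{i}" for i in range(matrix.shape[0])])


def brute_force_savgol(x, window, polyorder):
    """Independent per-window polynomial fit evaluated at the window center."""
    half = window // 2
    xp = np.pad(x, half, mode="reflect")
    out = np.empty_like(x, dtype=float)
    t = np.arange(window) - half
    for i in range(x.size):
        coeffs = np.polyfit(t, xp[i : i + window], polyorder)
        out[i] = np.polyval(coeffs, 0.0)
    return out


class TestSavitzkyGolay:
    def test_constant_unchanged(self):
        ss = _ss(np.full((2, 30), 3.5))
        np.testing.assert_allclose(sg_smooth(ss, 11, 2).intensities, 3.5, atol=1e-12)

    def test_quadratic_exact_in_interior(self):
        t = np.linspace(0, 1, 50)
        ss = _ss(1.0 + 2 * t - 3 * t**2)
        out = sg_smooth(ss, 11, 2).intensities[0]
        np.testing.assert_allclose(out[5:-5], ss.intensities[0][5:-5], atol=1e-9)

    def test_matches_brute_force_window_fits(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(80)
        out = sg_smooth(_ss(x), 11, 2).intensities[0]
        np.testing.assert_allclose(out, brute_force_savgol(x, 11, 2), atol=1e-9)

    @pytest.mark.parametrize("window,polyorder", [(10, 2), (11, 11), (1, 0)])
    def test_bad_config_rejected(self, window, polyorder):
        with pytest.raises(ConfigurationError):
            sg_smooth(_ss(np.zeros(30)), window, polyorder)

    def test_noise_variance_reduced(self):
        """Smoothing strictly reduces mean squared second difference on
        noise-corrupted smooth signals, across 50 seeded draws."""
        t = np.linspace(0, 1, 200)
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = np.sin(2 * np.pi * 3 * t) + 0.1 * rng.standard_normal(200)
            y = sg_smooth(_ss(x), 11, 2).intensities[0]
            assert np.mean(np.diff(y, 2) ** 2) < np.mean(np.diff(x, 2) ** 2)


class TestMSC:
    def test_reference_is_column_mean(self):
        ss = _ss([[0.0, 0.0, 0.0], [2.0, 2.0, 2.0]])
        np.testing.assert_allclose(msc_fit(ss), [1.0, 1.0, 1.0])
        rng = np.random.default_rng(1)
        m = rng.standard_normal((5, 20))
        np.testing.assert_allclose(msc_fit(_ss(m)), [np.mean(m[:, j]) for j in range(20)], atol=1e-12)

    def test_affine_distortion_inverted(self):
        ref = np.sin(np.linspace(0, 3, 40)) + 2
        ss = _ss(2.0 * ref + 3.0)
        np.testing.assert_allclose(msc_apply(ss, ref).intensities[0], ref, atol=1e-10)

    def test_reference_is_fixed_point(self):
        ref = np.linspace(1, 2, 25)
        np.testing.assert_allclose(msc_apply(_ss(ref), ref).intensities[0], ref, atol=1e-10)

    def test_corrected_output_has_unit_ols_fit(self):
        """Re-fitting each corrected spectrum against the reference gives
        intercept 0 and slope 1 (the OLS oracle on the output)."""
        rng = np.random.default_rng(2)
        ref = np.abs(rng.standard_normal(30)).cumsum()
        x = rng.uniform(0.5, 1.5, (6, 1)) * ref + rng.uniform(-1, 1, (6, 1)) + 0.1 * rng.standard_normal((6, 30))
        out = msc_apply(_ss(x), ref).intensities
        for row in out:
            slope, intercept = np.polyfit(ref, row, 1)
            assert abs(slope - 1) < 1e-8 and abs(intercept) < 1e-8

    def test_scatter_invariance(self):
        """msc_apply(m*x + c) == msc_apply(x) for any m>0, c."""
        rng = np.random.default_rng(3)
        ref = np.abs(rng.standard_normal(40)).cumsum()
        x = _ss(ref + rng.standard_normal(40))
        base = msc_apply(x, ref).intensities
        for m, c in [(2.0, 0.0), (0.5, 3.0), (7.0, -1.5)]:
            distorted = _ss(m * x.intensities + c)
            np.testing.assert_allclose(msc_apply(distorted, ref).intensities, base, atol=1e-8)

    def test_zero_slope_reports_sample_id(self):
        ref = np.linspace(1, 2, 10)
        flat = _ss(np.full((1, 10), 5.0))
        with pytest.raises(CorrectionError) as err:
            msc_apply(flat, ref)
        assert err.value.sample_id == "s0"

    def test_needs_two_spectra(self):
        with pytest.raises(ValidationError):
            msc_fit(_ss(np.zeros((1, 5))))


class TestCentering:
    def test_mean_and_apply(self):
        ss = _ss([[1.0, 3.0], [3.0, 5.0]])
        mean = center_fit(ss)
        np.testing.assert_allclose(mean, [2.0, 4.0])
        out = center_apply(ss, mean)
        np.testing.assert_allclose(out.intensities.mean(axis=0), 0.0, atol=1e-9)

    def test_zero_mean_is_identity(self, toy_spectra):
        out = center_apply(toy_spectra, np.zeros(toy_spectra.n_channels))
        np.testing.assert_array_equal(out.intensities, toy_spectra.intensities)

    def test_not_idempotent_with_train_mean(self):
        train = _ss([[1.0, 2.0], [3.0, 6.0]])
        test = _ss([[10.0, 10.0]])
        mean = center_fit(train)
        once = center_apply(test, mean)
        twice = center_apply(once, mean)
        assert not np.allclose(once.intensities, twice.intensities)
        np.testing.assert_allclose(twice.intensities, test.intensities - 2 * mean)


class TestPipeline:
    def test_single_step_pipelines_equal_primitives(self, small_dataset):
        ss, _, _ = small_dataset
        np.testing.assert_array_equal(
            PreprocessPipeline(("sg",)).fit(ss).transform(ss).intensities,
            sg_smooth(ss, 11, 2).intensities,
        )
        np.testing.assert_array_equal(
            PreprocessPipeline(("msc",)).fit(ss).transform(ss).intensities,
            msc_apply(ss, msc_fit(ss)).intensities,
        )
        np.testing.assert_array_equal(
            PreprocessPipeline(("center",)).fit(ss).transform(ss).intensities,
            center_apply(ss, center_fit(ss)).intensities,
        )

    def test_full_pipeline_centers_training_data(self, small_dataset):
        ss, _, _ = small_dataset
        out = PreprocessPipeline().fit_transform(ss)
        np.testing.assert_allclose(out.intensities.mean(axis=0), 0.0, atol=1e-9)

    def test_all_seven_combinations_match_manual_composition(self, small_dataset):
        """Each of the 7 step combinations equals the by-hand composition of
        its primitives, and all 7 outputs are distinct."""
        ss, _, _ = small_dataset
        outputs = []
        for steps in ALL_COMBINATIONS:
            pipe = PreprocessPipeline(steps).fit(ss)
            got = run_pipeline(ss, pipe).intensities
            manual = ss
            if "sg" in steps:
                manual = sg_smooth(manual, 11, 2)
            if "msc" in steps:
                manual = msc_apply(manual, msc_fit(manual))
            if "center" in steps:
                manual = center_apply(manual, center_fit(manual))
            np.testing.assert_allclose(got, manual.intensities, atol=1e-10)
            outputs.append(got)
        for i in range(len(outputs)):
            for j in range(i + 1, len(outputs)):
                assert not np.allclose(outputs[i], outputs[j])

    def test_canonical_order_enforced(self):
        assert PreprocessPipeline(("center", "sg", "msc")).steps == ("sg", "msc", "center")

    def test_apply_does_not_leak_test_statistics(self, small_dataset):
        """Applying a fitted pipeline to unseen data leaves fitted state
        byte-identical (no train/test leakage)."""
        ss, _, _ = small_dataset
        train, test = ss.subset(range(40)), ss.subset(range(40, 60))
        pipe = PreprocessPipeline().fit(train)
        ref_before = pipe.msc_reference_.copy()
        mean_before = pipe.center_mean_.copy()
        pipe.transform(test)
        np.testing.assert_array_equal(pipe.msc_reference_, ref_before)
        np.testing.assert_array_equal(pipe.center_mean_, mean_before)
        # test output is NOT column-centered (train statistics were used)
        out = pipe.transform(test)
        assert np.abs(out.intensities.mean(axis=0)).max() > 1e-6

    def test_unfitted_transform_rejected(self, toy_spectra):
        with pytest.raises(ValidationError):
            PreprocessPipeline(("msc",)).transform(toy_spectra)

    def test_state_round_trip(self, small_dataset, tmp_path):
        ss, _, _ = small_dataset
        pipe = PreprocessPipeline().fit(ss)
        pipe.save(tmp_path / "p.json")
        back = PreprocessPipeline.load(tmp_path / "p.json")
        np.testing.assert_allclose(back.transform(ss).intensities, pipe.transform(ss).intensities)
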