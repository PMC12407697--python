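"""Generator: cortical patches, columnar maps, depth response, simulated runs."""

import numpy as np
import pytest

from lamodc import (AcquisitionModel, AliasingError, RunDesign, depth_response,
                    make_cortex_patch, simulate_odc_pattern, simulate_run,
                    simulate_vaso_pair)
from lamodc.design import condition_regressors
from lamodc.preproc import select_time_points
from lamodc.synthgen import BASELINE


class TestCortexPatch:
    def test_vertex_count_and_full_labelling(self):
        patch = make_cortex_patch(100, 100, spacing_mm=0.3)
        assert patch.n_vertices == 10_000
        assert patch.inner_surface.shape == (10_000, 3)
        assert not np.any(patch.region_label == "none")

    def test_flat_slab_constant_thickness(self):
        patch = make_cortex_patch(20, 20, thickness_mm=2.5, curvature_amp=0.0)
        diff = patch.outer_surface - patch.inner_surface
        assert np.allclose(diff[:, 2], 2.5)
        assert np.allclose(diff[:, :2], 0.0)

    def test_curved_slab_keeps_offset_but_varies_height(self):
        patch = make_cortex_patch(20, 20, thickness_mm=2.0, curvature_amp=0.5)
        assert np.ptp(patch.inner_surface[:, 2]) > 0.1
        assert np.allclose(patch.outer_surface[:, 2] - patch.inner_surface[:, 2], 2.0)

    def test_equal_fifths_counts_and_adjacency(self):
        patch = make_cortex_patch(100, 100)
        for region in ("V1", "V2a", "V2b", "V3a", "V3b"):
            assert np.count_nonzero(patch.region_label == region) == 2000
        # brute-force adjacency on the grid: V2a must touch V1, V3a touch V2b
        grid = patch.region_label.reshape(patch.n_y, patch.n_x)
        pairs = set(zip(grid[:, :-1].ravel(), grid[:, 1:].ravel()))
        assert ("V1", "V2a") in pairs
        assert ("V2b", "V3a") in pairs

    @pytest.mark.parametrize("kwargs", [dict(n_x=4), dict(thickness_mm=0.0),
                                        dict(spacing_mm=-1.0)])
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(ValueError):
            make_cortex_patch(**{**dict(n_x=20, n_y=20), **kwargs})


class TestOdcPattern:
    def test_spectral_peak_near_column_frequency(self):
        patch = make_cortex_patch(64, 64, spacing_mm=0.3,
                                  region_layout={"V1": 1.0})
        cmap = simulate_odc_pattern(patch, period_mm=1.0, seed=3)
        grid = patch.grid(cmap.preference)
        spec = np.abs(np.fft.fft2(grid)) ** 2
        fx = np.fft.fftfreq(64, d=0.3)
        FX, FY = np.meshgrid(fx, fx)
        f = np.sqrt(FX ** 2 + FY ** 2).ravel()
        power = spec.ravel()
        bins = np.arange(0.0, f.max(), 0.08)
        which = np.digitize(f, bins)
        radial = np.array([power[which == i].mean() if np.any(which == i) else 0.0
                           for i in range(1, bins.size)])
        peak_freq = bins[np.argmax(radial)] + 0.04
        assert 0.8 <= peak_freq <= 1.25

    def test_zero_outside_v1_and_bounded(self, patch):
        cmap = simulate_odc_pattern(patch, seed=1)
        outside = patch.region_label != "V1"
        assert np.all(cmap.preference[outside] == 0.0)
        assert np.all(np.abs(cmap.preference) <= 1.0)
        v1_mean = cmap.preference[patch.region_label == "V1"].mean()
        assert -0.2 < v1_mean < 0.2

    def test_infinite_gain_gives_binary_columns(self, patch):
        cmap = simulate_odc_pattern(patch, sigmoid_gain=np.inf, seed=2)
        v1 = patch.region_label == "V1"
        assert set(np.unique(cmap.preference[v1])) <= {-1.0, 1.0}

    def test_seed_determinism_and_decorrelation(self, patch):
        a = simulate_odc_pattern(patch, seed=7).preference
        b = simulate_odc_pattern(patch, seed=7).preference
        c = simulate_odc_pattern(patch, seed=8).preference
        v1 = patch.region_label == "V1"
        assert np.array_equal(a, b)
        r = np.corrcoef(a[v1], c[v1])[0, 1]
        assert abs(r) < 0.2

    def test_aliasing_error(self, patch):
        with pytest.raises(AliasingError):
            simulate_odc_pattern(patch, period_mm=0.5)  # 0.5 <= 2 * 0.3


class TestDepthResponse:
    def test_bold_amplitude_ratio(self):
        model = AcquisitionModel.ge_bold(pial_slope=3.0)
        a0, _, _ = depth_response(model, 0.0)
        a1, _, _ = depth_response(model, 1.0)
        assert np.isclose(a1 / a0, 4.0)

    def test_vaso_bump_argmax(self):
        model = AcquisitionModel.vaso(mid_peak_depth=0.5, pial_slope=0.0)
        d = np.arange(0, 1.01, 0.1)
        amp, _, _ = depth_response(model, d)
        assert d[np.argmax(amp)] == pytest.approx(0.5)

    def test_psf_and_noise_interpolate_monotonically(self):
        model = AcquisitionModel.ge_bold()
        d = np.linspace(0, 1, 11)
        _, fwhm, sigma = depth_response(model, d)
        assert np.all(np.diff(fwhm) >= 0)
        assert np.all(np.diff(sigma) >= 0)

    def test_depth_out_of_range(self):
        with pytest.raises(ValueError):
            depth_response(AcquisitionModel.ge_bold(), 1.2)


class TestSimulateRun:
    def test_volume_count_matches_design(self, patch, cmap):
        model = AcquisitionModel.ge_bold()
        series = simulate_run(patch, cmap, RunDesign(), model, seed=0)
        assert series.values.shape == (patch.n_vertices, 11, 90)

    def test_null_signal_is_flat_baseline(self, patch, cmap):
        model = AcquisitionModel.ge_bold(amplitude_base=0.0, venous_bias_amp=0.0,
                                         noise_sigma_deep=0.0, noise_sigma_pial=0.0)
        series = simulate_run(patch, cmap, RunDesign(), model, seed=0)
        assert np.allclose(series.values, BASELINE)

    def test_block_difference_matches_convolved_regressors(self, patch):
        """Noiseless, zero point spread, binary columns: the mean LEFT-minus-
        RIGHT signal at a preference +1 vertex equals twice the amplitude
        times baseline times the mean convolved regressor difference."""
        cmap = simulate_odc_pattern(patch, sigmoid_gain=np.inf, seed=4)
        design = RunDesign()
        model = AcquisitionModel.ge_bold(psf_fwhm_deep_mm=0.0, psf_fwhm_pial_mm=0.0,
                                         venous_bias_amp=0.0,
                                         noise_sigma_deep=0.0, noise_sigma_pial=0.0)
        series, truth = simulate_run(patch, cmap, design, model, seed=0,
                                     return_truth=True)
        idx, labels = select_time_points(design)
        reg = condition_regressors(design)
        diff = reg["LEFT"] - reg["RIGHT"]
        v = int(np.flatnonzero(cmap.preference == 1.0)[0])
        for d in (0, 5, 10):
            observed = (series.values[v, d, idx[labels == "LEFT"]].mean()
                        - series.values[v, d, idx[labels == "RIGHT"]].mean())
            expected = BASELINE * truth["amplitudes"][d] * (
                diff[idx[labels == "LEFT"]].mean() - diff[idx[labels == "RIGHT"]].mean())
            assert observed == pytest.approx(expected, abs=1e-9)

    def test_venous_bias_preserves_eye_contrast(self, patch, cmap):
        """The eye-symmetric coarse bias loads equally on both condition
        regressors, so the left-minus-right GLM contrast (z map) is unchanged
        by adding it (identical noise realization)."""
        from lamodc import glm_contrast

        design = RunDesign()
        with_bias = simulate_run(patch, cmap, design,
                                 AcquisitionModel.ge_bold(venous_bias_amp=0.02),
                                 seed=0)
        without = simulate_run(patch, cmap, design,
                               AcquisitionModel.ge_bold(venous_bias_amp=0.0),
                               seed=0)
        z_with = glm_contrast(with_bias, design).z
        z_without = glm_contrast(without, design).z
        assert np.allclose(z_with, z_without, atol=1e-8)

    def test_seed_determinism(self, patch, cmap):
        model = AcquisitionModel.ge_bold()
        a = simulate_run(patch, cmap, RunDesign(), model, seed=9)
        b = simulate_run(patch, cmap, RunDesign(), model, seed=9)
        assert np.array_equal(a.values, b.values)


class TestVasoPair:
    def test_pair_volume_counts(self, patch, cmap):
        design = RunDesign(tr_s=5.0)
        nulled, nn = simulate_vaso_pair(patch, cmap, design, AcquisitionModel.vaso(),
                                        seed=0)
        assert nulled.n_volumes == 54
        assert nn.n_volumes == 54
        assert np.allclose(nn.timestamps_s - nulled.timestamps_s, 2.5)

    def test_zero_cbv_makes_pair_identical(self, patch, cmap):
        design = RunDesign(tr_s=5.0)
        model = AcquisitionModel.vaso(amplitude_base=0.0, venous_bias_amp=0.0,
                                      noise_sigma_deep=0.0, noise_sigma_pial=0.0)
        nulled, nn = simulate_vaso_pair(patch, cmap, design, model, seed=0,
                                        aligned_timestamps=True)
        assert np.allclose(nulled.values, nn.values)

    def test_noiseless_ratio_is_one_minus_cbv(self, patch, cmap):
        design = RunDesign(tr_s=5.0)
        model = AcquisitionModel.vaso(noise_sigma_deep=0.0, noise_sigma_pial=0.0)
        nulled, nn, truth = simulate_vaso_pair(patch, cmap, design, model, seed=0,
                                               aligned_timestamps=True,
                                               bold_amp=0.05, return_truth=True)
        ratio = nulled.values / nn.values
        assert np.allclose(ratio, 1.0 - truth["cbv_nulled_times"], atol=1e-12)

    def test_rejects_non_vaso_model(self, patch, cmap):
        with pytest.raises(ValueError):
            simulate_vaso_pair(patch, cmap, RunDesign(tr_s=5.0),
                               AcquisitionModel.ge_bold(), seed=0)


class TestRunDesign:
    def test_timing_invariant_enforced(self):
        with pytest.raises(ValueError):
            RunDesign(run_duration_s=200.0)

    def test_pseudorandom_is_balanced_and_deterministic(self):
        a = RunDesign.pseudorandom(3)
        b = RunDesign.pseudorandom(3)
        assert a.conditions == b.conditions
        assert a.conditions.count("LEFT") == 4

    def test_tr_must_divide_duration(self):
        with pytest.raises(ValueError):
            RunDesign(tr_s=7.0)
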