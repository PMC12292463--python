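"""Phantom generator: anatomy, enhancement dynamics and the noise model."""

import numpy as np
import pytest

from lungperf.phantom import (NoiseSpec, PhantomSpec, apply_noise, fbm_surface,
                              generate_phantom, generate_vessel_tree)
from scipy import ndimage


def small_spec(**kw):
    defaults = dict(grid_shape=(8, 32, 32), n_timepoints=4,
                    enhancement_curve=(0.0, 0.5, 1.0, 0.5), vessel_levels=2)
    defaults.update(kw)
    return PhantomSpec(**defaults)


class TestSpecValidation:
    def test_rejects_multiple_curve_maxima(self):
        with pytest.raises(ValueError, match="maximum"):
            small_spec(enhancement_curve=(0.0, 1.0, 1.0, 0.5))

    def test_rejects_small_grid(self):
        with pytest.raises(ValueError):
            small_spec(grid_shape=(8, 8, 8))

    def test_rejects_negative_levels(self):
        with pytest.raises(ValueError):
            small_spec(parenchyma_level=-1.0)

    def test_noise_spec_requires_positive_gain(self):
        with pytest.raises(ValueError, match="gain"):
            NoiseSpec(gain_coeffs=(1.0, -2.0))


class TestVesselTree:
    def test_single_level_gives_one_trunk_per_lung(self):
        spec = small_spec(vessel_levels=1)
        vessels = generate_vessel_tree(spec, seed=3)
        assert vessels.any()
        _, n_components = ndimage.label(vessels)
        assert n_components == 2  # one connected trunk in each lung

    def test_deterministic_given_seed(self):
        spec = small_spec()
        a = generate_vessel_tree(spec, seed=7)
        b = generate_vessel_tree(spec, seed=7)
        assert np.array_equal(a, b)
        c = generate_vessel_tree(spec, seed=8)
        assert not np.array_equal(a, c)

    def test_level_voxel_counts_decrease(self):
        spec = PhantomSpec(grid_shape=(32, 64, 64), n_timepoints=4,
                           enhancement_curve=(0.0, 0.5, 1.0, 0.5), vessel_levels=4)
        _, _, counts = generate_vessel_tree(spec, seed=0, return_levels=True)
        levels = sorted(counts)
        assert levels == [1, 2, 3, 4]
        tallies = [counts[k] for k in levels]
        assert all(a > b for a, b in zip(tallies, tallies[1:]))

    def test_warns_on_subvoxel_radii(self):
        spec = small_spec(vessel_levels=12)
        with pytest.warns(UserWarning, match="sub-voxel"):
            generate_vessel_tree(spec, seed=0)


class TestGeneratePhantom:
    def test_zero_enhancement_curve_is_static(self):
        spec = small_spec(enhancement_curve=(0.0, 0.0, 0.0, 0.0))
        bundle = generate_phantom(spec, seed=0)
        data = bundle.clean_series.data
        for t in range(1, data.shape[0]):
            assert np.array_equal(data[t], data[0])

    def test_peak_frame_has_largest_lung_mean(self):
        spec = small_spec()
        bundle = generate_phantom(spec, seed=0)
        means = [frame[bundle.lung_mask].mean() for frame in bundle.clean_series.data]
        assert int(np.argmax(means)) == 2

    def test_full_deficit_lesion_never_enhances(self):
        # psf_fwhm=0: the acquisition PSF would smear neighbouring
        # enhancement into the lesion rim, which is partial-volume truth,
        # not a generator defect; the perfusion model itself must be silent
        spec = small_spec(lesion=((4, 16, 10), 4.0, 1.0), psf_fwhm=0.0)
        bundle = generate_phantom(spec, seed=0)
        zz, yy, xx = np.mgrid[0:8, 0:32, 0:32]
        lesion = (zz - 4) ** 2 + (yy - 16) ** 2 + (xx - 10) ** 2 <= 16
        data = bundle.clean_series.data
        for t in range(data.shape[0]):
            assert np.array_equal(data[t][lesion], data[0][lesion])

    def test_clean_series_non_negative(self):
        bundle = generate_phantom(small_spec(), seed=1)
        assert bundle.clean_series.data.min() >= 0


class TestApplyNoise:
    def test_bit_identical_reproducibility(self):
        bundle = generate_phantom(small_spec(), seed=0)
        spec = NoiseSpec(seed=9)
        a = apply_noise(bundle.clean_series, spec)
        b = apply_noise(bundle.clean_series, spec)
        assert np.array_equal(a.data, b.data)

    def test_near_zero_sigma_limit(self):
        bundle = generate_phantom(small_spec(), seed=0)
        noisy = apply_noise(bundle.clean_series, NoiseSpec(base_sigma=1e-9, seed=0))
        assert np.allclose(noisy.data, bundle.clean_series.data, atol=1e-6)

    def test_noise_is_zero_mean(self):
        bundle = generate_phantom(small_spec(), seed=0)
        noisy = apply_noise(bundle.clean_series, NoiseSpec(seed=1))
        resid = noisy.data - bundle.clean_series.data
        # spatially correlated noise: effective n ~ 32k/9, so the sample
        # mean has std ~ sigma*gain/sqrt(n_eff) ~ 0.08; allow 4 sigma
        assert abs(resid.mean()) < 0.32

    def test_sigma_calibration_in_uniform_gain_region(self):
        spec = PhantomSpec(grid_shape=(8, 64, 64), n_timepoints=4,
                           enhancement_curve=(0.0, 0.5, 1.0, 0.5))
        bundle = generate_phantom(spec, seed=0)
        noise = NoiseSpec(base_sigma=4.0, correlation_fwhm=3.0,
                          gain_coeffs=(1.0, 0.0), seed=2)  # uniform gain
        noisy = apply_noise(bundle.clean_series, noise)
        resid = (noisy.data - bundle.clean_series.data).ravel()
        assert resid.size >= 10_000
        assert abs(resid.std() / 4.0 - 1.0) < 0.05

    def test_white_noise_has_no_lag1_correlation(self):
        spec = PhantomSpec(grid_shape=(8, 64, 64), n_timepoints=4,
                           enhancement_curve=(0.0, 0.5, 1.0, 0.5))
        bundle = generate_phantom(spec, seed=0)
        noisy = apply_noise(bundle.clean_series,
                            NoiseSpec(correlation_fwhm=0.0, gain_coeffs=(1.0, 0.0), seed=3))
        resid = noisy.data - bundle.clean_series.data
        rho1 = np.corrcoef(resid[..., :-1].ravel(), resid[..., 1:].ravel())[0, 1]
        assert abs(rho1) < 0.05

    def test_correlated_noise_autocorrelation_profile(self):
        # Gaussian kernel with FWHM f: autocorrelation exp(-d^2 / (4 sigma^2)),
        # sigma = f / 2.355 -> lag-1 ~ 0.92 for f = 4, lag-10 ~ 0
        spec = PhantomSpec(grid_shape=(8, 64, 64), n_timepoints=4,
                           enhancement_curve=(0.0, 0.5, 1.0, 0.5))
        bundle = generate_phantom(spec, seed=0)
        noisy = apply_noise(bundle.clean_series,
                            NoiseSpec(correlation_fwhm=4.0, gain_coeffs=(1.0, 0.0), seed=4))
        resid = noisy.data - bundle.clean_series.data
        rho1 = np.corrcoef(resid[..., :-1].ravel(), resid[..., 1:].ravel())[0, 1]
        rho10 = np.corrcoef(resid[..., :-10].ravel(), resid[..., 10:].ravel())[0, 1]
        assert rho1 > 0.4
        assert abs(rho10) < 0.05


class TestFbmSurface:
    def test_deterministic_and_normalised(self):
        a = fbm_surface((64, 64), 0.5, seed=3)
        b = fbm_surface((64, 64), 0.5, seed=3)
        assert np.array_equal(a, b)
        assert abs(a.mean()) < 1e-9
        assert abs(a.std() - 1.0) < 1e-9

    @pytest.mark.parametrize("hurst", [0.2, 0.5, 0.8])
    def test_increment_scaling_matches_hurst(self, hurst):
        """Variogram exponent over lags 1-32 should recover H (fBm oracle)."""
        exps = []
        for seed in range(3):
            z = fbm_surface((128, 128), hurst, seed=seed)
            lags = np.array([1, 2, 4, 8, 16, 32])
            sf = [np.mean((z[:, d:] - z[:, :-d]) ** 2) for d in lags]
            exps.append(np.polyfit(np.log(lags), np.log(sf), 1)[0] / 2)
        assert abs(np.mean(exps) - hurst) < 0.12
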