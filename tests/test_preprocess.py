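"""MNF denoising, spectral angle mapper and RGB rendering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from hsilesion.hsi_io import SpectralCube
from hsilesion.phantom import PhantomConfig, generate_spectral_phantom
from hsilesion.hsi_io import normalize_reflectance
from hsilesion.preprocess import (
    fit_mnf,
    mnf_denoise,
    render_rgb,
    sam_angle,
    segment_skin,
)


def _cube(values, wl=None, kind="reflectance"):
    values = np.asarray(values, dtype=float)
    if wl is None:
        wl = 450.0 + 10.0 * np.arange(values.shape[2])
    return SpectralCube(values=values, wavelengths_nm=wl, kind=kind)


class TestMNF:
    def _rank_cube(self, rank, shape=(24, 24, 8), noise=0.0, seed=0):
        # spatially smooth abundance maps: the neighbor-difference noise
        # estimator must see noise, not signal gradients
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(seed)
        spatial = np.stack([
            gaussian_filter(rng.standard_normal(shape[:2]), sigma=4.0)
            for _ in range(rank)
        ], axis=-1).reshape(-1, rank)
        spectra = rng.random((rank, shape[2])) + 0.5
        clean = (spatial @ spectra).reshape(shape) + 1.0
        noisy = clean + noise * rng.standard_normal(shape)
        return clean, noisy

    def test_rank1_noiseless_cube_passes_through(self):
        clean, _ = self._rank_cube(rank=1)
        out = mnf_denoise(_cube(clean), n_components=1)
        np.testing.assert_allclose(out.values, clean, rtol=1e-6)

    def test_keeping_all_components_is_identity(self, rng):
        values = rng.random((10, 10, 6))
        out = mnf_denoise(_cube(values), n_components=6)
        np.testing.assert_allclose(out.values, values, rtol=1e-8, atol=1e-10)

    def test_truncation_reduces_error_to_clean_signal(self):
        # Monte-Carlo oracle: known rank-3 signal + white noise
        wins = 0
        for seed in range(20):
            clean, noisy = self._rank_cube(rank=3, noise=0.05, seed=seed)
            denoised = mnf_denoise(_cube(noisy), n_components=3)
            mse_before = np.mean((noisy - clean) ** 2)
            mse_after = np.mean((denoised.values - clean) ** 2)
            wins += mse_after < mse_before
        assert wins == 20

    def test_eigenvalues_sorted_and_transforms_inverse(self, rng):
        values = rng.random((12, 12, 5))
        model = fit_mnf(_cube(values))
        assert np.all(np.diff(model.eigenvalues) <= 1e-9)
        np.testing.assert_allclose(model.forward @ model.backward,
                                   np.eye(5), atol=1e-8)

    def test_auto_selection_keeps_signal_components(self):
        _, noisy = self._rank_cube(rank=3, noise=0.02, seed=1)
        out = mnf_denoise(_cube(noisy), n_components="auto")
        assert 1 <= out.metadata["mnf_components"] <= 8

    def test_rescaling_consistency(self, rng):
        # band-wise gain followed by the inverse gain leaves output unchanged
        values = rng.random((16, 16, 4)) + 0.2
        gain = np.array([1.0, 2.5, 0.5, 4.0])
        base = mnf_denoise(_cube(values), n_components=2).values
        scaled = mnf_denoise(_cube(values * gain), n_components=2).values / gain
        np.testing.assert_allclose(scaled, base, rtol=1e-6, atol=1e-9)

    def test_singular_noise_covariance_warns_and_recovers(self):
        values = np.ones((8, 8, 3))  # zero noise differences
        with pytest.warns(UserWarning, match="singular"):
            out = mnf_denoise(_cube(values), n_components=1)
        assert np.isfinite(out.values).all()


class TestSAM:
    def test_identical_spectra_have_zero_angle(self):
        v = np.array([0.3, 0.5, 0.2])
        assert sam_angle(v, v) == pytest.approx(0.0, abs=1e-6)

    def test_orthogonal_spectra_have_right_angle(self):
        assert sam_angle([1.0, 0.0], [0.0, 2.0]) == pytest.approx(np.pi / 2)

    def test_known_45_degree_case(self):
        assert sam_angle([1.0, 0.0], [1.0, 1.0]) == pytest.approx(np.pi / 4)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            sam_angle([0.0, 0.0], [1.0, 1.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        a=arrays(np.float64, 5, elements=st.floats(0.01, 10.0)),
        b=arrays(np.float64, 5, elements=st.floats(0.01, 10.0)),
        gain=st.floats(0.01, 100.0),
    )
    def test_symmetry_and_scale_invariance(self, a, b, gain):
        assert sam_angle(a, b) == pytest.approx(sam_angle(b, a), abs=1e-9)
        assert sam_angle(a * gain, b) == pytest.approx(sam_angle(a, b),
                                                       abs=1e-7)
        assert 0.0 <= sam_angle(a, b) <= np.pi


class TestSegmentation:
    def test_uniform_cube_fully_matches_reference(self):
        values = np.tile([0.2, 0.5, 0.4], (8, 8, 1))
        mask = segment_skin(_cube(values), (0, 0), angle_threshold=0.01)
        assert mask.all()

    def test_two_material_phantom_split_at_half_separation(self):
        a = np.array([1.0, 0.0, 0.0])
        b = np.array([np.cos(0.3), np.sin(0.3), 0.0])  # 0.3 rad apart
        values = np.empty((4, 6, 3))
        values[:, :3] = a
        values[:, 3:] = b
        mask = segment_skin(_cube(values), a, angle_threshold=0.15)
        assert mask[:, :3].all() and not mask[:, 3:].any()

    def test_pi_threshold_keeps_everything(self, rng):
        values = rng.random((5, 5, 4)) + 0.1
        mask = segment_skin(_cube(values), (2, 2), angle_threshold=np.pi)
        assert mask.all()

    def test_empty_result_suggests_larger_threshold(self):
        values = np.tile([1.0, 0.0], (4, 4, 1))
        with pytest.raises(ValueError, match="threshold"):
            segment_skin(_cube(values), np.array([0.0, 1.0]),
                         angle_threshold=0.05)

    def test_phantom_skin_recovered_at_default_threshold(self):
        for seed in (0, 1, 2):
            config = PhantomConfig(image_size=96, seed=seed)
            cube, refs, masks = generate_spectral_phantom(config)
            refl = normalize_reflectance(cube, refs)
            anchor = tuple(np.argwhere(masks.healthy)[0])
            mask = segment_skin(refl, anchor)
            recovered = (mask & masks.skin).sum() / masks.skin.sum()
            assert recovered >= 0.99
            assert not (mask & ~masks.skin).any()


class TestRGB:
    def _flat_cube(self, level):
        wl = np.arange(400.0, 701.0, 10.0)
        values = np.full((2, 2, wl.size), level)
        return SpectralCube(values=values, wavelengths_nm=wl,
                            kind="reflectance")

    def test_perfect_reflector_renders_white(self):
        rgb = render_rgb(self._flat_cube(1.0))
        np.testing.assert_allclose(rgb, 1.0, atol=0.02)

    def test_black_renders_black(self):
        rgb = render_rgb(self._flat_cube(0.0))
        np.testing.assert_allclose(rgb, 0.0, atol=1e-9)

    def test_narrowband_450nm_is_blue_dominant(self):
        wl = np.arange(400.0, 701.0, 10.0)
        values = np.zeros((1, 1, wl.size))
        values[0, 0, np.argmin(np.abs(wl - 450.0))] = 1.0
        rgb = render_rgb(SpectralCube(values=values, wavelengths_nm=wl,
                                      kind="reflectance"))[0, 0]
        assert rgb[2] == rgb.max() and rgb[2] > 0

    def test_output_clipped_to_unit_interval(self, rng):
        wl = np.arange(400.0, 701.0, 10.0)
        values = rng.random((4, 4, wl.size)) * 1.5
        rgb = render_rgb(SpectralCube(values=values, wavelengths_nm=wl,
                                      kind="reflectance"))
        assert rgb.min() >= 0.0 and rgb.max() <= 1.0

    def test_nir_only_cube_rejected(self):
        wl = np.arange(800.0, 1000.0, 10.0)
        values = np.ones((2, 2, wl.size))
        with pytest.raises(ValueError, match="400-700"):
            render_rgb(SpectralCube(values=values, wavelengths_nm=wl,
                                    kind="reflectance"))
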