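"""Phantom geometry, index-field calibration and study-replica structure."""

import numpy as np
import pytest

from hsilesion.chromophores import mu_a_deoxy_hb, mu_a_melanin, mu_a_oxy_hb, \
    mu_a_water
from hsilesion.hsi_io import normalize_reflectance
from hsilesion.phantom import (
    CLASS_LABELS,
    ConfigurationError,
    PhantomConfig,
    REGIONS,
    generate_index_phantom,
    generate_spectral_phantom,
    generate_study_replica,
    make_region_masks,
)


def effective_se(sd: float, n: int, corr_length: float) -> float:
    """Standard error of a region mean of the correlated phantom field.

    The Gaussian-filtered field has integral correlation area ~4*pi*l^2,
    shrinking the effective sample size accordingly.
    """
    corr_area = max(4.0 * np.pi * corr_length**2, 1.0)
    return sd * np.sqrt(corr_area / n)


class TestRegionMasks:
    @pytest.mark.parametrize("size", [512, 128])
    def test_default_geometry_hits_published_pixel_ratios(self, size):
        masks = make_region_masks(PhantomConfig(image_size=size))
        c = masks.counts()
        assert c["healthy"] / c["tumor"] == pytest.approx(40.0, abs=4.0)
        assert c["healthy"] / c["peritumor"] == pytest.approx(11.0, abs=1.1)

    def test_masks_are_pairwise_disjoint_and_shaped(self):
        masks = make_region_masks(PhantomConfig(image_size=128))
        assert not (masks.tumor & masks.peritumor).any()
        assert not (masks.tumor & masks.healthy).any()
        assert not (masks.peritumor & masks.healthy).any()
        # tumor disc sits inside the peritumor disc inside the square
        assert masks.skin.sum() == sum(masks.counts().values())

    def test_zero_tumor_radius_gives_empty_tumor_full_annulus(self):
        config = PhantomConfig(image_size=128, tumor_radius=0.0,
                               peritumor_outer_radius=20.0,
                               healthy_frame_side=100.0)
        masks = make_region_masks(config)
        assert masks.tumor.sum() == 0
        assert masks.peritumor.sum() > 0

    def test_oversized_geometry_rejected(self):
        with pytest.raises(ConfigurationError, match="fit"):
            PhantomConfig(image_size=64, tumor_radius=20.0,
                          peritumor_outer_radius=40.0,
                          healthy_frame_side=100.0)

    def test_inverted_radii_rejected(self):
        with pytest.raises(ConfigurationError, match="smaller"):
            PhantomConfig(image_size=128, tumor_radius=30.0,
                          peritumor_outer_radius=20.0)

    def test_nonincreasing_wavelengths_rejected(self):
        with pytest.raises(ConfigurationError, match="increasing"):
            PhantomConfig(image_size=128,
                          wavelengths_nm=[500.0, 500.0, 510.0])


class TestIndexPhantom:
    def test_region_means_recovered_at_large_pixel_counts(self):
        # >=10^4 tumor pixels; tolerance three (correlation-aware) SEs
        config = PhantomConfig(image_size=512, tumor_radius=60.0,
                               peritumor_outer_radius=90.0,
                               healthy_frame_side=400.0, seed=5)
        stack, masks = generate_index_phantom(config)
        assert masks.tumor.sum() >= 10_000
        for symbol in ("E_Daw", "oxy_I", "M_Daw"):
            for region in REGIONS:
                mean, sd = config.region_index_params[symbol][region]
                n = masks.region(region).sum()
                se = effective_se(sd, n, config.texture_params[region])
                observed = np.nanmean(stack[symbol][masks.region(region)])
                assert observed == pytest.approx(mean, abs=3 * se), \
                    (symbol, region)

    def test_zero_variance_fields_are_piecewise_constant(self):
        config = PhantomConfig(image_size=128, seed=2)
        for params in config.region_index_params.values():
            for region in REGIONS:
                params[region] = (params[region][0], 0.0)
        stack, masks = generate_index_phantom(config)
        for region in REGIONS:
            vals = stack["E_Daw"][masks.region(region)]
            assert np.unique(vals).size == 1

    def test_background_pixels_are_missing(self):
        stack, masks = generate_index_phantom(PhantomConfig(image_size=128,
                                                            seed=3))
        assert np.isnan(stack["E_Daw"][~masks.skin]).all()
        assert np.isfinite(stack["E_Daw"][masks.skin]).all()

    def test_same_seed_reproduces_identical_arrays(self):
        a, _ = generate_index_phantom(PhantomConfig(image_size=128, seed=9))
        b, _ = generate_index_phantom(PhantomConfig(image_size=128, seed=9))
        for symbol in a.symbols:
            np.testing.assert_array_equal(a[symbol], b[symbol])

    def test_negative_sd_rejected(self):
        config_kwargs = dict(image_size=128)
        config = PhantomConfig(**config_kwargs)
        config.region_index_params["E_Daw"]["tumor"] = (98.97, -1.0)
        with pytest.raises(ConfigurationError, match="sd"):
            PhantomConfig(image_size=128,
                          region_index_params=config.region_index_params)


class TestSpectralPhantom:
    def test_normalization_inverts_forward_model_without_noise(self):
        config = PhantomConfig(image_size=64, noise_sd=0.0, seed=4)
        cube, refs, masks = generate_spectral_phantom(config)
        refl = normalize_reflectance(cube, refs)
        from hsilesion.phantom import true_reflectance
        rng = np.random.default_rng(config.seed)
        expected = true_reflectance(config, masks, rng)
        np.testing.assert_allclose(refl.values, expected, rtol=1e-9)

    def test_reflectance_stays_below_one_on_skin(self):
        config = PhantomConfig(image_size=64, seed=6)
        cube, refs, masks = generate_spectral_phantom(config)
        refl = normalize_reflectance(cube, refs).values[masks.skin]
        assert np.mean((refl > 0) & (refl < 1)) >= 0.95

    def test_more_blood_absorbs_more_in_green_band(self):
        # forward-model oracle on one spectrum: reflectance at 540-580 nm
        # strictly decreases with blood volume
        lam = np.arange(400.0, 1000.0, 7.0)
        band = (lam >= 540) & (lam <= 580)
        mu_blood = 0.7 * mu_a_oxy_hb(lam) + 0.3 * mu_a_deoxy_hb(lam)
        baseline = 0.03 * mu_a_melanin(lam) + 0.65 * mu_a_water(lam)
        previous = None
        for blood in (0.005, 0.01, 0.02, 0.04):
            refl = 0.9 * np.exp(-2.4 * (blood * mu_blood + baseline))
            value = refl[band].mean()
            if previous is not None:
                assert value < previous
            previous = value

    def test_tumor_has_higher_erythema_and_oxygenation_than_healthy(self):
        # large tumor + low chromophore texture so region means dominate
        # over the correlated-field sampling noise
        config = PhantomConfig(image_size=160, tumor_radius=30.0,
                               peritumor_outer_radius=45.0,
                               healthy_frame_side=150.0,
                               chromophore_rel_sd=0.05, seed=8)
        cube, refs, masks = generate_spectral_phantom(config)
        from hsilesion.indices import compute_index
        refl = normalize_reflectance(cube, refs)
        for symbol in ("E_Daw", "oxy_I", "oxy_H", "M_Daw"):
            img = compute_index(refl, symbol, skin_mask=masks.skin)
            t = np.nanmean(img[masks.tumor])
            p = np.nanmean(img[masks.peritumor])
            h = np.nanmean(img[masks.healthy])
            assert t > p > h, symbol


class TestStudyReplica:
    def test_default_replica_has_72_balanced_rois(self):
        replica = generate_study_replica(n_lesions=24, seed=1,
                                         config=PhantomConfig(image_size=64))
        assert len(replica.roi_records) == 72
        assert replica.class_counts() == {"I": 24, "II": 24, "III": 24}

    def test_two_lesions_give_six_records(self):
        replica = generate_study_replica(n_lesions=2, seed=1,
                                         config=PhantomConfig(image_size=64))
        assert len(replica.roi_records) == 6

    def test_replica_is_reproducible_under_seed(self):
        cfg = PhantomConfig(image_size=64)
        a = generate_study_replica(n_lesions=3, seed=5, config=cfg)
        b = generate_study_replica(n_lesions=3, seed=5, config=cfg)
        for la, lb in zip(a.lesions, b.lesions):
            np.testing.assert_array_equal(la.stack["E_Daw"],
                                          lb.stack["E_Daw"])

    def test_single_lesion_rejected(self):
        with pytest.raises(ConfigurationError, match="n_lesions"):
            generate_study_replica(n_lesions=1)

    def test_class_labels_follow_region_convention(self):
        assert CLASS_LABELS == {"tumor": "I", "peritumor": "II",
                                "healthy": "III"}
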