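"""Synthetic skin-lesion phantoms with the study's geometry and statistics.

The patient cohort behind this pipeline is not public, so phantoms provide
inputs with the structure the analysis assumes: a round tumor, an annular
peritumor, and a square healthy-skin frame with a central void, sized so
that healthy:tumor pixel counts are ~40:1 and healthy:peritumor ~11:1.

Two phantom flavors exist:

* index-space phantoms draw each of the 12 tissue-index images directly as
  spatially correlated Gaussian fields with per-region (mean, sd) calibrated
  to the published region statistics (Dawson erythema 98.97 +/- 21.43 tumor,
  70.58 +/- 13.32 peritumor, 67.87 +/- 20.70 healthy; Ishimaru oxygenation
  70.16/68.41/65.34; Dawson melanin 5.92 tumor / 4.46 healthy);
* spectral phantoms synthesize a raw camera cube through a Beer-Lambert
  forward model R = R0 * exp(-sum_i c_i mu_a,i l) plus white/dark reference
  frames, so the full normalize -> denoise -> index chain can be exercised.

Healthy skin gets a longer spatial-correlation length than tumor tissue,
emulating the greater texture non-uniformity of healthy skin.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chromophores import mu_a_deoxy_hb, mu_a_melanin, mu_a_oxy_hb, mu_a_water
from .hsi_io import ReferenceFrames, SpectralCube
from .indices import INDEX_SYMBOLS, TissueIndexStack

__all__ = [
    "REGIONS",
    "CLASS_LABELS",
    "PhantomConfig",
    "RegionMaskSet",
    "StudyReplica",
    "ConfigurationError",
    "make_region_masks",
    "generate_index_phantom",
    "generate_spectral_phantom",
    "generate_study_replica",
]

REGIONS = ("tumor", "peritumor", "healthy")
#: class labels: I = tumor, II = peritumor, III = healthy skin
CLASS_LABELS = {"tumor": "I", "peritumor": "II", "healthy": "III"}

# geometry solved from the target pixel ratios healthy:tumor = 40 and
# healthy:peritumor = 11:  r_p/r_t = sqrt(1 + 40/11), side/r_t = sqrt(491*pi/11)
_PERI_RADIUS_FACTOR = float(np.sqrt(51.0 / 11.0))
_SIDE_FACTOR = float(np.sqrt(491.0 * np.pi / 11.0))

# per-region (mean, sd) defaults for every index image; entries marked
# assumed=True have no published region statistics and are package choices.
REGION_INDEX_DEFAULTS: dict[str, dict] = {
    "E_Daw": {"tumor": (98.97, 21.43), "peritumor": (70.58, 13.32),
              "healthy": (67.87, 20.70), "assumed": False},
    "oxy_I": {"tumor": (70.16, 2.12), "peritumor": (68.41, 2.24),
              "healthy": (65.34, 4.02), "assumed": False},
    "M_Daw": {"tumor": (5.92, 0.94), "peritumor": (5.20, 0.92),
              "healthy": (4.46, 0.91), "assumed": False},
    "oxy_H": {"tumor": (55.0, 4.0), "peritumor": (51.0, 4.0),
              "healthy": (47.0, 6.0), "assumed": True},
    "E_c_Daw": {"tumor": (90.0, 20.0), "peritumor": (63.0, 13.0),
                "healthy": (61.0, 19.0), "assumed": True},
    "E_Diff": {"tumor": (30.0, 6.0), "peritumor": (23.0, 5.0),
               "healthy": (21.0, 6.0), "assumed": True},
    "E_Wag": {"tumor": (40.0, 8.0), "peritumor": (31.0, 6.0),
              "healthy": (29.0, 8.0), "assumed": True},
    "M_Wag": {"tumor": (12.0, 2.0), "peritumor": (10.5, 2.0),
              "healthy": (9.0, 2.0), "assumed": True},
    "oxy_T": {"tumor": (60.0, 5.0), "peritumor": (55.0, 5.0),
              "healthy": (50.0, 7.0), "assumed": True},
    "TWI": {"tumor": (55.0, 8.0), "peritumor": (50.0, 7.0),
            "healthy": (45.0, 9.0), "assumed": True},
    "THI": {"tumor": (25.0, 6.0), "peritumor": (19.0, 4.0),
            "healthy": (17.0, 5.0), "assumed": True},
    "NTP": {"tumor": (30.0, 5.0), "peritumor": (26.0, 4.0),
            "healthy": (24.0, 6.0), "assumed": True},
    # grayscale luminance stand-in for the RGB photograph channel
    "RGB": {"tumor": (0.45, 0.08), "peritumor": (0.55, 0.08),
            "healthy": (0.62, 0.10), "assumed": True},
}

#: spatial-correlation length (pixels); healthy skin is the most non-uniform
TEXTURE_DEFAULTS = {"tumor": 3.0, "peritumor": 5.0, "healthy": 8.0}

#: per-region chromophore fractions for the spectral forward model
CHROMOPHORE_DEFAULTS = {
    "tumor": {"blood": 0.025, "oxygen_saturation": 0.75,
              "melanin": 0.040, "water": 0.75},
    "peritumor": {"blood": 0.017, "oxygen_saturation": 0.68,
                  "melanin": 0.035, "water": 0.70},
    "healthy": {"blood": 0.012, "oxygen_saturation": 0.62,
                "melanin": 0.030, "water": 0.65},
}


class ConfigurationError(ValueError):
    """Raised for phantom geometry/parameter configurations that cannot work."""


@dataclass
class PhantomConfig:
    """Parameters of one phantom lesion.

    Geometry defaults emulate the 512x512 camera frame; pass
    ``image_size=128`` (the test default) for a proportionally scaled-down
    phantom with the same region pixel ratios.
    """

    image_size: tuple[int, int] = (512, 512)
    wavelengths_nm: np.ndarray = field(
        default_factory=lambda: np.arange(400.0, 1000.0 + 1e-9, 7.0)
    )
    tumor_radius: float | None = None
    peritumor_outer_radius: float | None = None
    healthy_frame_side: float | None = None
    region_index_params: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 REGION_INDEX_DEFAULTS.items()}
    )
    texture_params: dict = field(default_factory=lambda: dict(TEXTURE_DEFAULTS))
    chromophore_params: dict = field(
        default_factory=lambda: {r: dict(v) for r, v in
                                 CHROMOPHORE_DEFAULTS.items()}
    )
    base_reflectance: float = 0.9
    path_length: float = 2.4  # effective optical path (arb. units)
    chromophore_rel_sd: float = 0.15
    background_reflectance: float = 0.15
    noise_sd: float = 0.002  # reflectance units
    seed: int = 0

    def __post_init__(self) -> None:
        if np.isscalar(self.image_size):
            self.image_size = (int(self.image_size), int(self.image_size))
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ConfigurationError("wavelength grid must be strictly increasing")
        if (self.wavelengths_nm[0] < 400 - 1e-9
                or self.wavelengths_nm[-1] > 1000 + 1e-9):
            raise ConfigurationError("wavelength grid must lie within 400-1000 nm")
        # geometry defaults scale with the frame so the 40:1 / 11:1 pixel
        # ratios hold at any image size
        scale = min(self.image_size) / 512.0
        if self.tumor_radius is None:
            self.tumor_radius = 40.0 * scale
        if self.peritumor_outer_radius is None:
            self.peritumor_outer_radius = self.tumor_radius * _PERI_RADIUS_FACTOR
        if self.healthy_frame_side is None:
            self.healthy_frame_side = self.tumor_radius * _SIDE_FACTOR
        if self.tumor_radius < 0:
            raise ConfigurationError("tumor_radius must be >= 0")
        if self.tumor_radius >= self.peritumor_outer_radius:
            raise ConfigurationError(
                "tumor_radius must be smaller than peritumor_outer_radius"
            )
        if (self.healthy_frame_side > min(self.image_size)
                or 2 * self.peritumor_outer_radius > min(self.image_size)):
            raise ConfigurationError("region geometry does not fit in image_size")
        for symbol, params in self.region_index_params.items():
            for region in REGIONS:
                mean, sd = params[region]
                if sd < 0:
                    raise ConfigurationError(
                        f"negative sd for {symbol}/{region}"
                    )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")

    @property
    def n_bands(self) -> int:
        return self.wavelengths_nm.size

    def to_manifest(self) -> dict:
        """JSON-serializable record of true parameters and assumptions."""
        return {
            "image_size": list(self.image_size),
            "n_bands": self.n_bands,
            "tumor_radius": self.tumor_radius,
            "peritumor_outer_radius": self.peritumor_outer_radius,
            "healthy_frame_side": self.healthy_frame_side,
            "region_index_params": {
                sym: {
                    **{r: list(p[r]) for r in REGIONS},
                    "assumed": bool(p.get("assumed", True)),
                }
                for sym, p in self.region_index_params.items()
            },
            "texture_params": dict(self.texture_params),
            "chromophore_params": {r: dict(v) for r, v in
                                   self.chromophore_params.items()},
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }


@dataclass
class RegionMaskSet:
    """Disjoint tumor/peritumor/healthy masks plus the overall skin mask."""

    tumor: np.ndarray
    peritumor: np.ndarray
    healthy: np.ndarray

    def __post_init__(self) -> None:
        if (self.tumor & self.peritumor).any() or \
           (self.tumor & self.healthy).any() or \
           (self.peritumor & self.healthy).any():
            raise ValueError("region masks must be pairwise disjoint")

    @property
    def skin(self) -> np.ndarray:
        return self.tumor | self.peritumor | self.healthy

    def region(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def counts(self) -> dict[str, int]:
        return {r: int(self.region(r).sum()) for r in REGIONS}

    def label_image(self) -> np.ndarray:
        """0 = background, 1 = tumor, 2 = peritumor, 3 = healthy."""
        labels = np.zeros(self.tumor.shape, dtype=np.uint8)
        labels[self.tumor] = 1
        labels[self.peritumor] = 2
        labels[self.healthy] = 3
        return labels


def make_region_masks(config: PhantomConfig) -> RegionMaskSet:
    """Build the study's region geometry.

    Tumor: filled disc.  Peritumor: annulus around it.  Healthy skin: a
    centered square frame with the peritumor disc as the central void.
    """
    rows, cols = config.image_size
    rr, cc = np.mgrid[0:rows, 0:cols]
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    dist2 = (rr - cy) ** 2 + (cc - cx) ** 2
    tumor = dist2 <= config.tumor_radius**2
    disc = dist2 <= config.peritumor_outer_radius**2
    peritumor = disc & ~tumor
    half = config.healthy_frame_side / 2.0
    square = (np.abs(rr - cy) <= half) & (np.abs(cc - cx) <= half)
    healthy = square & ~disc
    return RegionMaskSet(tumor=tumor, peritumor=peritumor, healthy=healthy)


def _correlated_field(
    shape: tuple[int, int], corr_length: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean unit-variance Gaussian random field.

    White noise is low-pass filtered in the Fourier domain with a Gaussian
    transfer function of the given correlation length; ``corr_length`` <= 0.5
    falls back to plain white noise.
    """
    noise = rng.standard_normal(shape)
    if corr_length <= 0.5:
        return noise
    ky = np.fft.fftfreq(shape[0])[:, None]
    kx = np.fft.fftfreq(shape[1])[None, :]
    transfer = np.exp(-2.0 * (np.pi * corr_length) ** 2 * (ky**2 + kx**2))
    f = np.fft.ifft2(np.fft.fft2(noise) * transfer).real
    sd = f.std()
    if sd == 0:
        return np.zeros(shape)
    return (f - f.mean()) / sd


def generate_index_phantom(
    config: PhantomConfig,
    region_mean_offsets: dict | None = None,
) -> tuple[TissueIndexStack, RegionMaskSet]:
    """Draw the 12 index images (plus the RGB luminance channel) directly.

    Pixels inside region r follow a spatially correlated field with the
    configured mean/sd; non-skin pixels are NaN.  ``region_mean_offsets``
    optionally shifts per-(symbol, region) means (used for between-lesion
    variability in study replicas).
    """
    masks = make_region_masks(config)
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.image_size)
    channels = list(INDEX_SYMBOLS) + ["RGB"]
    images: dict[str, np.ndarray] = {}
    for symbol in channels:
        params = config.region_index_params[symbol]
        image = np.full(shape, np.nan)
        for region in REGIONS:
            mean, sd = params[region]
            if region_mean_offsets is not None:
                mean = mean + region_mean_offsets.get((symbol, region), 0.0)
            mask = masks.region(region)
            if not mask.any():
                continue
            fld = _correlated_field(shape, config.texture_params[region], rng)
            image[mask] = mean + sd * fld[mask]
        images[symbol] = image
    luminance = images.pop("RGB")
    rgb = np.clip(np.repeat(luminance[:, :, None], 3, axis=2), 0.0, 1.0)
    provenance = {
        sym: {"formula": "phantom", "seed": config.seed} for sym in images
    }
    stack = TissueIndexStack(
        indices=images, skin_mask=masks.skin, rgb=rgb, provenance=provenance
    )
    return stack, masks


def _region_chromophore_fields(
    config: PhantomConfig, masks: RegionMaskSet, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Per-pixel chromophore fraction maps with mild spatial texture."""
    shape = tuple(config.image_size)
    fields = {}
    for chrom in ("blood", "oxygen_saturation", "melanin", "water"):
        img = np.zeros(shape)
        for region in REGIONS:
            mean = config.chromophore_params[region][chrom]
            mask = masks.region(region)
            fld = _correlated_field(shape, config.texture_params[region], rng)
            img[mask] = mean * (1.0 + config.chromophore_rel_sd * fld[mask])
        fields[chrom] = np.clip(img, 0.0, 1.0)
    return fields


def true_reflectance(config: PhantomConfig, masks: RegionMaskSet,
                     rng: np.random.Generator) -> np.ndarray:
    """Beer-Lambert forward model R = R0 exp(-sum_i c_i mu_a,i(lambda) l)."""
    lam = config.wavelengths_nm
    fields = _region_chromophore_fields(config, masks, rng)
    blood = fields["blood"][:, :, None]
    sao2 = fields["oxygen_saturation"][:, :, None]
    mel = fields["melanin"][:, :, None]
    water = fields["water"][:, :, None]
    mu = (
        blood * (sao2 * mu_a_oxy_hb(lam) + (1 - sao2) * mu_a_deoxy_hb(lam))
        + mel * mu_a_melanin(lam)
        + water * mu_a_water(lam)
    )
    refl = config.base_reflectance * np.exp(-config.path_length * mu)
    out_of_range = np.mean((refl <= 0) | (refl >= 1))
    if out_of_range > 0.01:
        warnings.warn(
            f"{out_of_range:.1%} of modeled reflectances outside (0,1) "
            "before clipping", stacklevel=2,
        )
    refl = np.clip(refl, 1e-6, 1.0 - 1e-6)
    refl = np.where(masks.skin[:, :, None], refl,
                    config.background_reflectance)
    return refl


def generate_spectral_phantom(
    config: PhantomConfig,
) -> tuple[SpectralCube, ReferenceFrames, RegionMaskSet]:
    """Synthesize a raw camera cube plus white/dark reference frames.

    The raw cube is constructed as dark + R*(white - dark) + noise, so
    reflectance normalization recovers the true modeled reflectance up to
    the configured noise.
    """
    rng = np.random.default_rng(config.seed)
    masks = make_region_masks(config)
    refl = true_reflectance(config, masks, rng)
    rows, cols = config.image_size
    lam = config.wavelengths_nm
    # halogen-like illumination rising toward the NIR, in camera counts
    illum = 3000.0 * (0.4 + 0.6 * (lam - lam[0]) / (lam[-1] - lam[0]))
    dark = np.full((rows, cols, lam.size), 96.0)
    white = dark + illum[None, None, :]
    raw = dark + refl * (white - dark)
    if config.noise_sd > 0:
        raw = raw + config.noise_sd * (white - dark) * \
            rng.standard_normal(raw.shape)
    cube = SpectralCube(values=raw, wavelengths_nm=lam, kind="raw",
                        metadata={"phantom_seed": config.seed})
    refs = ReferenceFrames(white=white, dark=dark)
    return cube, refs, masks


@dataclass
class LesionRecord:
    lesion_id: str
    stack: TissueIndexStack
    masks: RegionMaskSet
    cube: SpectralCube | None = None
    refs: ReferenceFrames | None = None


@dataclass
class StudyReplica:
    """A synthetic stand-in for the study cohort: n lesions x 3 ROIs."""

    lesions: list[LesionRecord]
    roi_records: list[dict]  # {"lesion_id", "region", "class_label"}
    seed: int

    def __post_init__(self) -> None:
        if len(self.roi_records) != 3 * len(self.lesions):
            raise ValueError("expected 3 ROI records per lesion")
        counts = self.class_counts()
        if len(set(counts.values())) > 1:
            raise ValueError(f"unbalanced classes: {counts}")

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.roi_records:
            counts[rec["class_label"]] = counts.get(rec["class_label"], 0) + 1
        return counts


def generate_study_replica(
    n_lesions: int = 24,
    mode: str = "index",
    seed: int = 0,
    config: PhantomConfig | None = None,
    between_lesion_sd_frac: float = 0.25,
) -> StudyReplica:
    """Generate a balanced cohort of phantom lesions.

    Each lesion's per-region index means are jittered with sd equal to
    ``between_lesion_sd_frac`` times that index's between-region contrast,
    emulating patient-to-patient variability around the pooled statistics.
    """
    if n_lesions < 2:
        raise ConfigurationError("n_lesions must be >= 2")
    if mode not in ("index", "spectral"):
        raise ConfigurationError(f"unknown replica mode {mode!r}")
    if config is None:
        config = PhantomConfig(image_size=(128, 128), seed=seed)
    master_rng = np.random.default_rng(seed)
    lesions: list[LesionRecord] = []
    roi_records: list[dict] = []
    base_params = config.region_index_params
    for i in range(n_lesions):
        lesion_seed = int(master_rng.integers(0, 2**31 - 1))
        lesion_cfg = PhantomConfig(
            image_size=config.image_size,
            wavelengths_nm=config.wavelengths_nm,
            tumor_radius=config.tumor_radius,
            peritumor_outer_radius=config.peritumor_outer_radius,
            healthy_frame_side=config.healthy_frame_side,
            region_index_params={k: dict(v) for k, v in base_params.items()},
            texture_params=dict(config.texture_params),
            chromophore_params={r: dict(v) for r, v in
                                config.chromophore_params.items()},
            noise_sd=config.noise_sd,
            seed=lesion_seed,
        )
        offsets = {}
        for symbol, params in base_params.items():
            means = [params[r][0] for r in REGIONS]
            contrast = max(means) - min(means)
            for region in REGIONS:
                offsets[(symbol, region)] = float(
                    master_rng.normal(0.0, between_lesion_sd_frac * contrast)
                )
        lesion_id = f"lesion{i:03d}"
        if mode == "index":
            stack, masks = generate_index_phantom(lesion_cfg, offsets)
            record = LesionRecord(lesion_id, stack, masks)
        else:
            cube, refs, masks = generate_spectral_phantom(lesion_cfg)
            record = LesionRecord(lesion_id, stack=None, masks=masks,
                                  cube=cube, refs=refs)
        lesions.append(record)
        for region in REGIONS:
            roi_records.append({
                "lesion_id": lesion_id,
                "region": region,
                "class_label": CLASS_LABELS[region],
            })
    return StudyReplica(lesions=lesions, roi_records=roi_records, seed=seed)


def write_manifest(config: PhantomConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config.to_manifest(), indent=2))
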