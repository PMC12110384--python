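"""Reflectance-cube preprocessing: MNF denoising, SAM segmentation, RGB.

The minimum noise fraction (MNF) transform whitens the noise using a
covariance estimated from neighboring-pixel differences, runs PCA in the
whitened space, truncates low-SNR components, and back-projects.  The
spectral angle mapper (SAM) measures per-pixel similarity to a reference
spectrum as the angle between spectra, which is invariant to illumination
scaling.  RGB rendering integrates reflectance against the CIE 1931
observer under D65 and converts to gamma-encoded sRGB.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.measure import label as cc_label

from .cie import XYZ_TO_SRGB, cmf_xyz, d65_spd
from .hsi_io import SpectralCube

__all__ = [
    "MNFModel",
    "fit_mnf",
    "mnf_denoise",
    "sam_angle",
    "sam_angle_map",
    "segment_skin",
    "render_rgb",
]


# ---------------------------------------------------------------------------
# Minimum noise fraction
# ---------------------------------------------------------------------------


@dataclass
class MNFModel:
    """Fitted MNF transform.

    ``forward`` maps centered band space to MNF component space (components
    ordered by descending noise-whitened variance); ``backward`` is its
    inverse.  ``eigenvalues`` are the noise-whitened variances.
    """

    mean: np.ndarray
    forward: np.ndarray  # (bands, bands): components = (x - mean) @ forward
    backward: np.ndarray
    eigenvalues: np.ndarray
    noise_covariance: np.ndarray

    @property
    def n_bands(self) -> int:
        return self.mean.size


def _noise_covariance(values: np.ndarray, valid: np.ndarray,
                      direction: str) -> np.ndarray:
    """Half the covariance of first differences between neighboring pixels."""
    diffs = []
    if direction in ("horizontal", "both"):
        d = values[:, 1:, :] - values[:, :-1, :]
        m = valid[:, 1:] & valid[:, :-1]
        diffs.append(d[m])
    if direction in ("vertical", "both"):
        d = values[1:, :, :] - values[:-1, :, :]
        m = valid[1:, :] & valid[:-1, :]
        diffs.append(d[m])
    diff = np.concatenate(diffs, axis=0)
    if diff.shape[0] < 2:
        raise ValueError("not enough neighboring pixel pairs for noise estimate")
    return np.cov(diff, rowvar=False) / 2.0


def fit_mnf(cube: SpectralCube, direction: str = "horizontal") -> MNFModel:
    """Estimate the MNF transform from a cube.

    Singular noise covariances are ridge-regularized with
    eps = 1e-8 * trace / bands (with a warning).
    """
    values = cube.values
    bands = values.shape[2]
    if bands < 2:
        raise ValueError("MNF requires at least 2 bands")
    valid = np.all(np.isfinite(values), axis=2)
    pixels = values[valid]
    if pixels.shape[0] < bands + 1:
        raise ValueError("MNF requires at least bands+1 valid pixels")
    sigma_n = _noise_covariance(values, valid, direction)
    # ridge-regularize if (near-)singular
    eigmin = np.linalg.eigvalsh(sigma_n)[0]
    if eigmin <= 1e-12 * max(np.trace(sigma_n), 1e-300):
        eps = 1e-8 * np.trace(sigma_n) / bands
        if eps <= 0:
            eps = 1e-12
        warnings.warn("singular noise covariance; ridge-regularizing",
                      stacklevel=2)
        sigma_n = sigma_n + eps * np.eye(bands)
    # noise whitening: sigma_n = V L V^T  ->  W = V L^{-1/2}
    lam, vec = np.linalg.eigh(sigma_n)
    lam = np.maximum(lam, 1e-30)
    whiten = vec @ np.diag(lam**-0.5)
    unwhiten = np.diag(lam**0.5) @ vec.T
    mean = pixels.mean(axis=0)
    centered = pixels - mean
    whitened = centered @ whiten
    cov_w = np.cov(whitened, rowvar=False)
    evals, evecs = np.linalg.eigh(cov_w)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    forward = whiten @ evecs
    backward = evecs.T @ unwhiten
    return MNFModel(mean=mean, forward=forward, backward=backward,
                    eigenvalues=evals, noise_covariance=sigma_n)


def mnf_denoise(
    cube: SpectralCube,
    n_components: int | str = "auto",
    direction: str = "horizontal",
) -> SpectralCube:
    """Denoise a cube by truncating low-SNR MNF components.

    ``n_components="auto"`` keeps components whose noise-whitened variance
    exceeds 1 (i.e. variance above the noise floor); an integer keeps that
    many leading components.  The output has identical shape; non-finite
    pixels pass through unchanged.
    """
    model = fit_mnf(cube, direction=direction)
    bands = model.n_bands
    if n_components == "auto":
        n_keep = max(int(np.sum(model.eigenvalues > 1.0)), 1)
    else:
        n_keep = int(n_components)
        if not 1 <= n_keep <= bands:
            raise ValueError(f"n_components must be in [1, {bands}]")
    values = cube.values
    valid = np.all(np.isfinite(values), axis=2)
    flat = values[valid] - model.mean
    comps = flat @ model.forward
    comps[:, n_keep:] = 0.0
    restored = comps @ model.backward + model.mean
    out = values.astype(float).copy()
    out[valid] = restored
    meta = dict(cube.metadata)
    meta["mnf_components"] = n_keep
    return SpectralCube(values=out, wavelengths_nm=cube.wavelengths_nm,
                        kind=cube.kind, metadata=meta)


# ---------------------------------------------------------------------------
# Spectral angle mapper
# ---------------------------------------------------------------------------


def sam_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Angle between two spectra in radians, in [0, pi]; scale-invariant."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("spectra must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("SAM is undefined for a zero spectrum")
    cosang = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.arccos(cosang))


def sam_angle_map(cube: SpectralCube, reference: np.ndarray) -> np.ndarray:
    """Per-pixel spectral angle to ``reference`` (NaN for invalid pixels)."""
    ref = np.asarray(reference, dtype=float).ravel()
    if ref.size != cube.n_bands:
        raise ValueError("reference length must equal cube bands")
    nref = np.linalg.norm(ref)
    if nref == 0:
        raise ValueError("SAM is undefined for a zero reference spectrum")
    values = cube.values
    norms = np.linalg.norm(values, axis=2)
    dots = values @ ref
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.clip(dots / (norms * nref), -1.0, 1.0)
    angles = np.arccos(cosang)
    angles[norms == 0] = np.nan
    return angles


def segment_skin(
    cube: SpectralCube,
    reference: tuple[int, int] | np.ndarray,
    angle_threshold: float = 0.25,
    largest_component_only: bool = False,
) -> np.ndarray:
    """SAM-based skin/background segmentation.

    ``reference`` is either a (row, col) pixel coordinate whose spectrum is
    used as the skin reference, or an explicit reference spectrum.  The mask
    keeps pixels within ``angle_threshold`` radians of the reference.
    """
    if isinstance(reference, tuple) and len(reference) == 2 and \
            np.isscalar(reference[0]):
        row, col = reference
        ref = cube.values[int(row), int(col), :]
    else:
        ref = np.asarray(reference, dtype=float)
    angles = sam_angle_map(cube, ref)
    with np.errstate(invalid="ignore"):
        mask = angles <= angle_threshold
    if not mask.any():
        raise ValueError(
            f"no pixels within {angle_threshold} rad of the reference; "
            "increase the angle threshold"
        )
    if largest_component_only:
        labels = cc_label(mask, connectivity=2)
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        mask = labels == sizes.argmax()
    return mask


# ---------------------------------------------------------------------------
# RGB rendering
# ---------------------------------------------------------------------------


def render_rgb(cube: SpectralCube) -> np.ndarray:
    """Render a reflectance cube to gamma-encoded sRGB in [0, 1].

    XYZ = sum_lambda R * S_D65 * cmf * dlambda, normalized so a perfect
    reflector has Y = 1, then XYZ -> linear sRGB (D65) -> gamma encoding.
    """
    wl = cube.wavelengths_nm
    visible = (wl >= 400.0) & (wl <= 700.0)
    if visible.sum() < 3:
        raise ValueError("cube has no usable bands in the 400-700 nm range")
    lam = wl[visible]
    cmf = cmf_xyz(lam)  # (n, 3)
    spd = d65_spd(lam)
    # trapezoidal quadrature weights on the (possibly non-uniform) grid
    dl = np.gradient(lam)
    weights = cmf * (spd * dl)[:, None]  # (n, 3)
    norm = weights[:, 1].sum()  # Y of the perfect reflector
    refl = np.nan_to_num(cube.values[:, :, visible], nan=0.0)
    xyz = (refl @ weights) / norm
    linear = xyz @ XYZ_TO_SRGB.T
    linear = np.clip(linear, 0.0, None)
    srgb = np.where(
        linear <= 0.0031308,
        12.92 * linear,
        1.055 * np.power(linear, 1 / 2.4) - 0.055,
    )
    return np.clip(srgb, 0.0, 1.0)
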