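"""CIE 1931 2-degree colorimetry: color-matching functions and D65.

The color-matching functions use the published multi-lobe piecewise-Gaussian
analytic fit (accurate to ~1% of peak), evaluated on any wavelength grid.
The D65 illuminant is a coarse 10-nm relative-power table, linearly
interpolated.  Rendering normalizes to the white point (Y of a perfect
reflector = 1), so residual table error cancels for near-neutral scenes.
"""

from __future__ import annotations

import numpy as np

__all__ = ["cmf_xyz", "d65_spd", "XYZ_TO_SRGB"]


def _lobe(lam: np.ndarray, peak: float, s_left: float, s_right: float,
          height: float) -> np.ndarray:
    sigma = np.where(lam < peak, s_left, s_right)
    return height * np.exp(-0.5 * ((lam - peak) / sigma) ** 2)


def cmf_xyz(lam_nm) -> np.ndarray:
    """CIE 1931 2-deg x̄, ȳ, z̄ as an (n, 3) array."""
    lam = np.asarray(lam_nm, dtype=float)
    x = (_lobe(lam, 599.8, 37.9, 31.0, 1.056)
         + _lobe(lam, 442.0, 16.0, 26.7, 0.362)
         - _lobe(lam, 501.1, 20.4, 26.2, 0.065))
    y = (_lobe(lam, 568.8, 46.9, 40.5, 0.821)
         + _lobe(lam, 530.9, 16.3, 31.1, 0.286))
    z = (_lobe(lam, 437.0, 11.8, 36.0, 1.217)
         + _lobe(lam, 459.0, 26.0, 13.8, 0.681))
    return np.stack([x, y, z], axis=-1)


# CIE D65 relative spectral power, 400..700 nm at 10 nm (100 at 560 nm)
_D65_WL = np.arange(400.0, 701.0, 10.0)
_D65_POWER = np.array([
    82.8, 91.5, 93.4, 86.7, 104.9, 117.0, 117.8, 114.9, 115.9, 112.4,
    108.8, 109.1, 107.8, 104.8, 107.7, 104.4, 104.0, 100.0, 96.3, 95.8,
    88.7, 90.0, 89.6, 87.7, 83.3, 83.7, 80.0, 80.2, 82.3, 78.3, 71.6,
])


def d65_spd(lam_nm) -> np.ndarray:
    """D65 relative power, linearly interpolated (0 outside 400-700 nm)."""
    lam = np.asarray(lam_nm, dtype=float)
    return np.interp(lam, _D65_WL, _D65_POWER, left=0.0, right=0.0)


# linear sRGB (D65) from CIE XYZ, IEC 61966-2-1
XYZ_TO_SRGB = np.array([
    [3.2406, -1.5372, -0.4986],
    [-0.9689, 1.8758, 0.0415],
    [0.0557, -0.2040, 1.0570],
])
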