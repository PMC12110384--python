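"""Coarse skin-chromophore absorption shapes for the spectral phantom.

These are smooth analytic approximations to the published absorption
spectra of oxy-/deoxy-hemoglobin, eumelanin and water over 400-1000 nm.
They reproduce the qualitative features the phantom forward model needs —
the hemoglobin Soret and Q bands, the oxy/deoxy double-peak vs single-peak
structure in the 540-580 nm window, the 760 nm deoxy-Hb shoulder, the
oxy > deoxy ordering above the ~800 nm isosbestic point, the melanin
power-law decay and the 970 nm water band — not radiometric accuracy.
Units are arbitrary absorption per unit path; the phantom scales them.
"""

from __future__ import annotations

import numpy as np

__all__ = ["mu_a_oxy_hb", "mu_a_deoxy_hb", "mu_a_melanin", "mu_a_water"]


def _gauss(lam: np.ndarray, center: float, width: float, height: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((lam - center) / width) ** 2)


def mu_a_oxy_hb(lam_nm) -> np.ndarray:
    """Oxy-hemoglobin: Soret band at 415 nm, Q bands at 542/577 nm,
    weak NIR tail rising above deoxy-Hb beyond ~800 nm."""
    lam = np.asarray(lam_nm, dtype=float)
    return (
        _gauss(lam, 415.0, 18.0, 100.0)
        + _gauss(lam, 542.0, 12.0, 12.0)
        + _gauss(lam, 577.0, 10.0, 12.0)
        + _gauss(lam, 925.0, 90.0, 1.4)
        + 0.25
    )


def mu_a_deoxy_hb(lam_nm) -> np.ndarray:
    """Deoxy-hemoglobin: Soret band at 430 nm, single Q band at 556 nm,
    characteristic 760 nm shoulder, falling NIR tail."""
    lam = np.asarray(lam_nm, dtype=float)
    return (
        _gauss(lam, 430.0, 20.0, 110.0)
        + _gauss(lam, 556.0, 16.0, 14.0)
        + _gauss(lam, 760.0, 22.0, 1.6)
        + 0.9 * np.exp(-(lam - 600.0) / 250.0).clip(max=3.0)
        + 0.2
    )


def mu_a_melanin(lam_nm) -> np.ndarray:
    """Eumelanin: monotone power-law decay ~ (lambda/500)^-3.46."""
    lam = np.asarray(lam_nm, dtype=float)
    return 6.0 * (lam / 500.0) ** (-3.46)


def mu_a_water(lam_nm) -> np.ndarray:
    """Water: near-transparent in the visible, 970 nm absorption band."""
    lam = np.asarray(lam_nm, dtype=float)
    return (
        _gauss(lam, 970.0, 35.0, 1.2)
        + _gauss(lam, 740.0, 30.0, 0.05)
        + 0.01
    )
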