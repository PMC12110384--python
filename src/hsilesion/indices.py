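"""Tissue-index images computed from a reflectance cube.

A tissue index is a scalar image estimating a physiological property
(blood content, melanin, oxygenation at two depths, water, perfusion) from
reflectance at a handful of wavelengths.  All formulas use the absorbance
convention A(lambda) = -log10 R(lambda), with R at each required wavelength
taken as the mean over a band window (default +/-3.5 nm, one camera band).

The registry implements the twelve classical indices used for skin-lesion
characterization:

=========  ================================  =============================
symbol     name                              estimates
=========  ================================  =============================
E_Daw      Dawson's erythema index           tissue blood content
E_c_Daw    corrected Dawson's erythema idx   blood content, melanin-corrected
E_Diff     Diffey's erythema index           tissue blood content
M_Daw      Dawson's melanin index            melanin content
oxy_H      Huang's oxygenation index         superficial oxygenation
oxy_I      Ishimaru's oxygenation index      deeper (NIR) oxygenation
E_Wag      Wagner's erythema index           tissue blood content
M_Wag      Wagner's melanin index            melanin content
oxy_T      tissue oxygenation index          oxygenation
TWI        tissue water index                water concentration
THI        total hemoglobin index            hemoglobin
NTP        NIR perfusion index               perfusion
=========  ================================  =============================

Indices built purely from absorbance differences with zero weight sum
(all E/M/TWI/THI/NTP forms) are invariant to a global positive gain on
reflectance; the three oxygenation ratios are not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .hsi_io import SpectralCube

__all__ = [
    "INDEX_SYMBOLS",
    "INDEX_REGISTRY",
    "IndexFormula",
    "TissueIndexStack",
    "compute_index",
    "compute_all_indices",
]


@dataclass(frozen=True)
class IndexFormula:
    symbol: str
    description: str
    wavelengths_nm: tuple[float, ...]
    # maps {wavelength: absorbance image} -> index image
    evaluate: Callable[[dict[float, np.ndarray]], np.ndarray]
    gain_invariant: bool


def _mean(*arrays: np.ndarray) -> np.ndarray:
    return sum(arrays) / len(arrays)


def _build_registry() -> dict[str, IndexFormula]:
    reg: dict[str, IndexFormula] = {}

    def add(symbol, description, wavelengths, fn, gain_invariant):
        reg[symbol] = IndexFormula(symbol, description, tuple(wavelengths), fn,
                                   gain_invariant)

    add(
        "E_Daw", "Dawson's erythema index (blood content)",
        (510, 545, 560, 575, 610),
        lambda A: 100.0 * (A[560] + 1.5 * (A[545] + A[575])
                           - 2.0 * (A[510] + A[610])),
        True,
    )
    add(
        "M_Daw", "Dawson's melanin index (red/NIR absorbance slope)",
        (650, 700),
        lambda A: 100.0 * (A[650] - A[700]),
        True,
    )
    add(
        "E_c_Daw", "melanin-corrected Dawson erythema index",
        (510, 545, 560, 575, 610, 650, 700),
        lambda A: (100.0 * (A[560] + 1.5 * (A[545] + A[575])
                            - 2.0 * (A[510] + A[610]))
                   - 1.5 * 100.0 * (A[650] - A[700])),
        True,
    )
    add(
        "E_Diff", "Diffey's erythema index (green/red log-ratio)",
        (560, 650),
        lambda A: 100.0 * (A[560] - A[650]),
        True,
    )
    add(
        "oxy_H", "Huang's superficial oxygenation index "
                 "(oxy-Hb Q-band doublet vs deoxy-Hb 556 nm peak)",
        (542, 556, 577),
        lambda A: 100.0 * (A[542] + A[577])
        / (A[542] + A[577] + 2.0 * A[556]),
        False,
    )
    add(
        "oxy_I", "Ishimaru's deeper oxygenation index "
                 "(NIR two-band ratio across the ~800 nm isosbestic point)",
        (760, 850),
        lambda A: 100.0 * A[850] / (A[760] + A[850]),
        False,
    )
    add(
        "E_Wag", "Wagner's erythema index (mean green absorbance above red)",
        (545, 555, 565, 575, 650),
        lambda A: 100.0 * (_mean(A[545], A[555], A[565], A[575]) - A[650]),
        True,
    )
    add(
        "M_Wag", "Wagner's melanin index (red/NIR absorbance slope)",
        (660, 780),
        lambda A: 100.0 * (A[660] - A[780]),
        True,
    )
    add(
        "oxy_T", "tissue oxygenation index (visible + NIR oxy bands)",
        (560, 580, 760, 850),
        lambda A: 100.0 * (A[580] + A[850])
        / (A[580] + A[850] + A[560] + A[760]),
        False,
    )
    add(
        "TWI", "tissue water index (970 nm water band above NIR baseline)",
        (860, 970),
        lambda A: 100.0 * (A[970] - A[860]),
        True,
    )
    add(
        "THI", "total hemoglobin index (green absorbance above red baseline)",
        (544, 560, 576, 690),
        lambda A: 100.0 * (_mean(A[544], A[560], A[576]) - A[690]),
        True,
    )
    add(
        "NTP", "NIR perfusion index (800 nm blood absorbance above baseline)",
        (690, 800),
        lambda A: 100.0 * (A[800] - A[690]),
        True,
    )
    return reg


INDEX_REGISTRY = _build_registry()
INDEX_SYMBOLS = tuple(INDEX_REGISTRY)  # 12 symbols, registry order


@dataclass
class TissueIndexStack:
    """The 12 tissue-index images (plus optional RGB) for one lesion.

    All images share the spatial shape; pixels outside ``skin_mask`` are NaN.
    ``provenance`` records, per symbol, the wavelengths and window used.
    """

    indices: dict[str, np.ndarray]
    skin_mask: np.ndarray
    rgb: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {img.shape for img in self.indices.values()}
        if len(shapes) > 1:
            raise ValueError("index images must share a spatial shape")

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(self.indices)

    def __getitem__(self, symbol: str) -> np.ndarray:
        return self.indices[symbol]


def _window_reflectance(
    cube: SpectralCube, wavelength: float, window_nm: float, mode: str
) -> np.ndarray:
    wl = cube.wavelengths_nm
    if wavelength < wl[0] - window_nm or wavelength > wl[-1] + window_nm:
        raise ValueError(
            f"required wavelength {wavelength} nm outside cube range "
            f"[{wl[0]}, {wl[-1]}] nm"
        )
    if mode == "nearest":
        return cube.values[:, :, cube.band_index(wavelength)].astype(float)
    sel = np.abs(wl - wavelength) <= window_nm
    if not sel.any():
        sel[cube.band_index(wavelength)] = True
    return cube.values[:, :, sel].mean(axis=2)


def compute_index(
    cube: SpectralCube,
    index_id: str,
    skin_mask: np.ndarray | None = None,
    window_nm: float = 3.5,
    mode: str = "window",
) -> np.ndarray:
    """Evaluate one tissue index per pixel.

    Pixels with non-positive reflectance at any required wavelength (where
    the absorbance log is undefined) are set to NaN.
    """
    if cube.kind != "reflectance":
        raise ValueError("tissue indices require a reflectance cube")
    if index_id not in INDEX_REGISTRY:
        raise KeyError(f"unknown tissue index {index_id!r}")
    formula = INDEX_REGISTRY[index_id]
    absorbance: dict[float, np.ndarray] = {}
    bad = np.zeros(cube.values.shape[:2], dtype=bool)
    for w in formula.wavelengths_nm:
        refl = _window_reflectance(cube, w, window_nm, mode)
        nonpos = ~(refl > 0)
        bad |= nonpos
        with np.errstate(divide="ignore", invalid="ignore"):
            absorbance[w] = -np.log10(np.where(nonpos, np.nan, refl))
    with np.errstate(invalid="ignore", divide="ignore"):
        image = np.asarray(formula.evaluate(absorbance), dtype=float)
    image[bad] = np.nan
    if skin_mask is not None:
        image = np.where(np.asarray(skin_mask, dtype=bool), image, np.nan)
    return image


def compute_all_indices(
    cube: SpectralCube,
    skin_mask: np.ndarray | None = None,
    window_nm: float = 3.5,
    mode: str = "window",
    rgb: np.ndarray | None = None,
) -> TissueIndexStack:
    """Compute all 12 index images, identically masked, with provenance."""
    if skin_mask is None:
        skin_mask = np.ones(cube.values.shape[:2], dtype=bool)
    skin_mask = np.asarray(skin_mask, dtype=bool)
    images = {}
    provenance = {}
    for symbol in INDEX_SYMBOLS:
        images[symbol] = compute_index(cube, symbol, skin_mask, window_nm, mode)
        formula = INDEX_REGISTRY[symbol]
        provenance[symbol] = {
            "formula": symbol,
            "wavelengths_nm": list(formula.wavelengths_nm),
            "window_nm": window_nm,
            "mode": mode,
            "gain_invariant": formula.gain_invariant,
        }
    return TissueIndexStack(
        indices=images, skin_mask=skin_mask, rgb=rgb, provenance=provenance
    )
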