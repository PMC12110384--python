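"""2D radiomic features: 18 first-order + 75 texture-matrix features.

The extractor follows the reference-standard feature definitions used in
quantitative radiomics (first-order statistics plus the GLCM, GLRLM, GLSZM,
NGTDM and GLDM texture-matrix families; the shape class is excluded), for a
total of exactly 93 features per (image, mask) pair.

Conventions
-----------
* Gray-level discretization: fixed bin count (default 32) over the ROI
  range, level = ceil(Ng*(x-min)/(max-min)) clamped to [1, Ng]; a constant
  ROI maps to a single level 1.
* Texture matrices use distance 1 and the four 2D directions (0/45/90/135
  degrees) where directional; per-direction feature values are averaged.
* GLSZM zones use 8-connectivity; NGTDM uses the 8-neighborhood; GLDM uses
  dependence threshold alpha = 0 (neighbor counted as dependent when its
  level equals the center level), with the center pixel included in the
  dependence size so sizes start at 1.
* Degenerate ROIs (constant, single pixel) produce defined fallbacks, never
  NaN: correlation-type features fall back to 1, NGTDM Coarseness saturates
  at 1e6, everything else falls back to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "DiscretizedROI",
    "FEATURE_NAMES",
    "DIRECTIONS",
    "discretize",
    "first_order_features",
    "glcm_matrix",
    "glrlm_matrix",
    "glszm_matrix",
    "ngtdm_matrix",
    "gldm_matrix",
    "texture_features",
    "extract_features",
    "luminance",
]

_EPS = np.spacing(1.0)

#: distance-1 offsets for the 0, 45, 90 and 135 degree directions
DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

_NEIGHBORS8 = ((0, 1), (0, -1), (1, 0), (-1, 0),
               (1, 1), (1, -1), (-1, 1), (-1, -1))


def luminance(rgb: np.ndarray) -> np.ndarray:
    """Rec. 709 luminance of an (rows, cols, 3) image."""
    rgb = np.asarray(rgb, dtype=float)
    return rgb[..., 0] * 0.2126 + rgb[..., 1] * 0.7152 + rgb[..., 2] * 0.0722


@dataclass
class DiscretizedROI:
    """Integer gray-level image (levels 1..n_bins inside mask, 0 outside)."""

    levels: np.ndarray
    mask: np.ndarray
    values: np.ndarray  # original float values (NaN outside mask)
    n_bins: int

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def discretize(image: np.ndarray, mask: np.ndarray, n_bins: int = 32) -> DiscretizedROI:
    """Fixed-bin-count gray-level discretization of the masked region."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool) & np.isfinite(image)
    if not mask.any():
        raise ValueError("empty mask (no finite pixels)")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    vals = image[mask]
    lo, hi = vals.min(), vals.max()
    levels = np.zeros(image.shape, dtype=np.int32)
    if hi == lo:
        levels[mask] = 1
    else:
        lv = np.ceil(n_bins * (vals - lo) / (hi - lo))
        levels[mask] = np.clip(lv, 1, n_bins).astype(np.int32)
    masked_values = np.where(mask, image, np.nan)
    return DiscretizedROI(levels=levels, mask=mask, values=masked_values,
                          n_bins=n_bins)


# ---------------------------------------------------------------------------
# First-order statistics
# ---------------------------------------------------------------------------


def first_order_features(roi: DiscretizedROI) -> dict[str, float]:
    """The 18 first-order features (intensity distribution statistics)."""
    x = roi.values[roi.mask]
    n = x.size
    mean = x.mean()
    var = x.var()  # population convention
    hist = np.bincount(roi.levels[roi.mask])[1:]
    p = hist[hist > 0] / n
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    mid = x[(x >= p10) & (x <= p90)]
    if var > 0:
        m2 = var
        m3 = np.mean((x - mean) ** 3)
        m4 = np.mean((x - mean) ** 4)
        skewness = m3 / m2**1.5
        kurtosis = m4 / m2**2  # not excess-corrected
    else:
        skewness = 0.0
        kurtosis = 0.0
    return {
        "Energy": float(np.sum(x**2)),
        "TotalEnergy": float(np.sum(x**2)),  # unit pixel area
        "Entropy": float(-np.sum(p * np.log2(p + _EPS))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation": float(
            np.mean(np.abs(mid - mid.mean())) if mid.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": float(skewness),
        "Kurtosis": float(kurtosis),
        "Variance": float(var),
        "Uniformity": float(np.sum(p**2)),
    }


# ---------------------------------------------------------------------------
# Texture matrices
# ---------------------------------------------------------------------------


def _shift_pairs(levels: np.ndarray, mask: np.ndarray, offset: tuple[int, int]):
    """Level pairs (a, b) for all in-mask pixel pairs at ``offset``."""
    dr, dc = offset
    rows, cols = levels.shape
    r0 = slice(max(0, -dr), min(rows, rows - dr))
    c0 = slice(max(0, -dc), min(cols, cols - dc))
    r1 = slice(max(0, dr), min(rows, rows + dr))
    c1 = slice(max(0, dc), min(cols, cols + dc))
    m = mask[r0, c0] & mask[r1, c1]
    return levels[r0, c0][m], levels[r1, c1][m]


def glcm_matrix(roi: DiscretizedROI, offset: tuple[int, int]) -> np.ndarray:
    """Symmetric normalized gray-level co-occurrence matrix (one direction)."""
    nmax = int(roi.levels.max())
    a, b = _shift_pairs(roi.levels, roi.mask, offset)
    mat = np.zeros((nmax, nmax))
    np.add.at(mat, (a - 1, b - 1), 1.0)
    mat = mat + mat.T  # symmetric
    total = mat.sum()
    return mat / total if total > 0 else mat


def _lines(levels: np.ndarray, mask: np.ndarray, offset: tuple[int, int]):
    """1D scan lines (level arrays with 0 = gap) along a direction."""
    lv = np.where(mask, levels, 0)
    dr, dc = offset
    if (dr, dc) == (0, 1):
        return [lv[r, :] for r in range(lv.shape[0])]
    if (dr, dc) == (-1, 0):
        return [lv[:, c] for c in range(lv.shape[1])]
    if (dr, dc) == (-1, 1):  # 45 degrees: anti-diagonals
        flipped = lv[::-1, :]
        return [np.diagonal(flipped, off)
                for off in range(-lv.shape[0] + 1, lv.shape[1])]
    if (dr, dc) == (-1, -1):  # 135 degrees: main diagonals
        return [np.diagonal(lv, off)
                for off in range(-lv.shape[0] + 1, lv.shape[1])]
    raise ValueError(f"unsupported direction {offset}")


def glrlm_matrix(roi: DiscretizedROI, offset: tuple[int, int]) -> np.ndarray:
    """Gray-level run-length matrix P[level-1, runlength-1] (one direction)."""
    nmax = int(roi.levels.max())
    max_len = max(roi.levels.shape)
    mat = np.zeros((nmax, max_len))
    for line in _lines(roi.levels, roi.mask, offset):
        if line.size == 0:
            continue
        # run-length encode; level 0 marks gaps
        change = np.flatnonzero(np.diff(line)) + 1
        starts = np.concatenate(([0], change))
        lengths = np.diff(np.concatenate((starts, [line.size])))
        values = line[starts]
        keep = values > 0
        np.add.at(mat, (values[keep] - 1, lengths[keep] - 1), 1.0)
    return mat


def glszm_matrix(roi: DiscretizedROI) -> np.ndarray:
    """Gray-level size-zone matrix P[level-1, zonesize-1] (8-connectivity)."""
    nmax = int(roi.levels.max())
    structure = np.ones((3, 3), dtype=int)
    entries: list[tuple[int, int]] = []
    max_size = 1
    for level in range(1, nmax + 1):
        binary = roi.levels == level
        if not binary.any():
            continue
        labeled, n_zones = ndimage.label(binary, structure=structure)
        if n_zones == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        for s in sizes:
            entries.append((level, int(s)))
            max_size = max(max_size, int(s))
    mat = np.zeros((nmax, max_size))
    for level, s in entries:
        mat[level - 1, s - 1] += 1.0
    return mat


def ngtdm_matrix(roi: DiscretizedROI) -> tuple[np.ndarray, np.ndarray]:
    """NGTDM vectors: counts n_i and summed differences s_i per level.

    Only pixels with at least one in-mask neighbor contribute.
    """
    nmax = int(roi.levels.max())
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    lv = np.where(roi.mask, roi.levels, 0).astype(float)
    valid = roi.mask.astype(float)
    neighbor_sum = ndimage.convolve(lv, kernel, mode="constant", cval=0.0)
    neighbor_count = ndimage.convolve(valid, kernel, mode="constant", cval=0.0)
    has_neighbors = roi.mask & (neighbor_count > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = neighbor_sum / neighbor_count
    diff = np.abs(roi.levels - avg)
    n_i = np.zeros(nmax)
    s_i = np.zeros(nmax)
    lvq = roi.levels[has_neighbors]
    dq = diff[has_neighbors]
    np.add.at(n_i, lvq - 1, 1.0)
    np.add.at(s_i, lvq - 1, dq)
    return n_i, s_i


def gldm_matrix(roi: DiscretizedROI, alpha: int = 0) -> np.ndarray:
    """Gray-level dependence matrix P[level-1, dependence-1].

    Dependence size = 1 (center) + number of 8-neighbors whose level differs
    from the center by at most ``alpha``.
    """
    nmax = int(roi.levels.max())
    dep = np.zeros(roi.levels.shape, dtype=np.int32)
    for offset in _NEIGHBORS8:
        dr, dc = offset
        rows, cols = roi.levels.shape
        r_center = slice(max(0, -dr), min(rows, rows - dr))
        c_center = slice(max(0, -dc), min(cols, cols - dc))
        r_nb = slice(max(0, dr), min(rows, rows + dr))
        c_nb = slice(max(0, dc), min(cols, cols + dc))
        both = roi.mask[r_center, c_center] & roi.mask[r_nb, c_nb]
        close = np.abs(
            roi.levels[r_center, c_center] - roi.levels[r_nb, c_nb]
        ) <= alpha
        dep[r_center, c_center] += (both & close).astype(np.int32)
    dep_sizes = dep[roi.mask] + 1
    levels = roi.levels[roi.mask]
    mat = np.zeros((nmax, int(dep_sizes.max())))
    np.add.at(mat, (levels - 1, dep_sizes - 1), 1.0)
    return mat


# ---------------------------------------------------------------------------
# Texture features
# ---------------------------------------------------------------------------


def _crop(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Drop empty gray-level rows / size columns; return (P, i values, j values)."""
    rows = mat.sum(axis=1) > 0
    cols = mat.sum(axis=0) > 0
    i = np.flatnonzero(rows) + 1.0
    j = np.flatnonzero(cols) + 1.0
    return mat[np.ix_(rows, cols)], i, j


def _glcm_features(P: np.ndarray) -> dict[str, float]:
    P, iv, jv = _crop(P)
    if P.sum() == 0:  # no valid pixel pairs
        base = {name: 0.0 for name in _GLCM_NAMES}
        base["Correlation"] = 1.0
        base["MCC"] = 1.0
        return base
    ng = iv.size
    I, J = np.meshgrid(iv, jv, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    ux = float(np.sum(iv * px))
    uy = float(np.sum(jv * py))
    sigx = float(np.sqrt(np.sum(px * (iv - ux) ** 2)))
    sigy = float(np.sqrt(np.sum(py * (jv - uy) ** 2)))
    # sum / difference marginals
    ksum = (I + J).astype(int)
    kdiff = np.abs(I - J).astype(int)
    psum = np.zeros(int(ksum.max()) + 1)
    np.add.at(psum, ksum.ravel(), P.ravel())
    pdiff = np.zeros(int(kdiff.max()) + 1)
    np.add.at(pdiff, kdiff.ravel(), P.ravel())
    ks = np.arange(psum.size)
    kd = np.arange(pdiff.size)
    hx = float(-np.sum(px * np.log2(px + _EPS)))
    hy = float(-np.sum(py * np.log2(py + _EPS)))
    hxy = float(-np.sum(P * np.log2(P + _EPS)))
    pxpy = np.outer(px, py)
    hxy1 = float(-np.sum(P * np.log2(pxpy + _EPS)))
    hxy2 = float(-np.sum(pxpy * np.log2(pxpy + _EPS)))
    da = float(np.sum(kd * pdiff))
    if sigx * sigy > 0:
        correlation = (float(np.sum(P * I * J)) - ux * uy) / (sigx * sigy)
    else:
        correlation = 1.0
    hmax = max(hx, hy)
    imc1 = (hxy - hxy1) / hmax if hmax > 0 else 0.0
    imc2 = float(np.sqrt(1 - np.exp(-2.0 * (hxy2 - hxy)))) \
        if hxy2 >= hxy else 0.0
    if ng > 1:
        with np.errstate(invalid="ignore", divide="ignore"):
            q = (P[:, None, :] * P[None, :, :] /
                 (px[:, None, None] * py[None, None, :])).sum(axis=2)
        eig = np.sort(np.linalg.eigvals(q).real)
        mcc = float(np.sqrt(max(eig[-2], 0.0)))
    else:
        mcc = 1.0
    off = I != J
    return {
        "Autocorrelation": float(np.sum(P * I * J)),
        "JointAverage": ux,
        "ClusterProminence": float(np.sum(P * (I + J - ux - uy) ** 4)),
        "ClusterShade": float(np.sum(P * (I + J - ux - uy) ** 3)),
        "ClusterTendency": float(np.sum(P * (I + J - ux - uy) ** 2)),
        "Contrast": float(np.sum(P * (I - J) ** 2)),
        "Correlation": float(correlation),
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-np.sum(pdiff * np.log2(pdiff + _EPS))),
        "DifferenceVariance": float(np.sum(pdiff * (kd - da) ** 2)),
        "Id": float(np.sum(P / (1.0 + np.abs(I - J)))),
        "Idm": float(np.sum(P / (1.0 + (I - J) ** 2))),
        "Idmn": float(np.sum(P / (1.0 + ((I - J) ** 2) / ng**2))),
        "Idn": float(np.sum(P / (1.0 + np.abs(I - J) / ng))),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": float(np.sum(P[off] / (I[off] - J[off]) ** 2)),
        "JointEnergy": float(np.sum(P**2)),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(P.max()),
        "SumAverage": float(np.sum(ks * psum)),
        "SumEntropy": float(-np.sum(psum * np.log2(psum + _EPS))),
        "SumSquares": float(np.sum(P * (I - ux) ** 2)),
    }


def _run_type_features(mat: np.ndarray, n_pixels: int, kind: str) -> dict:
    """Shared GLRLM/GLSZM feature algebra (run length vs zone size)."""
    P, iv, jv = _crop(mat)
    nr = P.sum()
    if nr == 0:
        return {name: 0.0 for name in
                (_GLRLM_NAMES if kind == "run" else _GLSZM_NAMES)}
    I, J = np.meshgrid(iv, jv, indexing="ij")
    p = P / nr
    mu_i = float(np.sum(p * I))
    mu_j = float(np.sum(p * J))
    pg = P.sum(axis=1)
    pl = P.sum(axis=0)
    vals = {
        "gln": float(np.sum(pg**2) / nr),
        "glnn": float(np.sum(pg**2) / nr**2),
        "jn": float(np.sum(pl**2) / nr),
        "jnn": float(np.sum(pl**2) / nr**2),
        "pct": float(nr / n_pixels),
        "glv": float(np.sum(p * (I - mu_i) ** 2)),
        "jv": float(np.sum(p * (J - mu_j) ** 2)),
        "ent": float(-np.sum(p * np.log2(p + _EPS))),
        "sje": float(np.sum(P / J**2) / nr),
        "lje": float(np.sum(P * J**2) / nr),
        "lgl": float(np.sum(P / I**2) / nr),
        "hgl": float(np.sum(P * I**2) / nr),
        "sjlgl": float(np.sum(P / (I**2 * J**2)) / nr),
        "sjhgl": float(np.sum(P * I**2 / J**2) / nr),
        "ljlgl": float(np.sum(P * J**2 / I**2) / nr),
        "ljhgl": float(np.sum(P * I**2 * J**2) / nr),
    }
    if kind == "run":
        return {
            "ShortRunEmphasis": vals["sje"],
            "LongRunEmphasis": vals["lje"],
            "GrayLevelNonUniformity": vals["gln"],
            "GrayLevelNonUniformityNormalized": vals["glnn"],
            "RunLengthNonUniformity": vals["jn"],
            "RunLengthNonUniformityNormalized": vals["jnn"],
            "RunPercentage": vals["pct"],
            "GrayLevelVariance": vals["glv"],
            "RunVariance": vals["jv"],
            "RunEntropy": vals["ent"],
            "LowGrayLevelRunEmphasis": vals["lgl"],
            "HighGrayLevelRunEmphasis": vals["hgl"],
            "ShortRunLowGrayLevelEmphasis": vals["sjlgl"],
            "ShortRunHighGrayLevelEmphasis": vals["sjhgl"],
            "LongRunLowGrayLevelEmphasis": vals["ljlgl"],
            "LongRunHighGrayLevelEmphasis": vals["ljhgl"],
        }
    return {
        "SmallAreaEmphasis": vals["sje"],
        "LargeAreaEmphasis": vals["lje"],
        "GrayLevelNonUniformity": vals["gln"],
        "GrayLevelNonUniformityNormalized": vals["glnn"],
        "SizeZoneNonUniformity": vals["jn"],
        "SizeZoneNonUniformityNormalized": vals["jnn"],
        "ZonePercentage": vals["pct"],
        "GrayLevelVariance": vals["glv"],
        "ZoneVariance": vals["jv"],
        "ZoneEntropy": vals["ent"],
        "LowGrayLevelZoneEmphasis": vals["lgl"],
        "HighGrayLevelZoneEmphasis": vals["hgl"],
        "SmallAreaLowGrayLevelEmphasis": vals["sjlgl"],
        "SmallAreaHighGrayLevelEmphasis": vals["sjhgl"],
        "LargeAreaLowGrayLevelEmphasis": vals["ljlgl"],
        "LargeAreaHighGrayLevelEmphasis": vals["ljhgl"],
    }


def _ngtdm_features(n_i: np.ndarray, s_i: np.ndarray) -> dict[str, float]:
    present = n_i > 0
    nvp = n_i.sum()
    if nvp == 0:
        return {"Coarseness": 1e6, "Contrast": 0.0, "Busyness": 0.0,
                "Complexity": 0.0, "Strength": 0.0}
    iv = np.flatnonzero(present) + 1.0
    p = n_i[present] / nvp
    s = s_i[present]
    ngp = iv.size
    sum_ps = float(np.sum(p * s))
    coarseness = 1.0 / sum_ps if sum_ps > 0 else 1e6
    coarseness = min(coarseness, 1e6)
    I, J = np.meshgrid(iv, iv, indexing="ij")
    Pi, Pj = np.meshgrid(p, p, indexing="ij")
    Si, Sj = np.meshgrid(s, s, indexing="ij")
    if ngp > 1:
        contrast = float(
            np.sum(Pi * Pj * (I - J) ** 2) / (ngp * (ngp - 1))
        ) * float(s.sum() / nvp)
        denom = float(np.sum(np.abs(I * Pi - J * Pj)))
        busyness = sum_ps / denom if denom > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
    complexity = float(
        np.sum(np.abs(I - J) * (Pi * Si + Pj * Sj) / (Pi + Pj)) / nvp
    )
    s_total = float(s.sum())
    strength = (
        float(np.sum((Pi + Pj) * (I - J) ** 2)) / s_total
        if s_total > 0 else 0.0
    )
    return {"Coarseness": coarseness, "Contrast": contrast,
            "Busyness": busyness, "Complexity": complexity,
            "Strength": strength}


def _gldm_features(mat: np.ndarray) -> dict[str, float]:
    P, iv, jv = _crop(mat)
    nz = P.sum()
    if nz == 0:
        return {name: 0.0 for name in _GLDM_NAMES}
    I, J = np.meshgrid(iv, jv, indexing="ij")
    p = P / nz
    mu_i = float(np.sum(p * I))
    mu_j = float(np.sum(p * J))
    pg = P.sum(axis=1)
    pd = P.sum(axis=0)
    return {
        "SmallDependenceEmphasis": float(np.sum(P / J**2) / nz),
        "LargeDependenceEmphasis": float(np.sum(P * J**2) / nz),
        "GrayLevelNonUniformity": float(np.sum(pg**2) / nz),
        "DependenceNonUniformity": float(np.sum(pd**2) / nz),
        "DependenceNonUniformityNormalized": float(np.sum(pd**2) / nz**2),
        "GrayLevelVariance": float(np.sum(p * (I - mu_i) ** 2)),
        "DependenceVariance": float(np.sum(p * (J - mu_j) ** 2)),
        "DependenceEntropy": float(-np.sum(p * np.log2(p + _EPS))),
        "LowGrayLevelEmphasis": float(np.sum(P / I**2) / nz),
        "HighGrayLevelEmphasis": float(np.sum(P * I**2) / nz),
        "SmallDependenceLowGrayLevelEmphasis":
            float(np.sum(P / (I**2 * J**2)) / nz),
        "SmallDependenceHighGrayLevelEmphasis":
            float(np.sum(P * I**2 / J**2) / nz),
        "LargeDependenceLowGrayLevelEmphasis":
            float(np.sum(P * J**2 / I**2) / nz),
        "LargeDependenceHighGrayLevelEmphasis":
            float(np.sum(P * I**2 * J**2) / nz),
    }


def _average_over_directions(per_direction: list[dict]) -> dict[str, float]:
    keys = per_direction[0].keys()
    return {k: float(np.mean([d[k] for d in per_direction])) for k in keys}


def texture_features(roi: DiscretizedROI) -> dict[str, float]:
    """All 75 texture features: 24 GLCM + 16 GLRLM + 16 GLSZM + 5 NGTDM
    + 14 GLDM, with directional families averaged over the 4 directions."""
    out: dict[str, float] = {}
    glcm = _average_over_directions(
        [_glcm_features(glcm_matrix(roi, off)) for off in DIRECTIONS]
    )
    out.update({f"GLCM_{k}": v for k, v in glcm.items()})
    glrlm = _average_over_directions(
        [_run_type_features(glrlm_matrix(roi, off), roi.n_pixels, "run")
         for off in DIRECTIONS]
    )
    out.update({f"GLRLM_{k}": v for k, v in glrlm.items()})
    glszm = _run_type_features(glszm_matrix(roi), roi.n_pixels, "zone")
    out.update({f"GLSZM_{k}": v for k, v in glszm.items()})
    ngtdm = _ngtdm_features(*ngtdm_matrix(roi))
    out.update({f"NGTDM_{k}": v for k, v in ngtdm.items()})
    gldm = _gldm_features(gldm_matrix(roi))
    out.update({f"GLDM_{k}": v for k, v in gldm.items()})
    return out


def extract_features(image: np.ndarray, mask: np.ndarray,
                     n_bins: int = 32) -> dict[str, float]:
    """Full 93-feature radiomic vector for one masked 2D image.

    Returns an ordered mapping ``FIRSTORDER_*`` then texture-family names;
    all values finite.
    """
    roi = discretize(image, mask, n_bins=n_bins)
    features = {f"FIRSTORDER_{k}": v
                for k, v in first_order_features(roi).items()}
    features.update(texture_features(roi))
    assert len(features) == 93, f"expected 93 features, got {len(features)}"
    bad = {k: v for k, v in features.items() if not np.isfinite(v)}
    if bad:
        raise AssertionError(f"non-finite features: {sorted(bad)}")
    return features


_GLCM_NAMES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "Id", "Idm", "Idmn", "Idn",
    "Imc1", "Imc2", "InverseVariance", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)
_GLRLM_NAMES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)
_GLSZM_NAMES = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)
_NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")
_GLDM_NAMES = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"FIRSTORDER_{n}" for n in (
        "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
        "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
        "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
        "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
    )]
    + [f"GLCM_{n}" for n in _GLCM_NAMES]
    + [f"GLRLM_{n}" for n in _GLRLM_NAMES]
    + [f"GLSZM_{n}" for n in _GLSZM_NAMES]
    + [f"NGTDM_{n}" for n in _NGTDM_NAMES]
    + [f"GLDM_{n}" for n in _GLDM_NAMES]
)
assert len(FEATURE_NAMES) == 93
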