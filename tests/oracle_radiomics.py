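"""Independent brute-force radiomics oracle.

A second, deliberately naive implementation of the 93-feature vector using
plain Python loops and dictionaries.  It shares only the feature
*definitions* with the package, not code paths: matrices are accumulated
pixel by pixel, zones by explicit flood fill, features by explicit sums.
Used to cross-check the vectorized extractor.
"""

from __future__ import annotations

import math

import numpy as np

EPS = float(np.spacing(1.0))
OFFSETS = [(0, 1), (-1, 1), (-1, 0), (-1, -1)]
NEIGH8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def oracle_discretize(image, mask, n_bins):
    rows, cols = image.shape
    vals = [image[r, c] for r in range(rows) for c in range(cols)
            if mask[r, c] and math.isfinite(image[r, c])]
    lo, hi = min(vals), max(vals)
    levels = {}
    for r in range(rows):
        for c in range(cols):
            if not (mask[r, c] and math.isfinite(image[r, c])):
                continue
            if hi == lo:
                levels[(r, c)] = 1
            else:
                lv = math.ceil(n_bins * (image[r, c] - lo) / (hi - lo))
                levels[(r, c)] = min(max(lv, 1), n_bins)
    return levels


def oracle_first_order(image, mask, levels):
    x = sorted(image[r, c] for (r, c) in levels)
    xs = np.array([image[r, c] for (r, c) in levels], dtype=float)
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    counts = {}
    for lv in levels.values():
        counts[lv] = counts.get(lv, 0) + 1
    probs = [c / n for c in counts.values()]
    p10, p25, p50, p75, p90 = np.percentile(xs, [10, 25, 50, 75, 90])
    mid = [v for v in x if p10 <= v <= p90]
    mid_mean = sum(mid) / len(mid) if mid else 0.0
    if var > 0:
        m3 = sum((v - mean) ** 3 for v in x) / n
        m4 = sum((v - mean) ** 4 for v in x) / n
        skew = m3 / var**1.5
        kurt = m4 / var**2
    else:
        skew = kurt = 0.0
    return {
        "Energy": sum(v**2 for v in x),
        "TotalEnergy": sum(v**2 for v in x),
        "Entropy": -sum(p * math.log2(p + EPS) for p in probs),
        "Minimum": x[0],
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": x[-1],
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": x[-1] - x[0],
        "MeanAbsoluteDeviation": sum(abs(v - mean) for v in x) / n,
        "RobustMeanAbsoluteDeviation":
            sum(abs(v - mid_mean) for v in mid) / len(mid) if mid else 0.0,
        "RootMeanSquared": math.sqrt(sum(v**2 for v in x) / n),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": sum(p**2 for p in probs),
    }


def _glcm_counts(levels, offset):
    counts = {}
    dr, dc = offset
    for (r, c), a in levels.items():
        nb = (r + dr, c + dc)
        if nb in levels:
            b = levels[nb]
            counts[(a, b)] = counts.get((a, b), 0) + 1
            counts[(b, a)] = counts.get((b, a), 0) + 1  # symmetric
    return counts


def oracle_glcm(levels, offset):
    counts = _glcm_counts(levels, offset)
    total = sum(counts.values())
    names = ["Autocorrelation", "JointAverage", "ClusterProminence",
             "ClusterShade", "ClusterTendency", "Contrast", "Correlation",
             "DifferenceAverage", "DifferenceEntropy", "DifferenceVariance",
             "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2", "InverseVariance",
             "JointEnergy", "JointEntropy", "MCC", "MaximumProbability",
             "SumAverage", "SumEntropy", "SumSquares"]
    if total == 0:
        out = {n: 0.0 for n in names}
        out["Correlation"] = 1.0
        out["MCC"] = 1.0
        return out
    P = {k: v / total for k, v in counts.items()}
    ivals = sorted({i for i, _ in P})
    jvals = sorted({j for _, j in P})
    px = {i: sum(p for (a, _), p in P.items() if a == i) for i in ivals}
    py = {j: sum(p for (_, b), p in P.items() if b == j) for j in jvals}
    ng = len(ivals)
    ux = sum(i * px[i] for i in ivals)
    uy = sum(j * py[j] for j in jvals)
    sigx = math.sqrt(sum(px[i] * (i - ux) ** 2 for i in ivals))
    sigy = math.sqrt(sum(py[j] * (j - uy) ** 2 for j in jvals))
    psum, pdiff = {}, {}
    for (i, j), p in P.items():
        psum[i + j] = psum.get(i + j, 0.0) + p
        pdiff[abs(i - j)] = pdiff.get(abs(i - j), 0.0) + p
    hx = -sum(p * math.log2(p + EPS) for p in px.values())
    hy = -sum(p * math.log2(p + EPS) for p in py.values())
    hxy = -sum(p * math.log2(p + EPS) for p in P.values())
    hxy1 = -sum(p * math.log2(px[i] * py[j] + EPS) for (i, j), p in P.items())
    hxy2 = -sum(px[i] * py[j] * math.log2(px[i] * py[j] + EPS)
                for i in ivals for j in jvals)
    da = sum(k * p for k, p in pdiff.items())
    corr = ((sum(p * i * j for (i, j), p in P.items()) - ux * uy)
            / (sigx * sigy)) if sigx * sigy > 0 else 1.0
    hmax = max(hx, hy)
    imc1 = (hxy - hxy1) / hmax if hmax > 0 else 0.0
    imc2 = math.sqrt(1 - math.exp(-2 * (hxy2 - hxy))) if hxy2 >= hxy else 0.0
    if ng > 1:
        q = np.zeros((ng, ng))
        for a, i in enumerate(ivals):
            for b, j in enumerate(ivals):
                q[a, b] = sum(
                    P.get((i, k), 0.0) * P.get((j, k), 0.0) / (px[i] * py[k])
                    for k in jvals
                )
        eig = sorted(np.linalg.eigvals(q).real)
        mcc = math.sqrt(max(eig[-2], 0.0))
    else:
        mcc = 1.0
    return {
        "Autocorrelation": sum(p * i * j for (i, j), p in P.items()),
        "JointAverage": ux,
        "ClusterProminence":
            sum(p * (i + j - ux - uy) ** 4 for (i, j), p in P.items()),
        "ClusterShade":
            sum(p * (i + j - ux - uy) ** 3 for (i, j), p in P.items()),
        "ClusterTendency":
            sum(p * (i + j - ux - uy) ** 2 for (i, j), p in P.items()),
        "Contrast": sum(p * (i - j) ** 2 for (i, j), p in P.items()),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy":
            -sum(p * math.log2(p + EPS) for p in pdiff.values()),
        "DifferenceVariance":
            sum(p * (k - da) ** 2 for k, p in pdiff.items()),
        "Id": sum(p / (1 + abs(i - j)) for (i, j), p in P.items()),
        "Idm": sum(p / (1 + (i - j) ** 2) for (i, j), p in P.items()),
        "Idmn": sum(p / (1 + (i - j) ** 2 / ng**2) for (i, j), p in P.items()),
        "Idn": sum(p / (1 + abs(i - j) / ng) for (i, j), p in P.items()),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": sum(p / (i - j) ** 2 for (i, j), p in P.items()
                               if i != j),
        "JointEnergy": sum(p**2 for p in P.values()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": max(P.values()),
        "SumAverage": sum(k * p for k, p in psum.items()),
        "SumEntropy": -sum(p * math.log2(p + EPS) for p in psum.values()),
        "SumSquares": sum(p * (i - ux) ** 2 for (i, j), p in P.items()),
    }


def _runs(levels, shape, offset):
    """Run-length counts {(level, length): n} along one direction."""
    dr, dc = offset
    rows, cols = shape
    counts = {}

    def bump(level, length):
        if level is not None and length > 0:
            counts[(level, length)] = counts.get((level, length), 0) + 1

    for r0 in range(rows):
        for c0 in range(cols):
            # scan-line start: stepping backwards leaves the grid
            if 0 <= r0 - dr < rows and 0 <= c0 - dc < cols:
                continue
            r, c = r0, c0
            current, length = None, 0
            while 0 <= r < rows and 0 <= c < cols:
                lv = levels.get((r, c))
                if lv is not None and lv == current:
                    length += 1
                else:
                    bump(current, length)
                    current = lv
                    length = 1 if lv is not None else 0
                r += dr
                c += dc
            bump(current, length)
    return counts


def _run_or_zone_features(counts, n_pixels, kind):
    total = sum(counts.values())
    if kind == "run":
        names = ["ShortRunEmphasis", "LongRunEmphasis",
                 "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
                 "RunLengthNonUniformity", "RunLengthNonUniformityNormalized",
                 "RunPercentage", "GrayLevelVariance", "RunVariance",
                 "RunEntropy", "LowGrayLevelRunEmphasis",
                 "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
                 "ShortRunHighGrayLevelEmphasis",
                 "LongRunLowGrayLevelEmphasis", "LongRunHighGrayLevelEmphasis"]
    else:
        names = ["SmallAreaEmphasis", "LargeAreaEmphasis",
                 "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
                 "SizeZoneNonUniformity", "SizeZoneNonUniformityNormalized",
                 "ZonePercentage", "GrayLevelVariance", "ZoneVariance",
                 "ZoneEntropy", "LowGrayLevelZoneEmphasis",
                 "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
                 "SmallAreaHighGrayLevelEmphasis",
                 "LargeAreaLowGrayLevelEmphasis",
                 "LargeAreaHighGrayLevelEmphasis"]
    if total == 0:
        return {n: 0.0 for n in names}
    p = {k: v / total for k, v in counts.items()}
    mu_i = sum(pp * i for (i, _), pp in p.items())
    mu_j = sum(pp * j for (_, j), pp in p.items())
    by_i, by_j = {}, {}
    for (i, j), v in counts.items():
        by_i[i] = by_i.get(i, 0) + v
        by_j[j] = by_j.get(j, 0) + v
    vals = [
        sum(v / j**2 for (_, j), v in counts.items()) / total,
        sum(v * j**2 for (_, j), v in counts.items()) / total,
        sum(v**2 for v in by_i.values()) / total,
        sum(v**2 for v in by_i.values()) / total**2,
        sum(v**2 for v in by_j.values()) / total,
        sum(v**2 for v in by_j.values()) / total**2,
        total / n_pixels,
        sum(pp * (i - mu_i) ** 2 for (i, _), pp in p.items()),
        sum(pp * (j - mu_j) ** 2 for (_, j), pp in p.items()),
        -sum(pp * math.log2(pp + EPS) for pp in p.values()),
        sum(v / i**2 for (i, _), v in counts.items()) / total,
        sum(v * i**2 for (i, _), v in counts.items()) / total,
        sum(v / (i**2 * j**2) for (i, j), v in counts.items()) / total,
        sum(v * i**2 / j**2 for (i, j), v in counts.items()) / total,
        sum(v * j**2 / i**2 for (i, j), v in counts.items()) / total,
        sum(v * i**2 * j**2 for (i, j), v in counts.items()) / total,
    ]
    # reorder: names list above is (sje, lje, gln, glnn, jn, jnn, pct, glv,
    # jv, ent, lgl, hgl, sjlgl, sjhgl, ljlgl, ljhgl) matching vals order
    return dict(zip(names, [float(v) for v in vals]))


def oracle_glrlm(levels, shape, offset, n_pixels):
    return _run_or_zone_features(_runs(levels, shape, offset), n_pixels, "run")


def oracle_glszm(levels, n_pixels):
    seen = set()
    counts = {}
    for start in levels:
        if start in seen:
            continue
        lv = levels[start]
        stack = [start]
        seen.add(start)
        size = 0
        while stack:
            r, c = stack.pop()
            size += 1
            for dr, dc in NEIGH8:
                nb = (r + dr, c + dc)
                if nb in levels and nb not in seen and levels[nb] == lv:
                    seen.add(nb)
                    stack.append(nb)
        counts[(lv, size)] = counts.get((lv, size), 0) + 1
    return _run_or_zone_features(counts, n_pixels, "zone")


def oracle_ngtdm(levels):
    n_i, s_i = {}, {}
    for (r, c), lv in levels.items():
        nbs = [levels[(r + dr, c + dc)] for dr, dc in NEIGH8
               if (r + dr, c + dc) in levels]
        if not nbs:
            continue
        avg = sum(nbs) / len(nbs)
        n_i[lv] = n_i.get(lv, 0) + 1
        s_i[lv] = s_i.get(lv, 0.0) + abs(lv - avg)
    nvp = sum(n_i.values())
    if nvp == 0:
        return {"Coarseness": 1e6, "Contrast": 0.0, "Busyness": 0.0,
                "Complexity": 0.0, "Strength": 0.0}
    lvls = sorted(n_i)
    p = {i: n_i[i] / nvp for i in lvls}
    ngp = len(lvls)
    sum_ps = sum(p[i] * s_i[i] for i in lvls)
    coars = min(1.0 / sum_ps if sum_ps > 0 else 1e6, 1e6)
    if ngp > 1:
        contrast = (sum(p[i] * p[j] * (i - j) ** 2
                        for i in lvls for j in lvls)
                    / (ngp * (ngp - 1))) * (sum(s_i.values()) / nvp)
        denom = sum(abs(i * p[i] - j * p[j]) for i in lvls for j in lvls)
        busy = sum_ps / denom if denom > 0 else 0.0
    else:
        contrast = busy = 0.0
    compl = sum(abs(i - j) * (p[i] * s_i[i] + p[j] * s_i[j]) / (p[i] + p[j])
                for i in lvls for j in lvls) / nvp
    s_tot = sum(s_i.values())
    strength = (sum((p[i] + p[j]) * (i - j) ** 2
                    for i in lvls for j in lvls) / s_tot) if s_tot > 0 else 0.0
    return {"Coarseness": coars, "Contrast": contrast, "Busyness": busy,
            "Complexity": compl, "Strength": strength}


def oracle_gldm(levels, alpha=0):
    counts = {}
    for (r, c), lv in levels.items():
        dep = 1
        for dr, dc in NEIGH8:
            nb = (r + dr, c + dc)
            if nb in levels and abs(levels[nb] - lv) <= alpha:
                dep += 1
        counts[(lv, dep)] = counts.get((lv, dep), 0) + 1
    total = sum(counts.values())
    p = {k: v / total for k, v in counts.items()}
    mu_i = sum(pp * i for (i, _), pp in p.items())
    mu_j = sum(pp * j for (_, j), pp in p.items())
    by_i, by_j = {}, {}
    for (i, j), v in counts.items():
        by_i[i] = by_i.get(i, 0) + v
        by_j[j] = by_j.get(j, 0) + v
    return {
        "SmallDependenceEmphasis":
            sum(v / j**2 for (_, j), v in counts.items()) / total,
        "LargeDependenceEmphasis":
            sum(v * j**2 for (_, j), v in counts.items()) / total,
        "GrayLevelNonUniformity": sum(v**2 for v in by_i.values()) / total,
        "DependenceNonUniformity": sum(v**2 for v in by_j.values()) / total,
        "DependenceNonUniformityNormalized":
            sum(v**2 for v in by_j.values()) / total**2,
        "GrayLevelVariance":
            sum(pp * (i - mu_i) ** 2 for (i, _), pp in p.items()),
        "DependenceVariance":
            sum(pp * (j - mu_j) ** 2 for (_, j), pp in p.items()),
        "DependenceEntropy":
            -sum(pp * math.log2(pp + EPS) for pp in p.values()),
        "LowGrayLevelEmphasis":
            sum(v / i**2 for (i, _), v in counts.items()) / total,
        "HighGrayLevelEmphasis":
            sum(v * i**2 for (i, _), v in counts.items()) / total,
        "SmallDependenceLowGrayLevelEmphasis":
            sum(v / (i**2 * j**2) for (i, j), v in counts.items()) / total,
        "SmallDependenceHighGrayLevelEmphasis":
            sum(v * i**2 / j**2 for (i, j), v in counts.items()) / total,
        "LargeDependenceLowGrayLevelEmphasis":
            sum(v * j**2 / i**2 for (i, j), v in counts.items()) / total,
        "LargeDependenceHighGrayLevelEmphasis":
            sum(v * i**2 * j**2 for (i, j), v in counts.items()) / total,
    }


def _avg(dicts):
    return {k: sum(d[k] for d in dicts) / len(dicts) for k in dicts[0]}


def oracle_extract(image, mask, n_bins=32):
    levels = oracle_discretize(image, mask, n_bins)
    shape = image.shape
    n_pixels = len(levels)
    out = {f"FIRSTORDER_{k}": v
           for k, v in oracle_first_order(image, mask, levels).items()}
    glcm = _avg([oracle_glcm(levels, off) for off in OFFSETS])
    out.update({f"GLCM_{k}": v for k, v in glcm.items()})
    glrlm = _avg([oracle_glrlm(levels, shape, off, n_pixels)
                  for off in OFFSETS])
    out.update({f"GLRLM_{k}": v for k, v in glrlm.items()})
    out.update({f"GLSZM_{k}": v
                for k, v in oracle_glszm(levels, n_pixels).items()})
    out.update({f"NGTDM_{k}": v for k, v in oracle_ngtdm(levels).items()})
    out.update({f"GLDM_{k}": v for k, v in oracle_gldm(levels).items()})
    return out
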