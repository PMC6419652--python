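"""Independent literal-definition oracles used only by the test suite.

Everything here is deliberately written the slow, obvious way (explicit
loops, dictionaries, flood fill) and shares no code with the package
implementations it checks.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np

NEIGH_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]

OFFSETS_13 = [
    (0, 0, 1),
    (0, 1, 0),
    (1, 0, 0),
    (0, 1, 1),
    (0, 1, -1),
    (1, 0, 1),
    (1, 0, -1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
]


def in_grid(idx, shape):
    return all(0 <= i < n for i, n in zip(idx, shape))


# ---------------------------------------------------------------- GLCM


def glcm_pairs(levels, offset):
    """Symmetrized co-occurrence counts {(i, j): count} for one offset."""
    counts = defaultdict(int)
    shape = levels.shape
    for v in np.ndindex(shape):
        if levels[v] == 0:
            continue
        w = tuple(a + b for a, b in zip(v, offset))
        if in_grid(w, shape) and levels[w] > 0:
            counts[(int(levels[v]), int(levels[w]))] += 1
            counts[(int(levels[w]), int(levels[v]))] += 1
    return dict(counts)


def glcm_features_oracle(levels):
    """Direction-averaged GLCM features by direct summation."""
    per_dir = []
    for off in OFFSETS_13:
        counts = glcm_pairs(levels, off)
        total = sum(counts.values())
        if total == 0:
            continue
        p = {k: c / total for k, c in counts.items()}
        contrast = sum(pc * (i - j) ** 2 for (i, j), pc in p.items())
        dissim = sum(pc * abs(i - j) for (i, j), pc in p.items())
        hom1 = sum(pc / (1 + abs(i - j)) for (i, j), pc in p.items())
        hom2 = sum(pc / (1 + (i - j) ** 2) for (i, j), pc in p.items())
        px = defaultdict(float)
        for (i, _j), pc in p.items():
            px[i] += pc
        mu = sum(i * q for i, q in px.items())
        var = sum((i - mu) ** 2 * q for i, q in px.items())
        if var == 0:
            corr = 1.0
        else:
            corr = (sum(i * j * pc for (i, j), pc in p.items()) - mu * mu) / var
        joint_ent = -sum(pc * math.log2(pc) for pc in p.values() if pc > 0)
        psum = defaultdict(float)
        pdiff = defaultdict(float)
        for (i, j), pc in p.items():
            psum[i + j] += pc
            pdiff[abs(i - j)] += pc
        sum_ent = -sum(q * math.log2(q) for q in psum.values() if q > 0)
        diff_ent = -sum(q * math.log2(q) for q in pdiff.values() if q > 0)
        per_dir.append(
            dict(
                contrast=contrast,
                dissimilarity=dissim,
                hom1=hom1,
                hom2=hom2,
                correlation=corr,
                joint_entropy=joint_ent,
                sum_entropy=sum_ent,
                diff_entropy=diff_ent,
            )
        )
    keys = per_dir[0].keys()
    return {k: float(np.mean([d[k] for d in per_dir])) for k in keys}


# ---------------------------------------------------------------- GLRLM


def runs_in_direction(levels, offset):
    """All maximal runs [(level, length), ...] along one direction."""
    shape = levels.shape
    runs = []
    for v in np.ndindex(shape):
        if levels[v] == 0:
            continue
        prev = tuple(a - b for a, b in zip(v, offset))
        if in_grid(prev, shape) and levels[prev] == levels[v]:
            continue  # not a run start
        length = 1
        cur = v
        while True:
            nxt = tuple(a + b for a, b in zip(cur, offset))
            if in_grid(nxt, shape) and levels[nxt] == levels[cur]:
                length += 1
                cur = nxt
            else:
                break
        runs.append((int(levels[v]), length))
    return runs


def glrlm_features_oracle(levels, n_voxels):
    per_dir = defaultdict(list)
    for off in OFFSETS_13:
        runs = runs_in_direction(levels, off)
        nr = len(runs)
        if nr == 0:
            continue
        sre = sum(1.0 / (l * l) for _g, l in runs) / nr
        lre = sum(float(l * l) for _g, l in runs) / nr
        by_g = defaultdict(int)
        by_l = defaultdict(int)
        for g, l in runs:
            by_g[g] += 1
            by_l[l] += 1
        gln = sum(c * c for c in by_g.values()) / nr
        rln = sum(c * c for c in by_l.values()) / nr
        per_dir["Short.Run.Emphasis"].append(sre)
        per_dir["Long.Run.Emphasis"].append(lre)
        per_dir["Gray.Level.Non-Uniformity"].append(gln)
        per_dir["Gray.Level.Non-Uniformity.Normalized"].append(gln / nr)
        per_dir["Run.Length.Non-Uniformity"].append(rln)
        per_dir["Run.Length.Non-Uniformity.Normalized"].append(rln / nr)
        per_dir["Run.Percentage"].append(nr / n_voxels)
    return {k: float(np.mean(v)) for k, v in per_dir.items()}


# ---------------------------------------------------------------- GLSZM


def zones_flood_fill(levels):
    """All 26-connected equal-level zones as [(level, size), ...]."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for v in np.ndindex(shape):
        if levels[v] == 0 or seen[v]:
            continue
        g = levels[v]
        stack = [v]
        seen[v] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for off in NEIGH_26:
                w = tuple(a + b for a, b in zip(cur, off))
                if in_grid(w, shape) and not seen[w] and levels[w] == g:
                    seen[w] = True
                    stack.append(w)
        zones.append((int(g), size))
    return zones


def glszm_features_oracle(levels, n_voxels):
    zones = zones_flood_fill(levels)
    nz = len(zones)
    p = 1.0 / nz
    mu_g = sum(g for g, _z in zones) * p
    mu_z = sum(z for _g, z in zones) * p
    by_g = defaultdict(int)
    by_z = defaultdict(int)
    for g, z in zones:
        by_g[g] += 1
        by_z[z] += 1
    gln = sum(c * c for c in by_g.values()) / nz
    szn = sum(c * c for c in by_z.values()) / nz
    return {
        "GrayLevelVariance": sum((g - mu_g) ** 2 for g, _z in zones) * p,
        "SmallAreaHighGrayLevelEmphasis": sum(g * g / (z * z) for g, z in zones) * p,
        "GrayLevelNonUniformity": gln,
        "GrayLevelNonUniformityNormalized": gln / nz,
        "SizeZoneNonUniformity": szn,
        "SizeZoneNonUniformityNormalized": szn / nz,
        "LargeAreaEmphasis": sum(z * z for _g, z in zones) * p,
        "ZoneVariance": sum((z - mu_z) ** 2 for _g, z in zones) * p,
        "ZonePercentage": nz / n_voxels,
    }


# ------------------------------------------------------------ first order


def first_order_oracle(values, n_bins):
    """Moment and histogram statistics computed by explicit sums."""
    values = [float(v) for v in values]
    n = len(values)
    mean = sum(values) / n
    m2 = sum((v - mean) ** 2 for v in values) / n
    m3 = sum((v - mean) ** 3 for v in values) / n
    m4 = sum((v - mean) ** 4 for v in values) / n
    out = {"Variance": m2, "STD": math.sqrt(m2)}
    out["Skewness"] = 0.0 if m2 == 0 else m3 / m2**1.5
    out["Kurtosis"] = 0.0 if m2 == 0 else m4 / m2**2
    lo, hi = min(values), max(values)
    hist = defaultdict(int)
    if hi == lo:
        hist[1] = n
    else:
        width = (hi - lo) / n_bins
        for v in values:
            b = min(int((v - lo) / width) + 1, n_bins)
            hist[b] += 1
    probs = [c / n for c in hist.values()]
    out["Entropy.image"] = -sum(p * math.log2(p) for p in probs)
    out["Energy"] = sum(p * p for p in probs)
    return out


def discretize_oracle(values_in_voi, n_bins):
    """Level assignment for a flat list of in-VOI values."""
    lo, hi = min(values_in_voi), max(values_in_voi)
    if hi == lo:
        return [1] * len(values_in_voi)
    width = (hi - lo) / n_bins
    return [min(int((v - lo) / width) + 1, n_bins) for v in values_in_voi]


# ------------------------------------------------------------- survival


def logrank_chi2_oracle(times, events, groups):
    """Two-group log-rank chi-square from the 2x2 tables at each event time."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    assert len(labels) == 2
    g1 = groups == labels[1]
    oml = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & g1).sum()
        oml += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return float(oml**2 / var)


def cox_grid_search_beta(x, times, events, lo=-5.0, hi=5.0, step=1e-4):
    """Dense grid maximization of the Efron partial log-likelihood."""
    x = np.asarray(x, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)

    def loglik(beta):
        ll = 0.0
        for t in sorted(set(times[events == 1])):
            dead = (times == t) & (events == 1)
            risk = times >= t
            wD = np.exp(beta * x[dead])
            wR = np.exp(beta * x[risk])
            d = dead.sum()
            ll += beta * x[dead].sum()
            for l in range(d):
                ll -= math.log(wR.sum() - (l / d) * wD.sum())
        return ll

    grid = np.arange(lo, hi + step, step)
    lls = np.array([loglik(b) for b in grid])
    return float(grid[int(np.argmax(lls))])


# -------------------------------------------------------------- phantom


def highres_phantom_max_oracle(
    center_mm, radius_mm, peak_suv, background_suv, psf_fwhm_mm, spacing_mm, shape, factor=4
):
    """Max coarse-grid voxel value via fine-grid rendering + discrete PSF
    convolution, sampled back at the coarse voxel centers."""
    from scipy.ndimage import gaussian_filter

    fine_spacing = [s / factor for s in spacing_mm]
    fine_shape = [(n - 1) * factor + 1 for n in shape]
    axes = [np.arange(n) * s for n, s in zip(fine_shape, fine_spacing)]
    r2 = (
        (axes[0][:, None, None] - center_mm[0]) ** 2
        + (axes[1][None, :, None] - center_mm[1]) ** 2
        + (axes[2][None, None, :] - center_mm[2]) ** 2
    )
    sigma_l = radius_mm / 2.0
    img = background_suv + (peak_suv - background_suv) * np.exp(-r2 / (2 * sigma_l**2))
    sigma_p = psf_fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    img = gaussian_filter(img, [sigma_p / s for s in fine_spacing], mode="nearest")
    coarse = img[::factor, ::factor, ::factor]
    return float(coarse.max())
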