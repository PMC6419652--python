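"""Standard SUV parameters and the 35-feature radiomic panel.

All texture features operate on a VOI discretized to a fixed number of gray
levels (default 255 equal-width bins over the in-VOI min-max range) and use
the 26-neighborhood: 13 unique direction offsets at distance 1 voxel for the
co-occurrence (GLCM) and run-length (GLRLM) matrices, 26-connectivity for the
size-zone (GLSZM) zones.  Formulas follow the common toolbox definitions for
each feature name; GLCM and GLRLM features are computed per direction and
averaged (unweighted) over non-empty directions.

Feature names reproduce the output-table headers verbatim, including the
``.1/.2/.3`` suffixes on the three GLCM entropies (toolbox column artifacts
kept for column-name compatibility).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import numpy as np
from scipy import ndimage

from .phantom import PhantomImage
from .segmentation import VOIMask, mtv

__all__ = [
    "FEATURE_NAMES",
    "DiscretizedVOI",
    "FeatureVector",
    "standard_params",
    "discretize",
    "first_order_features",
    "build_glcm",
    "glcm_features",
    "build_glrlm",
    "glrlm_features",
    "build_glszm",
    "glszm_features",
    "extract_all",
    "OFFSETS_13",
]

# the 13 unique 26-neighborhood offsets (one per +/- direction pair)
OFFSETS_13: tuple[tuple[int, int, int], ...] = (
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
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

FEATURE_NAMES: tuple[str, ...] = (
    "MTV",
    "SUVmin",
    "SUVmax",
    "SUVmean",
    "SUVdiff",
    "Variance",
    "Skewness",
    "Kurtosis",
    "Entropy.image",
    "STD",
    "Energy",
    "Contrast",
    "Dissimilarity",
    "Homogeneity.1",
    "Homogeneity.2",
    "Correlation",
    "Difference Entropy.1",
    "Joint Entropy.2",
    "Sum Entropy.3",
    "Short.Run.Emphasis",
    "Long.Run.Emphasis",
    "Gray.Level.Non-Uniformity",
    "Gray.Level.Non-Uniformity.Normalized",
    "Run.Length.Non-Uniformity",
    "Run.Length.Non-Uniformity.Normalized",
    "Run.Percentage",
    "GrayLevelVariance",
    "SmallAreaHighGrayLevelEmphasis",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "GrayLevelNonUniformity",
    "LargeAreaEmphasis",
    "ZoneVariance",
    "ZonePercentage",
)


@dataclass(frozen=True)
class DiscretizedVOI:
    """Integer level grid (1..n_bins inside the VOI, 0 outside)."""

    levels: np.ndarray
    n_bins: int
    bin_edges: np.ndarray

    @property
    def mask(self) -> np.ndarray:
        return self.levels > 0

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.levels))


class FeatureVector(dict):
    """Ordered mapping of the 35 named features (plus nothing else)."""

    def __init__(self, values: Mapping[str, float]):
        missing = set(FEATURE_NAMES) - set(values)
        extra = set(values) - set(FEATURE_NAMES)
        if missing or extra:
            raise ValueError(f"feature set mismatch: missing={missing}, extra={extra}")
        super().__init__({name: float(values[name]) for name in FEATURE_NAMES})


def standard_params(image: PhantomImage, voi: VOIMask) -> Dict[str, float]:
    """SUVmax / SUVmin / SUVmean / SUVdiff (= max - min) and MTV in ml."""
    vals = image.values[voi.mask]
    if vals.size == 0:
        raise ValueError("empty VOI")
    vmax, vmin = float(vals.max()), float(vals.min())
    return {
        "SUVmax": vmax,
        "SUVmin": vmin,
        "SUVmean": float(vals.mean()),
        "SUVdiff": vmax - vmin,
        "MTV": mtv(voi, image.spacing_mm),
    }


def discretize(image: PhantomImage, voi: VOIMask, n_bins: int = 255) -> DiscretizedVOI:
    """Fixed-bin-count equal-width discretization over the in-VOI range.

    level = floor((v - min) / width) + 1 with the maximum mapped to n_bins;
    a constant VOI maps everything to level 1.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    mask = voi.mask
    vals = image.values[mask]
    if vals.size == 0:
        raise ValueError("empty VOI")
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(image.shape, dtype=np.int32)
    if hi == lo:
        levels[mask] = 1
        edges = np.array([lo, hi])
    else:
        width = (hi - lo) / n_bins
        lev = np.floor((vals - lo) / width).astype(np.int32) + 1
        levels[mask] = np.clip(lev, 1, n_bins)
        edges = lo + width * np.arange(n_bins + 1)
    return DiscretizedVOI(levels, int(n_bins), edges)


def first_order_features(
    image: PhantomImage, voi: VOIMask, n_bins: int = 255
) -> Dict[str, float]:
    """Histogram statistics of the raw in-VOI intensities.

    Variance/STD are population moments; Skewness = m3/m2^1.5 and Kurtosis =
    m4/m2^2 (non-excess, normal -> 3).  Entropy (bits) and Energy are taken
    over the fixed-bin-count histogram used for discretization.  A
    zero-variance VOI returns Skewness = Kurtosis = 0 (degenerate).
    """
    vals = image.values[voi.mask]
    if vals.size < 2:
        raise ValueError("VOI needs at least 2 voxels")
    mean = vals.mean()
    dev = vals - mean
    m2 = float(np.mean(dev**2))
    out: Dict[str, float] = {"Variance": m2, "STD": float(np.sqrt(m2))}
    if m2 == 0.0:
        out["Skewness"] = 0.0
        out["Kurtosis"] = 0.0
    else:
        out["Skewness"] = float(np.mean(dev**3) / m2**1.5)
        out["Kurtosis"] = float(np.mean(dev**4) / m2**2)
    d = discretize(image, voi, n_bins)
    counts = np.bincount(d.levels[d.mask], minlength=d.n_bins + 1)[1:]
    p = counts[counts > 0] / vals.size
    out["Entropy.image"] = float(-np.sum(p * np.log2(p)))
    out["Energy"] = float(np.sum(p**2))
    return out


def _shift_int(arr: np.ndarray, offset: tuple[int, int, int], fill=0) -> np.ndarray:
    """out[v] = arr[v + offset], with `fill` where v + offset leaves the grid."""
    out = np.full_like(arr, fill)
    src, dst = [], []
    for n, d in zip(arr.shape, offset):
        if d >= 0:
            dst.append(slice(0, n - d))
            src.append(slice(d, n))
        else:
            dst.append(slice(-d, n))
            src.append(slice(0, n + d))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def build_glcm(d: DiscretizedVOI) -> Dict[tuple[int, int, int], np.ndarray]:
    """Symmetrized co-occurrence count matrix per direction offset.

    Counts in-VOI voxel pairs separated by each of the 13 offsets (both
    endpoints inside the VOI), then adds the transpose.
    """
    nb = d.n_bins
    L = d.levels
    out: Dict[tuple[int, int, int], np.ndarray] = {}
    for off in OFFSETS_13:
        Ls = _shift_int(L, off)
        both = (L > 0) & (Ls > 0)
        i = L[both] - 1
        j = Ls[both] - 1
        m = np.bincount(i * nb + j, minlength=nb * nb).reshape(nb, nb)
        out[off] = m + m.T
    return out


def _marginal_entropies(P: np.ndarray, iv: np.ndarray) -> tuple[float, float]:
    """(sum entropy, difference entropy) of a normalized GLCM (bits)."""
    nb = P.shape[0]
    sums = (iv[:, None] + iv[None, :]).ravel()
    diffs = np.abs(iv[:, None] - iv[None, :]).ravel()
    p_sum = np.bincount(sums - 2, weights=P.ravel(), minlength=2 * nb - 1)
    p_diff = np.bincount(diffs, weights=P.ravel(), minlength=nb)
    ps = p_sum[p_sum > 0]
    pd = p_diff[p_diff > 0]
    return float(-np.sum(ps * np.log2(ps))), float(-np.sum(pd * np.log2(pd)))


def glcm_features(glcm: Mapping[tuple[int, int, int], np.ndarray]) -> Dict[str, float]:
    """The eight co-occurrence features, averaged over non-empty directions."""
    feats = {
        "Contrast": [],
        "Dissimilarity": [],
        "Homogeneity.1": [],
        "Homogeneity.2": [],
        "Correlation": [],
        "Difference Entropy.1": [],
        "Joint Entropy.2": [],
        "Sum Entropy.3": [],
    }
    any_dir = False
    for M in glcm.values():
        total = M.sum()
        if total == 0:
            continue
        any_dir = True
        P = M / total
        nb = P.shape[0]
        iv = np.arange(1, nb + 1)
        di = iv[:, None] - iv[None, :]
        absdi = np.abs(di)
        feats["Contrast"].append(float(np.sum(P * di**2)))
        feats["Dissimilarity"].append(float(np.sum(P * absdi)))
        feats["Homogeneity.1"].append(float(np.sum(P / (1.0 + absdi))))
        feats["Homogeneity.2"].append(float(np.sum(P / (1.0 + di**2))))
        px = P.sum(axis=1)
        mu_x = float(np.sum(iv * px))
        var_x = float(np.sum((iv - mu_x) ** 2 * px))
        # symmetric matrix: marginals coincide
        if var_x == 0.0:
            feats["Correlation"].append(1.0)  # degenerate single-level VOI
        else:
            cross = float(np.sum(P * iv[:, None] * iv[None, :]))
            feats["Correlation"].append((cross - mu_x * mu_x) / var_x)
        pn = P[P > 0]
        feats["Joint Entropy.2"].append(float(-np.sum(pn * np.log2(pn))))
        se, de = _marginal_entropies(P, iv)
        feats["Sum Entropy.3"].append(se)
        feats["Difference Entropy.1"].append(de)
    if not any_dir:
        raise ValueError("all GLCM direction matrices are empty")
    return {k: float(np.mean(v)) for k, v in feats.items()}


def build_glrlm(d: DiscretizedVOI) -> Dict[tuple[int, int, int], np.ndarray]:
    """Run-length count matrix r(level, run length) per direction.

    A run is a maximal straight segment of equal-level in-VOI voxels along
    the offset; voxels outside the VOI break runs.  Run lengths are found by
    an iterative forward-extension pass (vectorized pointer chase).
    """
    L = d.levels
    nb = d.n_bins
    max_len = max(L.shape)
    out: Dict[tuple[int, int, int], np.ndarray] = {}
    for off in OFFSETS_13:
        nxt = _shift_int(L, off)
        same = (L > 0) & (L == nxt)  # run continues from v to v+off
        # f[v] = remaining run length starting at v
        f = (L > 0).astype(np.int32)
        while True:
            f_new = np.where(same, 1 + _shift_int(f, off), (L > 0).astype(np.int32))
            if np.array_equal(f_new, f):
                break
            f = f_new
        back = (-off[0], -off[1], -off[2])
        prev_same = _shift_int(same, back)  # same[v - off]: v continues a run
        starts = (L > 0) & ~prev_same
        g = L[starts] - 1
        ln = f[starts] - 1
        m = np.bincount(g * max_len + ln, minlength=nb * max_len).reshape(nb, max_len)
        out[off] = m
    return out


def glrlm_features(
    glrlm: Mapping[tuple[int, int, int], np.ndarray], n_voxels: int
) -> Dict[str, float]:
    """The seven run-length features, averaged over non-empty directions."""
    acc = {
        "Short.Run.Emphasis": [],
        "Long.Run.Emphasis": [],
        "Gray.Level.Non-Uniformity": [],
        "Gray.Level.Non-Uniformity.Normalized": [],
        "Run.Length.Non-Uniformity": [],
        "Run.Length.Non-Uniformity.Normalized": [],
        "Run.Percentage": [],
    }
    for R in glrlm.values():
        nr = R.sum()
        if nr == 0:
            continue
        lengths = np.arange(1, R.shape[1] + 1, dtype=np.float64)
        r_l = R.sum(axis=0)  # runs per length
        r_g = R.sum(axis=1)  # runs per gray level
        acc["Short.Run.Emphasis"].append(float(np.sum(r_l / lengths**2) / nr))
        acc["Long.Run.Emphasis"].append(float(np.sum(r_l * lengths**2) / nr))
        gln = float(np.sum(r_g.astype(np.float64) ** 2) / nr)
        acc["Gray.Level.Non-Uniformity"].append(gln)
        acc["Gray.Level.Non-Uniformity.Normalized"].append(gln / nr)
        rln = float(np.sum(r_l.astype(np.float64) ** 2) / nr)
        acc["Run.Length.Non-Uniformity"].append(rln)
        acc["Run.Length.Non-Uniformity.Normalized"].append(rln / nr)
        acc["Run.Percentage"].append(float(nr / n_voxels))
    if not acc["Run.Percentage"]:
        raise ValueError("empty GLRLM")
    return {k: float(np.mean(v)) for k, v in acc.items()}


@dataclass(frozen=True)
class GLSZM:
    """Sparse size-zone matrix: parallel (level, zone size, count) arrays."""

    levels: np.ndarray
    sizes: np.ndarray
    counts: np.ndarray
    n_bins: int

    @property
    def n_zones(self) -> int:
        return int(self.counts.sum())

    def to_dense(self) -> np.ndarray:
        out = np.zeros((self.n_bins, int(self.sizes.max())), dtype=np.int64)
        out[self.levels - 1, self.sizes - 1] = self.counts
        return out


def build_glszm(d: DiscretizedVOI) -> GLSZM:
    """Size-zone matrix: 26-connected equal-level zones and their sizes."""
    L = d.levels
    pairs: Dict[tuple[int, int], int] = {}
    for g in np.unique(L[L > 0]):
        lab, n_lab = ndimage.label(L == g, structure=_STRUCT_26)
        if n_lab == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            pairs[(int(g), int(s))] = pairs.get((int(g), int(s)), 0) + 1
    if not pairs:
        raise ValueError("empty VOI")
    keys = sorted(pairs)
    levels = np.array([k[0] for k in keys], dtype=np.int64)
    sizes = np.array([k[1] for k in keys], dtype=np.int64)
    counts = np.array([pairs[k] for k in keys], dtype=np.int64)
    return GLSZM(levels, sizes, counts, d.n_bins)


def glszm_features(glszm: GLSZM, n_voxels: int) -> Dict[str, float]:
    """The nine size-zone features from the sparse zone matrix."""
    g = glszm.levels.astype(np.float64)
    z = glszm.sizes.astype(np.float64)
    c = glszm.counts.astype(np.float64)
    nz = c.sum()
    p = c / nz
    mu_g = float(np.sum(p * g))
    mu_z = float(np.sum(p * z))
    # marginal sums over unique levels / unique sizes
    s_g = np.bincount(glszm.levels, weights=c)
    s_z = np.bincount(glszm.sizes, weights=c)
    gln = float(np.sum(s_g**2) / nz)
    szn = float(np.sum(s_z**2) / nz)
    return {
        "GrayLevelVariance": float(np.sum(p * (g - mu_g) ** 2)),
        "SmallAreaHighGrayLevelEmphasis": float(np.sum(p * g**2 / z**2)),
        "GrayLevelNonUniformity": gln,
        "GrayLevelNonUniformityNormalized": gln / nz,
        "SizeZoneNonUniformity": szn,
        "SizeZoneNonUniformityNormalized": szn / nz,
        "LargeAreaEmphasis": float(np.sum(p * z**2)),
        "ZoneVariance": float(np.sum(p * (z - mu_z) ** 2)),
        "ZonePercentage": float(nz / n_voxels),
    }


def extract_all(
    image: PhantomImage, voi: VOIMask, n_bins: int = 255
) -> FeatureVector:
    """The complete 35-entry feature vector for one image/VOI pair."""
    out: Dict[str, float] = {}
    out.update(standard_params(image, voi))
    out.update(first_order_features(image, voi, n_bins))
    d = discretize(image, voi, n_bins)
    out.update(glcm_features(build_glcm(d)))
    out.update(glrlm_features(build_glrlm(d), d.n_voxels))
    out.update(glszm_features(build_glszm(d), d.n_voxels))
    return FeatureVector(out)
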