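"""From-scratch 3D radiomics texture engine.

Implements gray-level discretization, the three matrix families used by the
radiomics signature — co-occurrence (GLCM), size-zone (GLSZM) and
neighbourhood gray-tone difference (NGTDM) — first-order statistics, and a
filter bank (wavelet sub-bands, Laplacian-of-Gaussian, exponential,
square-root, LBP-3D maps).  Features are emitted under canonical
``<filter>_<class>_<feature>`` names, e.g.
``exponential_glszm_SmallAreaEmphasis``.

All matrix builders operate on an integer-labelled VOI (levels 1..Ng) and
aggregate the 13 unique 3D directions into a single pooled, symmetrized
matrix, which makes the features invariant to axis-aligned rigid rotations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage

from .imagio import ImageVolume, SegmentationMask

__all__ = [
    "DiscretizationSpec",
    "discretize",
    "firstorder_features",
    "glcm_matrix",
    "glcm_features",
    "glszm_matrix",
    "glszm_features",
    "ngtdm_table",
    "ngtdm_features",
    "filter_bank",
    "extract_all",
    "DEFAULT_FILTERS",
]

# the 13 unique 3D direction offsets (the other 13 are their negatives)
OFFSETS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)
assert len(OFFSETS_3D) == 13


@dataclass(frozen=True)
class DiscretizationSpec:
    """Gray-level discretization: fixed bin width (HU) or fixed bin count."""

    mode: str = "width"  # "width" | "count"
    bin_width: float = 25.0
    bin_count: int = 16

    def __post_init__(self) -> None:
        if self.mode not in ("width", "count"):
            raise ValueError(f"unknown discretization mode {self.mode!r}")
        if self.mode == "width" and self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.mode == "count" and self.bin_count <= 0:
            raise ValueError("bin_count must be positive")


def discretize(
    data: np.ndarray, mask: np.ndarray, spec: DiscretizationSpec
) -> tuple[np.ndarray, int]:
    """Integer-label the VOI: levels start at 1, 0 marks background.

    Fixed width: ``level = floor((x - min_VOI) / width) + 1``.
    Fixed count: equal-width bins spanning the VOI range; the maximum value
    lands in the top bin.
    """
    m = np.asarray(mask).astype(bool)
    if not m.any():
        raise ValueError("empty mask")
    vals = np.asarray(data, dtype=np.float64)[m]
    lab = np.zeros(np.asarray(data).shape, dtype=np.int32)
    lo, hi = vals.min(), vals.max()
    if spec.mode == "width":
        levels = np.floor((vals - lo) / spec.bin_width).astype(np.int32) + 1
    else:
        if hi <= lo:
            levels = np.ones(vals.shape, dtype=np.int32)
        else:
            w = (hi - lo) / spec.bin_count
            levels = np.minimum(
                np.floor((vals - lo) / w).astype(np.int32) + 1, spec.bin_count
            )
    lab[m] = levels
    return lab, int(levels.max())


# ---------------------------------------------------------------------------
# first order

def firstorder_features(values: np.ndarray, n_bins_entropy: int = 16) -> dict[str, float]:
    """First-order statistics of the raw VOI intensities.

    Skewness uses population moments ``m3 / m2^1.5`` and kurtosis is
    non-excess ``m4 / m2^2`` (a normal sample tends to 3).  A zero-variance
    VOI yields skewness 0 and kurtosis NaN (with a warning) rather than
    aborting a cohort run.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("no values")
    mean = x.mean()
    c = x - mean
    m2 = np.mean(c**2)
    out: dict[str, float] = {
        "Mean": float(mean),
        "Median": float(np.median(x)),
        "Minimum": float(x.min()),
        "Maximum": float(x.max()),
        "Range": float(x.max() - x.min()),
        "Variance": float(m2),
        "Energy": float(np.sum(x**2)),
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
    }
    if m2 > 0:
        out["Skewness"] = float(np.mean(c**3) / m2**1.5)
        out["Kurtosis"] = float(np.mean(c**4) / m2**2)
    else:
        warnings.warn("zero-variance VOI: skewness set to 0, kurtosis undefined")
        out["Skewness"] = 0.0
        out["Kurtosis"] = float("nan")
    # histogram entropy on an equal-width binning of the VOI range
    if x.max() > x.min():
        hist, _ = np.histogram(x, bins=n_bins_entropy)
    else:
        hist = np.array([x.size])
    p = hist[hist > 0] / x.size
    out["Entropy"] = float(-np.sum(p * np.log2(p)))
    return out


# ---------------------------------------------------------------------------
# GLCM

def glcm_matrix(
    labelled: np.ndarray,
    distance: int = 1,
    offsets: tuple[tuple[int, int, int], ...] = OFFSETS_3D,
) -> np.ndarray:
    """Pooled symmetric co-occurrence probability matrix.

    Counts level pairs at `distance` along each offset direction (both
    voxels inside the VOI), adds the transpose, pools all directions and
    normalizes to sum 1.  The default offsets are the 13 unique 3D
    directions; a custom subset supports per-direction analysis.
    """
    lab = np.asarray(labelled)
    ng = int(lab.max())
    if (lab > 0).sum() < 2:
        raise ValueError("GLCM needs at least two occupied voxels")
    counts = np.zeros((ng, ng), dtype=np.float64)
    for off in offsets:
        o = tuple(d * distance for d in off)
        sl_a = tuple(
            slice(max(0, -d), min(s, s - d)) for d, s in zip(o, lab.shape)
        )
        sl_b = tuple(
            slice(max(0, d), min(s, s + d)) for d, s in zip(o, lab.shape)
        )
        a = lab[sl_a].ravel()
        b = lab[sl_b].ravel()
        ok = (a > 0) & (b > 0)
        if ok.any():
            np.add.at(counts, (a[ok] - 1, b[ok] - 1), 1.0)
    counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("no co-occurring voxel pairs inside the VOI")
    return counts / total


def glcm_features(labelled: np.ndarray, distance: int = 1) -> dict[str, float]:
    p = glcm_matrix(labelled, distance)
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu_x = float(np.sum(i * px))
    mu_y = mu_x  # symmetric matrix
    sig_x = float(np.sqrt(np.sum((i - mu_x) ** 2 * px)))
    eps = np.finfo(float).tiny
    feats = {
        "Contrast": float(np.sum((ii - jj) ** 2 * p)),
        "ClusterProminence": float(np.sum((ii + jj - mu_x - mu_y) ** 4 * p)),
        "ClusterShade": float(np.sum((ii + jj - mu_x - mu_y) ** 3 * p)),
        "JointEnergy": float(np.sum(p**2)),
        "JointEntropy": float(-np.sum(p[p > 0] * np.log2(p[p > 0]))),
        "Idm": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "Autocorrelation": float(np.sum(ii * jj * p)),
    }
    if sig_x > 0:
        feats["Correlation"] = float(
            (np.sum(ii * jj * p) - mu_x * mu_y) / (sig_x * sig_x + eps)
        )
    else:
        feats["Correlation"] = 1.0
    return feats


# ---------------------------------------------------------------------------
# GLSZM

def glszm_matrix(labelled: np.ndarray) -> dict[tuple[int, int], int]:
    """Zone counts keyed by (gray level, zone size), 26-connected zones."""
    lab = np.asarray(labelled)
    if not (lab > 0).any():
        raise ValueError("empty VOI")
    structure = np.ones((3, 3, 3), dtype=bool)
    zones: dict[tuple[int, int], int] = {}
    for level in np.unique(lab[lab > 0]):
        comp, n = ndimage.label(lab == level, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(comp.ravel())[1:]
        for s in sizes:
            key = (int(level), int(s))
            zones[key] = zones.get(key, 0) + 1
    return zones


def glszm_features(labelled: np.ndarray) -> dict[str, float]:
    """Size-zone features from 26-connected equal-level zones.

    With zone counts P(i, j) over Nz zones (i = gray level, j = zone size):

    * SmallAreaEmphasis      = (1/Nz) Σ P / j²
    * LargeAreaEmphasis      = (1/Nz) Σ P j²
    * SizeZoneNonUniformity  = (1/Nz) Σ_j (Σ_i P)²
    * GrayLevelNonUniformity = (1/Nz) Σ_i (Σ_j P)²
    * SmallAreaLowGrayLevelEmphasis = (1/Nz) Σ P / (i² j²)
    * ZoneVariance  = Σ p_j (j − μ)² over the zone-size marginal
    * ZonePercentage = Nz / N_voxels
    """
    lab = np.asarray(labelled)
    zones = glszm_matrix(lab)
    nz = sum(zones.values())
    n_vox = int((lab > 0).sum())
    sizes: dict[int, int] = {}
    levels: dict[int, int] = {}
    sae = lae = salgle = 0.0
    for (i, j), c in zones.items():
        sae += c / j**2
        lae += c * j**2
        salgle += c / (i**2 * j**2)
        sizes[j] = sizes.get(j, 0) + c
        levels[i] = levels.get(i, 0) + c
    mu = sum(j * c for j, c in sizes.items()) / nz
    zone_var = sum((c / nz) * (j - mu) ** 2 for j, c in sizes.items())
    return {
        "SmallAreaEmphasis": sae / nz,
        "LargeAreaEmphasis": lae / nz,
        "SizeZoneNonUniformity": sum(c**2 for c in sizes.values()) / nz,
        "GrayLevelNonUniformity": sum(c**2 for c in levels.values()) / nz,
        "SmallAreaLowGrayLevelEmphasis": salgle / nz,
        "ZoneVariance": zone_var,
        "ZonePercentage": nz / n_vox,
    }


# ---------------------------------------------------------------------------
# NGTDM

def ngtdm_table(
    labelled: np.ndarray, require_full_neighbourhood: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-level (n_i, p_i, s_i) for the neighbourhood gray-tone difference.

    For each in-VOI voxel the mean gray level of its in-VOI neighbours is
    computed (26-neighbourhood in 3D, 8 in 2D); ``s_i`` accumulates
    ``|i − neighbour mean|`` over voxels of level ``i``.  Voxels with no
    in-VOI neighbour are excluded; with ``require_full_neighbourhood`` only
    voxels whose entire neighbourhood exists and lies inside the VOI
    contribute.
    """
    lab = np.asarray(labelled, dtype=np.float64)
    m = lab > 0
    if not m.any():
        raise ValueError("empty VOI")
    kernel = np.ones((3,) * lab.ndim)
    kernel[(1,) * lab.ndim] = 0.0
    n_full = 3**lab.ndim - 1
    nb_sum = ndimage.convolve(lab * m, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.convolve(m.astype(np.float64), kernel, mode="constant", cval=0.0)
    if require_full_neighbourhood:
        valid = m & (nb_cnt >= n_full - 1e-9)
    else:
        valid = m & (nb_cnt > 0)
    ng = int(lab.max())
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    lv = lab[valid].astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        diffs = np.abs(lab[valid] - nb_sum[valid] / nb_cnt[valid])
    np.add.at(n_i, lv - 1, 1.0)
    np.add.at(s_i, lv - 1, diffs)
    total = n_i.sum()
    p_i = n_i / total if total > 0 else n_i
    return n_i, p_i, s_i


def ngtdm_features(
    labelled: np.ndarray, require_full_neighbourhood: bool = False
) -> dict[str, float]:
    """Busyness, Coarseness, Contrast, Complexity, Strength.

    Sums run over levels with nonzero probability; degenerate denominators
    (a single occupied level) yield 0 for the ratio features.
    """
    n_i, p_i, s_i = ngtdm_table(labelled, require_full_neighbourhood)
    ng = len(p_i)
    n_tot = n_i.sum()
    occ = np.flatnonzero(p_i > 0)
    ngp = len(occ)
    lv = occ + 1.0
    p = p_i[occ]
    s = s_i[occ]
    feats: dict[str, float] = {}
    ps = float(np.sum(p * s))
    feats["Coarseness"] = float(1.0 / ps) if ps > 0 else 0.0
    if ngp > 1 and n_tot > 0:
        di = lv[:, None] - lv[None, :]
        pij = p[:, None] * p[None, :]
        feats["Contrast"] = float(
            np.sum(pij * di**2) / (ngp * (ngp - 1)) * (s.sum() / n_tot)
        )
        denom = float(np.sum(np.abs(lv[:, None] * p[:, None] - lv[None, :] * p[None, :])))
        feats["Busyness"] = float(ps / denom) if denom > 0 else 0.0
        comp = np.sum(
            np.abs(di) * (p[:, None] * s[:, None] + p[None, :] * s[None, :]) / (p[:, None] + p[None, :])
        )
        feats["Complexity"] = float(comp / n_tot)
        stren = np.sum((p[:, None] + p[None, :]) * di**2)
        feats["Strength"] = float(stren / ps) if ps > 0 else 0.0
    else:
        feats["Contrast"] = 0.0
        feats["Busyness"] = 0.0
        feats["Complexity"] = 0.0
        feats["Strength"] = 0.0
    return feats


# ---------------------------------------------------------------------------
# filter bank

def _wavelet_subbands(data: np.ndarray, wavelet: str = "coif1") -> dict[str, np.ndarray]:
    """One-level stationary 3D wavelet decomposition, same-shape sub-bands.

    Sub-band names concatenate per-axis H/L in (axis0, axis1, axis2) order,
    e.g. ``HHL`` = highpass along the first two axes, lowpass along the
    third.  Odd axes are edge-padded to even length and cropped back.
    """
    pad = [(0, s % 2) for s in data.shape]
    x = np.pad(data, pad, mode="edge")
    coeffs = pywt.swtn(x, wavelet, level=1, start_level=0)[0]
    out = {}
    for key, arr in coeffs.items():
        name = "".join("L" if c == "a" else "H" for c in key)
        out[name] = arr[tuple(slice(0, s) for s in data.shape)]
    return out


def _lbp3d_maps(data: np.ndarray) -> dict[str, np.ndarray]:
    """Simplified rotation-invariant LBP-3D maps on the radius-1 sphere.

    For every voxel the 26 neighbour differences ``d_j = x_j − x_c`` are
    reduced to three rotation-invariant maps: ``m1`` the mean sign
    occupancy, ``m2`` the magnitude of the first-moment (dipole) vector of
    the sign pattern, and ``k`` the kurtosis of the difference
    distribution.  This is a deliberately lightweight variant of the
    spherical-harmonic LBP family; it is kept behind a feature flag and is
    not part of the oracle-checked matrix builders.
    """
    offsets = [o for o in np.ndindex(3, 3, 3) if o != (1, 1, 1)]
    dirs = np.array([np.array(o) - 1 for o in offsets], dtype=np.float64)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    padded = np.pad(data, 1, mode="edge")
    n = len(offsets)
    diffs = np.empty((n,) + data.shape, dtype=np.float64)
    for k, (oz, oy, ox) in enumerate(offsets):
        diffs[k] = padded[
            oz : oz + data.shape[0], oy : oy + data.shape[1], ox : ox + data.shape[2]
        ] - data
    signs = (diffs >= 0).astype(np.float64)
    m1 = signs.mean(axis=0)
    dip = np.tensordot(dirs, signs, axes=(0, 0))  # (3, z, y, x)
    m2 = np.sqrt(np.sum(dip**2, axis=0)) / n
    mu = diffs.mean(axis=0)
    c = diffs - mu
    v = np.mean(c**2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        k_map = np.where(v > 1e-12, np.mean(c**4, axis=0) / np.maximum(v, 1e-300) ** 2, 0.0)
    return {"lbp_3D_m1": m1, "lbp_3D_m2": m2, "lbp_3D_k": k_map}


SUPPORTED_FILTERS = ("original", "wavelet", "log_sigma", "exponential", "squareroot", "lbp3d")
DEFAULT_FILTERS = SUPPORTED_FILTERS

# filters whose output is no longer on the HU scale: discretize by bin count
_NON_HU = ("exponential", "squareroot", "lbp_3D")


def filter_bank(
    volume: ImageVolume,
    which: tuple[str, ...] = DEFAULT_FILTERS,
    log_sigma_mm: float = 2.0,
    wavelet: str = "coif1",
) -> dict[str, np.ndarray]:
    """Apply the image filter bank; returns filter-name → filtered grid."""
    unknown = set(which) - set(SUPPORTED_FILTERS)
    if unknown:
        raise ValueError(
            f"unknown filter(s) {sorted(unknown)}; supported: {list(SUPPORTED_FILTERS)}"
        )
    data = volume.data
    out: dict[str, np.ndarray] = {}
    if "original" in which:
        out["original"] = data
    if "wavelet" in which:
        for name, arr in _wavelet_subbands(data, wavelet).items():
            out[f"wavelet_{name}"] = arr
    if "log_sigma" in which:
        sig_vox = [log_sigma_mm / s for s in volume.spacing]
        tag = f"log_sigma_{log_sigma_mm:.1f}".replace(".", "_") + "_mm_3D"
        # mean-center first: the truncated discrete kernel has a small
        # nonzero DC gain, and the Laplacian of a constant must be 0
        out[tag] = ndimage.gaussian_laplace(data - data.mean(), sigma=sig_vox)
    if "exponential" in which:
        a = np.abs(data)
        amax = a.max()
        out["exponential"] = np.exp(a / amax) if amax > 0 else np.ones_like(a)
    if "squareroot" in which:
        out["squareroot"] = np.sign(data) * np.sqrt(np.abs(data))
    if "lbp3d" in which:
        out.update(_lbp3d_maps(data))
    return out


@dataclass(frozen=True)
class FeatureConfig:
    """Extraction configuration: filters, discretization, feature classes."""

    filters: tuple[str, ...] = DEFAULT_FILTERS
    disc_hu: DiscretizationSpec = DiscretizationSpec("width", bin_width=25.0)
    disc_other: DiscretizationSpec = DiscretizationSpec("count", bin_count=16)
    classes: tuple[str, ...] = ("firstorder", "glcm", "glszm", "ngtdm")
    glcm_distance: int = 1
    log_sigma_mm: float = 2.0


def extract_all(
    volume: ImageVolume,
    mask: SegmentationMask,
    config: FeatureConfig | None = None,
) -> dict[str, float]:
    """Extract every configured feature as a flat, canonically named row.

    A feature class that fails on a degenerate VOI (e.g. single level)
    yields NaN for its features with a warning instead of aborting the
    patient.
    """
    if config is None:
        config = FeatureConfig()
    if volume.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    filtered = filter_bank(volume, config.filters, log_sigma_mm=config.log_sigma_mm)
    # crop all grids to the mask bounding box (+1 voxel): the matrix
    # builders only see in-VOI voxels, so this changes nothing but speed
    full = mask.data
    bbox = tuple(
        slice(max(idx.min() - 1, 0), min(idx.max() + 2, s))
        for idx, s in zip(np.nonzero(full), full.shape)
    )
    m = full[bbox]
    filtered = {k: v[bbox] for k, v in filtered.items()}
    row: dict[str, float] = {}
    class_fns = {
        "glcm": lambda lab: glcm_features(lab, config.glcm_distance),
        "glszm": glszm_features,
        "ngtdm": ngtdm_features,
    }
    for fname, grid in filtered.items():
        spec = (
            config.disc_other
            if any(fname.startswith(p) for p in _NON_HU)
            else config.disc_hu
        )
        if "firstorder" in config.classes:
            for k, v in firstorder_features(grid[m]).items():
                row[f"{fname}_firstorder_{k}"] = v
        lab, _ = discretize(grid, m, spec)
        for cls in config.classes:
            if cls == "firstorder":
                continue
            try:
                feats = class_fns[cls](lab)
            except ValueError as exc:
                warnings.warn(f"{fname}/{cls} failed ({exc}); emitting NaN")
                feats = {k: float("nan") for k in _CLASS_FEATURE_NAMES[cls]}
            for k, v in feats.items():
                row[f"{fname}_{cls}_{k}"] = float(v)
    return row


_CLASS_FEATURE_NAMES = {
    "glcm": [
        "Contrast", "ClusterProminence", "ClusterShade", "JointEnergy",
        "JointEntropy", "Idm", "Autocorrelation", "Correlation",
    ],
    "glszm": [
        "SmallAreaEmphasis", "LargeAreaEmphasis", "SizeZoneNonUniformity",
        "GrayLevelNonUniformity", "SmallAreaLowGrayLevelEmphasis",
        "ZoneVariance", "ZonePercentage",
    ],
    "ngtdm": ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"],
}
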