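"""Radiomic feature panel: 841 features per tumor.

The panel consists of 105 features computed on the original image — 13 shape,
18 first-order, 23 GLCM, 14 GLDM, 16 GLRLM, 16 GLSZM and 5 NGTDM features —
plus the 92 non-shape features recomputed on each of the 8 sub-bands of a
single-level undecimated separable 3-D wavelet transform (every combination
of a low/high pass filter per axis), 105 + 8 x 92 = 841 in total.

Feature definitions follow the IBSI reference nomenclature.  Texture matrices
are built on fixed-bin-width discretized gray levels (see
:func:`radsurv.imaging.discretize`); GLCM and GLRLM aggregate over the 13
unique 3-D directions at distance 1 by computing each feature per direction
and averaging; GLSZM zones and GLDM dependencies use 26-connectivity.

Degenerate regions are handled explicitly: correlation-type GLCM features on
a constant region return the documented sentinel value 1 (Imc1/Imc2 return
0), and single-voxel regions yield NaN for all matrix features rather than
raising mid-pipeline.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import marching_cubes, mesh_surface_area

from .imaging import DiscretizedROI, ImageVolume, discretize, resample_isotropic

_EPS = np.spacing(1.0)

# ---------------------------------------------------------------------------
# panel layout
# ---------------------------------------------------------------------------

WAVELET_BANDS = ["".join(c) for c in itertools.product("LH", repeat=3)]

SHAPE_FEATURES = [
    "MeshVolume", "SurfaceArea", "SurfaceVolumeRatio", "Sphericity",
    "MajorAxisLength", "MinorAxisLength", "LeastAxisLength",
    "Elongation", "Flatness",
    "Maximum3DDiameter", "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow",
]
FIRSTORDER_FEATURES = [
    "Energy", "TotalEnergy", "Entropy", "Minimum", "Percentile10",
    "Percentile90", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
]
GLCM_FEATURES = [
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumEntropy", "SumSquares",
]
GLDM_FEATURES = [
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
]
GLRLM_FEATURES = [
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
]
GLSZM_FEATURES = [
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
]
NGTDM_FEATURES = ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]

CLASS_FEATURES = {
    "shape": SHAPE_FEATURES,
    "firstorder": FIRSTORDER_FEATURES,
    "glcm": GLCM_FEATURES,
    "gldm": GLDM_FEATURES,
    "glrlm": GLRLM_FEATURES,
    "glszm": GLSZM_FEATURES,
    "ngtdm": NGTDM_FEATURES,
}
_TEXTURE_CLASSES = ["glcm", "gldm", "glrlm", "glszm", "ngtdm"]
_NONSHAPE_CLASSES = ["firstorder"] + _TEXTURE_CLASSES


def feature_names() -> list[str]:
    """The 841 panel feature names, in deterministic extraction order."""
    names = []
    for cls in ["shape"] + _NONSHAPE_CLASSES:
        names += [f"original_{cls}_{f}" for f in CLASS_FEATURES[cls]]
    for band in WAVELET_BANDS:
        for cls in _NONSHAPE_CLASSES:
            names += [f"wavelet_{band}_{cls}_{f}" for f in CLASS_FEATURES[cls]]
    return names


def feature_manifest() -> list[dict]:
    """One record per panel feature: name, filter, class, feature."""
    records = []
    for name in feature_names():
        parts = name.split("_")
        if parts[0] == "original":
            filt, cls, feat = "original", parts[1], "_".join(parts[2:])
        else:
            filt, cls, feat = f"wavelet_{parts[1]}", parts[2], "_".join(parts[3:])
        records.append({"name": name, "filter": filt, "feature_class": cls, "feature": feat})
    return records


# 13 unique direction offsets at Chebyshev distance 1 (first nonzero positive)
_DIRECTIONS = [
    d for d in itertools.product((-1, 0, 1), repeat=3)
    if d > (0, 0, 0)
]
assert len(_DIRECTIONS) == 13


# ---------------------------------------------------------------------------
# wavelet filter bank
# ---------------------------------------------------------------------------

def _conv1d_periodic(data: np.ndarray, kernel: np.ndarray, axis: int) -> np.ndarray:
    """Centered discrete convolution with periodic boundary along one axis.

    out[i] = sum_j kernel[j] * data[(i - j + m//2) mod n]  with m = len(kernel).
    """
    return ndimage.convolve1d(data, kernel, axis=axis, mode="wrap", origin=0)


def wavelet_decompose(volume: np.ndarray, wavelet: str = "coif1") -> dict[str, np.ndarray]:
    """Single-level undecimated separable 3-D wavelet transform.

    Returns the 8 sub-bands keyed ``LLL`` ... ``HHH``; letter k applies the
    low (L) or high (H) pass decomposition filter along axis k.  Outputs stay
    on the input grid (no decimation); boundaries are periodic.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 3:
        raise ValueError("expected a 3-D volume")
    wav = pywt.Wavelet(wavelet)
    lo = np.asarray(wav.dec_lo, dtype=np.float64)
    hi = np.asarray(wav.dec_hi, dtype=np.float64)
    if min(volume.shape) < len(lo):
        raise ValueError(
            f"volume shape {volume.shape} smaller than filter length {len(lo)}"
        )
    kernels = {"L": lo, "H": hi}
    # factor the separable transform: filter axis 0 once per letter, reuse
    ax0 = {c: _conv1d_periodic(volume, kernels[c], 0) for c in "LH"}
    out: dict[str, np.ndarray] = {}
    for c0 in "LH":
        ax01 = {c: _conv1d_periodic(ax0[c0], kernels[c], 1) for c in "LH"}
        for c1 in "LH":
            for c2 in "LH":
                out[c0 + c1 + c2] = _conv1d_periodic(ax01[c1], kernels[c2], 2)
    return {band: out[band] for band in WAVELET_BANDS}


# ---------------------------------------------------------------------------
# first order
# ---------------------------------------------------------------------------

def firstorder_features(
    volume: np.ndarray,
    mask: np.ndarray,
    bin_width: float = 25.0,
    voxel_volume_mm3: float = 1.0,
) -> dict[str, float]:
    """18 first-order statistics of the masked intensities.

    Entropy and Uniformity are computed on the fixed-bin-width histogram;
    everything else uses the continuous intensities.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    x = np.asarray(volume, dtype=np.float64)[mask]
    n = x.size
    mean = float(x.mean())
    var = float(x.var())
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    hist = np.bincount(np.floor((x - x.min()) / bin_width).astype(np.int64))
    p = hist[hist > 0] / n
    if var > 0:
        m2 = var
        skew = float(np.mean((x - mean) ** 3) / m2 ** 1.5)
        kurt = float(np.mean((x - mean) ** 4) / m2 ** 2)
    else:
        skew, kurt = 0.0, 0.0
    return {
        "Energy": float(np.sum(x ** 2)),
        "TotalEnergy": float(voxel_volume_mm3 * np.sum(x ** 2)),
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation": float(np.mean(np.abs(robust - robust.mean()))) if robust.size else 0.0,
        "RootMeanSquared": float(np.sqrt(np.mean(x ** 2))),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float(np.sum(p ** 2)),
    }


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------

def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 400:
        try:
            points = points[ConvexHull(points).vertices]
        except QhullError:
            pass
    d2 = np.sum((points[:, None, :] - points[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def shape_features(mask: np.ndarray, spacing_mm: tuple[float, float, float]) -> dict[str, float]:
    """13 shape descriptors from the binary mask and its triangulated surface.

    The surface mesh comes from marching cubes on the zero-padded mask after
    a light Gaussian anti-aliasing (sigma 0.6 voxels) that suppresses the
    staircase-artifact inflation of surface area on digitized solids; mesh
    volume uses the divergence theorem over signed tetrahedra.  Axis lengths
    derive from the PCA eigenvalues of the physical voxel-center coordinates
    (length = 4 * sqrt(eigenvalue), the enclosing-ellipsoid convention).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    spacing = np.asarray(spacing_mm, dtype=float)
    padded = ndimage.gaussian_filter(np.pad(mask, 1).astype(np.float64), 0.6)
    if padded.max() <= 0.5:  # tiny mask smoothed below threshold
        padded = np.pad(mask, 1).astype(np.float64)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    area = float(mesh_surface_area(verts, faces))
    tri = verts[faces]
    vol = float(abs(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0))
    sphericity = (36.0 * np.pi * vol ** 2) ** (1.0 / 3.0) / area if area > 0 else 0.0

    coords = np.argwhere(mask) * spacing
    if len(coords) > 1:
        eig = np.sort(np.linalg.eigvalsh(np.cov(coords.T)))[::-1]
        eig = np.clip(eig, 0.0, None)
    else:
        eig = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()
    elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0
    flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 1.0

    # boundary voxels: masked voxels with at least one 6-neighbor outside
    eroded = ndimage.binary_erosion(mask)
    boundary = np.argwhere(mask & ~eroded) * spacing
    if len(boundary) == 0:
        boundary = coords
    max3d = _max_pairwise(boundary)

    def max2d(drop_axis: int) -> float:
        keep = [a for a in range(3) if a != drop_axis]
        best = 0.0
        vox = np.argwhere(mask & ~eroded)
        if len(vox) == 0:
            vox = np.argwhere(mask)
        for idx in np.unique(vox[:, drop_axis]):
            pts = vox[vox[:, drop_axis] == idx][:, keep] * spacing[keep]
            best = max(best, _max_pairwise(pts))
        return best

    return {
        "MeshVolume": vol,
        "SurfaceArea": area,
        "SurfaceVolumeRatio": area / vol if vol > 0 else np.nan,
        "Sphericity": sphericity,
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "LeastAxisLength": least,
        "Elongation": elongation,
        "Flatness": flatness,
        "Maximum3DDiameter": max3d,
        "Maximum2DDiameterSlice": max2d(2),   # in-plane for fixed axis 3
        "Maximum2DDiameterColumn": max2d(1),
        "Maximum2DDiameterRow": max2d(0),
    }


# ---------------------------------------------------------------------------
# texture matrices
# ---------------------------------------------------------------------------

def _nan_features(cls: str) -> dict[str, float]:
    return {f: float("nan") for f in CLASS_FEATURES[cls]}


def _shifted_pairs(levels: np.ndarray, d: tuple[int, int, int]):
    """Level values of all in-volume voxel pairs separated by offset d."""
    src = tuple(slice(max(0, -dd), levels.shape[k] - max(0, dd)) for k, dd in enumerate(d))
    dst = tuple(slice(max(0, dd), levels.shape[k] + min(0, dd)) for k, dd in enumerate(d))
    return levels[src], levels[dst]


def glcm_features(roi: DiscretizedROI) -> dict[str, float]:
    """23 gray-level co-occurrence features, averaged over the 13 directions.

    Each direction's co-occurrence matrix is symmetrized and normalized, the
    feature is evaluated per direction, and directions are averaged
    (directions with no voxel pair are excluded from the average).
    """
    levels = roi.levels
    ng = roi.n_levels
    if int((levels > 0).sum()) < 2:
        return _nan_features("glcm")
    mats = []
    for d in _DIRECTIONS:
        a, b = _shifted_pairs(levels, d)
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        counts = np.bincount(
            ((a[valid] - 1) * ng + (b[valid] - 1)).ravel(), minlength=ng * ng
        ).reshape(ng, ng).astype(np.float64)
        counts = counts + counts.T
        mats.append(counts / counts.sum())
    if not mats:
        return _nan_features("glcm")
    return _glcm_all(np.stack(mats), ng)


_GLCM_IDX_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}
_GLCM_ONEHOT_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _glcm_margin_indices(ng: int) -> tuple[np.ndarray, np.ndarray]:
    if ng not in _GLCM_IDX_CACHE:
        a = np.arange(ng)
        _GLCM_IDX_CACHE[ng] = (
            (a[:, None] + a[None, :]).ravel(),
            np.abs(a[:, None] - a[None, :]).ravel(),
        )
    return _GLCM_IDX_CACHE[ng]


def _glcm_margin_onehots(ng: int) -> tuple[np.ndarray, np.ndarray]:
    if ng not in _GLCM_ONEHOT_CACHE:
        sum_idx, diff_idx = _glcm_margin_indices(ng)
        onehot_sum = np.zeros((ng * ng, 2 * ng - 1))
        onehot_sum[np.arange(ng * ng), sum_idx] = 1.0
        onehot_diff = np.zeros((ng * ng, ng))
        onehot_diff[np.arange(ng * ng), diff_idx] = 1.0
        _GLCM_ONEHOT_CACHE[ng] = (onehot_sum, onehot_diff)
    return _GLCM_ONEHOT_CACHE[ng]


def _glcm_all(p: np.ndarray, ng: int) -> dict[str, float]:
    """Evaluate the 23 GLCM features on a (D, ng, ng) stack of normalized
    matrices, one per direction, and average over D."""
    i_idx = np.arange(1, ng + 1, dtype=np.float64)
    px = p.sum(axis=2)                       # (D, ng)
    mu = (i_idx * px).sum(axis=1)            # (D,)
    sigma2 = ((i_idx[None, :] - mu[:, None]) ** 2 * px).sum(axis=1)
    ii = i_idx[:, None]
    jj = i_idx[None, :]
    diff = np.abs(ii - jj)                   # (ng, ng)

    pflat = p.reshape(p.shape[0], -1)
    onehot_sum, onehot_diff = _glcm_margin_onehots(ng)
    pxy_sum = pflat @ onehot_sum             # (D, 2ng-1)
    pxy_diff = pflat @ onehot_diff           # (D, ng)
    kdiff = np.arange(0, ng, dtype=np.float64)
    da = (kdiff * pxy_diff).sum(axis=1)

    hx = -(px * np.log2(px + _EPS)).sum(axis=1)
    hxy = -(p * np.log2(p + _EPS)).sum(axis=(1, 2))
    pxpy = px[:, :, None] * px[:, None, :]
    hxy1 = -(p * np.log2(pxpy + _EPS)).sum(axis=(1, 2))
    hxy2 = -(pxpy * np.log2(pxpy + _EPS)).sum(axis=(1, 2))

    acor = (ii * jj * p).sum(axis=(1, 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(sigma2 > 0, (acor - mu ** 2) / np.where(sigma2 > 0, sigma2, 1.0), 1.0)
        imc1 = np.where(hx > 0, (hxy - hxy1) / np.where(hx > 0, hx, 1.0), 0.0)
    imc2 = np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0, None))

    if ng > 1:
        with np.errstate(divide="ignore", invalid="ignore"):
            a = p / px[:, :, None]
            b = p / px[:, None, :]
            q = np.nan_to_num(a) @ np.nan_to_num(b).transpose(0, 2, 1)
        eig = np.sort(np.real(np.linalg.eigvals(q)), axis=1)
        mcc = np.sqrt(np.clip(eig[:, -2], 0.0, None))
    else:
        mcc = np.ones(p.shape[0])

    cplus = ii + jj - 2 * mu[:, None, None]  # (D, ng, ng)
    inv_var = np.where(diff > 0, 1.0 / np.where(diff > 0, diff, 1.0) ** 2, 0.0)
    out = {
        "Autocorrelation": acor,
        "ClusterProminence": (cplus ** 4 * p).sum(axis=(1, 2)),
        "ClusterShade": (cplus ** 3 * p).sum(axis=(1, 2)),
        "ClusterTendency": (cplus ** 2 * p).sum(axis=(1, 2)),
        "Contrast": ((ii - jj) ** 2 * p).sum(axis=(1, 2)),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": -(pxy_diff * np.log2(pxy_diff + _EPS)).sum(axis=1),
        "DifferenceVariance": ((kdiff[None, :] - da[:, None]) ** 2 * pxy_diff).sum(axis=1),
        "Id": (p / (1.0 + diff)).sum(axis=(1, 2)),
        "Idm": (p / (1.0 + diff ** 2)).sum(axis=(1, 2)),
        "Idmn": (p / (1.0 + (diff / ng) ** 2)).sum(axis=(1, 2)),
        "Idn": (p / (1.0 + diff / ng)).sum(axis=(1, 2)),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": (p * inv_var).sum(axis=(1, 2)),
        "JointAverage": mu,
        "JointEnergy": (p ** 2).sum(axis=(1, 2)),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": p.max(axis=(1, 2)),
        "SumEntropy": -(pxy_sum * np.log2(pxy_sum + _EPS)).sum(axis=1),
        "SumSquares": sigma2,
    }
    return {k: float(np.mean(v)) for k, v in out.items()}


def _sz_style_features(mat: np.ndarray, np_voxels: int, names: dict[str, str]) -> dict[str, float]:
    """Shared run/zone/dependence feature formulas.

    ``mat[..., i, s]`` counts runs/zones/dependencies of gray level i+1 and
    size s+1; an optional leading axis holds directions, which are averaged.
    ``names`` maps generic keys to the class-specific feature names.
    """
    mat = np.asarray(mat, dtype=np.float64)
    if mat.ndim == 2:
        mat = mat[None]
    nr = mat.sum(axis=(1, 2))                               # (D,)
    i = np.arange(1, mat.shape[1] + 1, dtype=np.float64)[:, None]
    s = np.arange(1, mat.shape[2] + 1, dtype=np.float64)[None, :]
    p = mat / nr[:, None, None]
    mu_i = (i * p).sum(axis=(1, 2))
    mu_s = (s * p).sum(axis=(1, 2))
    pg = mat.sum(axis=2)                                    # (D, Ng)
    ps = mat.sum(axis=1)                                    # (D, S)
    plog = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    out = {
        "small": (mat / s ** 2).sum(axis=(1, 2)) / nr,
        "large": (mat * s ** 2).sum(axis=(1, 2)) / nr,
        "gln": (pg ** 2).sum(axis=1) / nr,
        "glnn": (pg ** 2).sum(axis=1) / nr ** 2,
        "szn": (ps ** 2).sum(axis=1) / nr,
        "sznn": (ps ** 2).sum(axis=1) / nr ** 2,
        "pct": nr / np_voxels,
        "glv": ((i - mu_i[:, None, None]) ** 2 * p).sum(axis=(1, 2)),
        "szv": ((s - mu_s[:, None, None]) ** 2 * p).sum(axis=(1, 2)),
        "entropy": -plog.sum(axis=(1, 2)),
        "lgl": (mat / i ** 2).sum(axis=(1, 2)) / nr,
        "hgl": (mat * i ** 2).sum(axis=(1, 2)) / nr,
        "slgl": (mat / (i ** 2 * s ** 2)).sum(axis=(1, 2)) / nr,
        "shgl": (mat * i ** 2 / s ** 2).sum(axis=(1, 2)) / nr,
        "llgl": (mat * s ** 2 / i ** 2).sum(axis=(1, 2)) / nr,
        "lhgl": (mat * i ** 2 * s ** 2).sum(axis=(1, 2)) / nr,
    }
    return {names[k]: float(np.mean(out[k])) for k in names}


_GLRLM_KEYMAP = {
    "small": "ShortRunEmphasis", "large": "LongRunEmphasis",
    "gln": "GrayLevelNonUniformity", "glnn": "GrayLevelNonUniformityNormalized",
    "szn": "RunLengthNonUniformity", "sznn": "RunLengthNonUniformityNormalized",
    "pct": "RunPercentage", "glv": "GrayLevelVariance", "szv": "RunVariance",
    "entropy": "RunEntropy", "lgl": "LowGrayLevelRunEmphasis",
    "hgl": "HighGrayLevelRunEmphasis", "slgl": "ShortRunLowGrayLevelEmphasis",
    "shgl": "ShortRunHighGrayLevelEmphasis", "llgl": "LongRunLowGrayLevelEmphasis",
    "lhgl": "LongRunHighGrayLevelEmphasis",
}
_GLSZM_KEYMAP = {
    "small": "SmallAreaEmphasis", "large": "LargeAreaEmphasis",
    "gln": "GrayLevelNonUniformity", "glnn": "GrayLevelNonUniformityNormalized",
    "szn": "SizeZoneNonUniformity", "sznn": "SizeZoneNonUniformityNormalized",
    "pct": "ZonePercentage", "glv": "GrayLevelVariance", "szv": "ZoneVariance",
    "entropy": "ZoneEntropy", "lgl": "LowGrayLevelZoneEmphasis",
    "hgl": "HighGrayLevelZoneEmphasis", "slgl": "SmallAreaLowGrayLevelEmphasis",
    "shgl": "SmallAreaHighGrayLevelEmphasis", "llgl": "LargeAreaLowGrayLevelEmphasis",
    "lhgl": "LargeAreaHighGrayLevelEmphasis",
}


def glrlm_matrix(levels: np.ndarray, direction: tuple[int, int, int], n_levels: int) -> np.ndarray:
    """Run-length matrix for one direction (rows: level, cols: run length)."""
    shape = levels.shape
    max_run = int(sum(abs(dd) * (n - 1) for dd, n in zip(direction, shape))) + 1
    mask = levels > 0

    def shift(arr, d, fill=0):
        out = np.full_like(arr, fill)
        src = tuple(slice(max(0, -dd), arr.shape[k] - max(0, dd)) for k, dd in enumerate(d))
        dst = tuple(slice(max(0, dd), arr.shape[k] + min(0, dd)) for k, dd in enumerate(d))
        out[dst] = arr[src]
        return out

    prev = shift(levels, direction)
    same_prev = mask & (prev == levels) & (prev > 0)
    nxt = shift(levels, tuple(-dd for dd in direction))
    same_next = mask & (nxt == levels) & (nxt > 0)

    # run length ending at each voxel: fixed point of C = same_prev ? C<<d + 1 : 1
    runlen = mask.astype(np.int32)
    for _ in range(max_run):
        upd = np.where(same_prev, shift(runlen, direction) + 1, mask.astype(np.int32))
        if np.array_equal(upd, runlen):
            break
        runlen = upd
    ends = mask & ~same_next
    g = levels[ends] - 1
    r = runlen[ends] - 1
    mat = np.zeros((n_levels, max(1, int(r.max()) + 1) if r.size else 1), dtype=np.float64)
    np.add.at(mat, (g, r), 1.0)
    return mat


def glrlm_features(roi: DiscretizedROI) -> dict[str, float]:
    """16 run-length features, averaged over the 13 directions."""
    levels = roi.levels
    np_vox = int((levels > 0).sum())
    if np_vox < 2:
        return _nan_features("glrlm")
    mats = [glrlm_matrix(levels, d, roi.n_levels) for d in _DIRECTIONS]
    width = max(m.shape[1] for m in mats)
    stack = np.zeros((len(mats), roi.n_levels, width))
    for k, m in enumerate(mats):
        stack[k, :, : m.shape[1]] = m
    return _sz_style_features(stack, np_vox, _GLRLM_KEYMAP)


_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone matrix: 26-connected zones of equal gray level."""
    zones: list[tuple[int, int]] = []
    for g in range(1, n_levels + 1):
        binary = levels == g
        if not binary.any():
            continue
        lab, nlab = ndimage.label(binary, structure=_STRUCT26)
        sizes = np.bincount(lab.ravel())[1:]
        zones += [(g, int(s)) for s in sizes]
    max_size = max(s for _, s in zones)
    mat = np.zeros((n_levels, max_size), dtype=np.float64)
    for g, s in zones:
        mat[g - 1, s - 1] += 1.0
    return mat


def glszm_features(roi: DiscretizedROI) -> dict[str, float]:
    """16 size-zone features (single matrix, no direction averaging)."""
    np_vox = int((roi.levels > 0).sum())
    if np_vox < 2:
        return _nan_features("glszm")
    mat = glszm_matrix(roi.levels, roi.n_levels)
    return _sz_style_features(mat, np_vox, _GLSZM_KEYMAP)


def gldm_matrix(levels: np.ndarray, n_levels: int, alpha: int = 0) -> np.ndarray:
    """Dependence matrix: dependence of a voxel = 1 + number of 26-neighbors
    inside the mask whose level differs by at most ``alpha``."""
    mask = levels > 0
    dep = np.zeros(levels.shape, dtype=np.int32)
    for d in _DIRECTIONS:
        for dd in (d, tuple(-x for x in d)):
            a, b = _shifted_pairs(levels, dd)
            src = tuple(slice(max(0, -x), levels.shape[k] - max(0, x)) for k, x in enumerate(dd))
            ok = (a > 0) & (b > 0) & (np.abs(a - b) <= alpha)
            dep[src] += ok
    dep = dep + 1
    g = levels[mask] - 1
    j = dep[mask] - 1
    mat = np.zeros((n_levels, int(j.max()) + 1), dtype=np.float64)
    np.add.at(mat, (g, j), 1.0)
    return mat


_GLDM_KEYMAP = {
    "small": "SmallDependenceEmphasis", "large": "LargeDependenceEmphasis",
    "gln": "GrayLevelNonUniformity", "szn": "DependenceNonUniformity",
    "sznn": "DependenceNonUniformityNormalized", "glv": "GrayLevelVariance",
    "szv": "DependenceVariance", "entropy": "DependenceEntropy",
    "lgl": "LowGrayLevelEmphasis", "hgl": "HighGrayLevelEmphasis",
    "slgl": "SmallDependenceLowGrayLevelEmphasis",
    "shgl": "SmallDependenceHighGrayLevelEmphasis",
    "llgl": "LargeDependenceLowGrayLevelEmphasis",
    "lhgl": "LargeDependenceHighGrayLevelEmphasis",
}


def gldm_features(roi: DiscretizedROI, alpha: int = 0) -> dict[str, float]:
    """14 gray-level dependence features (26-connectivity, tolerance alpha)."""
    np_vox = int((roi.levels > 0).sum())
    if np_vox < 2:
        return _nan_features("gldm")
    mat = gldm_matrix(roi.levels, roi.n_levels, alpha=alpha)
    return _sz_style_features(mat, np_vox, _GLDM_KEYMAP)


def ngtdm_features(roi: DiscretizedROI) -> dict[str, float]:
    """5 neighboring-gray-tone-difference features.

    For each voxel the average level of its masked 26-neighbors is computed
    (voxels with no masked neighbor contribute zero difference), s_i sums the
    absolute differences per level.
    """
    levels = roi.levels
    mask = levels > 0
    np_vox = int(mask.sum())
    if np_vox < 2:
        return _nan_features("ngtdm")
    ng = roi.n_levels
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0
    neigh_sum = ndimage.convolve((levels * mask).astype(np.float64), kernel, mode="constant")
    neigh_cnt = ndimage.convolve(mask.astype(np.float64), kernel, mode="constant")
    with np.errstate(divide="ignore", invalid="ignore"):
        neigh_avg = np.where(neigh_cnt > 0, neigh_sum / neigh_cnt, 0.0)
    diffs = np.where(mask & (neigh_cnt > 0), np.abs(levels - neigh_avg), 0.0)
    s = np.zeros(ng)
    n = np.zeros(ng)
    for g in range(1, ng + 1):
        sel = mask & (levels == g)
        n[g - 1] = sel.sum()
        s[g - 1] = diffs[sel].sum()
    p = n / np_vox
    present = p > 0
    ngp = int(present.sum())
    ivals = np.arange(1, ng + 1, dtype=np.float64)

    sum_ps = float(np.sum(p * s))
    coarseness = 1.0 / sum_ps if sum_ps > 0 else 1e6

    if ngp > 1:
        pi = p[present][:, None]
        pj = p[present][None, :]
        iv = ivals[present][:, None]
        jv = ivals[present][None, :]
        si = s[present][:, None]
        sj = s[present][None, :]
        contrast = float(np.sum(pi * pj * (iv - jv) ** 2) / (ngp * (ngp - 1)) * np.sum(s) / np_vox)
        denom = float(np.sum(np.abs(iv * pi - jv * pj)))
        busyness = sum_ps / denom if denom > 0 else 0.0
        complexity = float(np.sum(np.abs(iv - jv) * (pi * si + pj * sj) / (pi + pj)) / np_vox)
        strength = float(np.sum((pi + pj) * (iv - jv) ** 2) / np.sum(s)) if np.sum(s) > 0 else 0.0
    else:
        contrast, busyness, complexity, strength = 0.0, 0.0, 0.0, 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


# ---------------------------------------------------------------------------
# full panel
# ---------------------------------------------------------------------------

@dataclass
class ExtractionConfig:
    """Knobs of the extraction pipeline.

    voxel_size_mm : isotropic grid for resampling before extraction.
    bin_width : fixed bin width of gray-level discretization (intensity units);
        each wavelet band is re-binned against its own masked minimum.
    wavelet : PyWavelets name of the decomposition filter bank.
    resample : skip resampling entirely when False (input grid is used as-is).
    interpolation : image interpolator ("linear" | "nearest" | "bspline"); the
        mask is always nearest-neighbor.
    wavelet_bin_width : bin width used on the wavelet sub-bands (each band is
        referenced to its own masked minimum); None reuses ``bin_width``.
    pad_voxels : margin kept around the mask bounding box so that the wavelet
        kernels see real context.
    """

    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    bin_width: float = 25.0
    wavelet: str = "coif1"
    resample: bool = True
    interpolation: str = "linear"
    wavelet_bin_width: float | None = None
    pad_voxels: int = 4


@dataclass
class FeatureVector:
    """A named 841-entry feature vector for one patient."""

    patient_id: str
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = feature_names()
        if list(self.values.keys()) != expected:
            raise ValueError(
                f"feature vector must hold exactly the {len(expected)} panel features in order"
            )


def _texture_block(roi: DiscretizedROI) -> dict[str, float]:
    out = {}
    for cls, fn in (
        ("glcm", glcm_features),
        ("gldm", gldm_features),
        ("glrlm", glrlm_features),
        ("glszm", glszm_features),
        ("ngtdm", ngtdm_features),
    ):
        feats = fn(roi)
        out.update({f"{cls}_{k}": v for k, v in feats.items()})
    return out


def extract_all(
    volume: ImageVolume,
    mask: ImageVolume,
    config: ExtractionConfig | None = None,
    patient_id: str = "",
) -> FeatureVector:
    """Extract the full 841-feature panel from one volume/mask pair.

    Pipeline: isotropic resampling -> original-image features (105) ->
    undecimated wavelet decomposition -> 92 non-shape features per sub-band
    (8 x 92 = 736).  Failed feature classes propagate as NaN entries, never
    as dropped columns.
    """
    config = config or ExtractionConfig()
    if config.resample:
        volume, mask = resample_isotropic(
            volume, mask, config.voxel_size_mm,
            interpolation=config.interpolation, patient_id=patient_id or None,
        )
    m = np.asarray(mask.data, dtype=bool)
    if not m.any():
        raise ValueError("mask is empty")
    spacing = volume.spacing_mm
    voxel_volume = float(np.prod(spacing))

    # crop to the mask bounding box plus padding; wavelets see the context
    idx = np.argwhere(m)
    lo = np.maximum(idx.min(axis=0) - config.pad_voxels, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + config.pad_voxels, m.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    img = np.asarray(volume.data, dtype=np.float64)[sl]
    msk = m[sl]

    wav = pywt.Wavelet(config.wavelet)
    min_len = len(wav.dec_lo)
    if min(img.shape) < min_len:
        pad = [(0, max(0, min_len - s)) for s in img.shape]
        img = np.pad(img, pad, mode="edge")
        msk = np.pad(msk, pad, mode="constant")

    values: dict[str, float] = {}
    for k, v in shape_features(m, spacing).items():
        values[f"original_shape_{k}"] = v
    for k, v in firstorder_features(img, msk, config.bin_width, voxel_volume).items():
        values[f"original_firstorder_{k}"] = v
    roi = discretize(img, msk, config.bin_width)
    for k, v in _texture_block(roi).items():
        values[f"original_{k}"] = v

    wav_bw = config.wavelet_bin_width or config.bin_width
    bands = wavelet_decompose(img, config.wavelet)
    for band in WAVELET_BANDS:
        data = bands[band]
        broi = discretize(data, msk, wav_bw)
        fo = firstorder_features(data, msk, wav_bw, voxel_volume)
        for k, v in fo.items():
            values[f"wavelet_{band}_firstorder_{k}"] = v
        for k, v in _texture_block(broi).items():
            values[f"wavelet_{band}_{k}"] = v
    return FeatureVector(patient_id=patient_id, values=values)
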