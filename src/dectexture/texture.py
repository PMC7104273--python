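"""Multiparametric 2D texture features for CT ROIs.

Implements the 41-feature panel used for thyroid-nodule characterization on
virtual monochromatic images: 12 first-order histogram features, 5 gray-level
co-occurrence matrix (GLCM) features, 11 gray-level run-length (GLRL)
features, 4 gray-level gradient matrix (GLGM) features and 9 Laws texture
energy features.  Features are computed per axial slice on the mask-restricted
region, then averaged (unweighted) across usable slices of the ROI.

Conventions
-----------
* GLCM/GLRL operate on intensities quantized to ``n_levels`` gray levels
  (default 64) over the per-slice ROI min-max range; histogram, GLGM and Laws
  operate on raw HU.
* GLCM: distance 1, four directions (0/45/90/135 degrees), co-occurrences
  accumulated only between pairs of in-mask voxels, matrix symmetrized and
  normalized per direction, features averaged over directions.  Entropy uses
  log base 2.
* GLRL: maximal constant-level runs restricted to the mask (runs break at
  mask boundaries), same four directions, the eleven
  Galloway/Chu/Dasarathy features averaged over directions.  Gray levels are
  indexed from 1 in the low/high gray-level emphasis weights.
* GLGM: gradient magnitude by central differences at interior voxels (all
  four 4-neighbours in the mask), per-voxel spacing applied; mean (MGR),
  variance (VGR), skewness and kurtosis of the magnitudes.
* Laws: the nine 3x3 kernels from outer products of L3=[1,2,1] (level),
  E3=[-1,0,1] (edge) and S3=[-1,2,-1] (spot), applied to mean-subtracted ROI
  intensities; each feature is the mean absolute response over voxels whose
  full 3x3 support lies inside the mask.
* Skewness and kurtosis use population (biased) moments; kurtosis is
  non-excess (a Gaussian has kurtosis 3).  Degenerate inputs take their
  defined limits instead of NaN: constant slices give GLCM contrast 0,
  energy 1, entropy 0, homogeneity 1, correlation 0; zero-variance gradient
  distributions give skewness and kurtosis 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InputError, RoiError
from .io import RoiMask, VmiStack

HISTOGRAM_FEATURES = (
    "mean", "median", "sd", "variance", "skewness", "kurtosis",
    "energy", "entropy", "min", "max", "range", "iqr",
)
GLCM_FEATURES = ("contrast", "correlation", "energy", "homogeneity", "entropy")
GLRL_FEATURES = (
    "SRE", "LRE", "GLN", "RLN", "RP",
    "LGRE", "HGRE", "SRLGE", "SRHGE", "LRLGE", "LRHGE",
)
GLGM_FEATURES = ("MGR", "VGR", "skewness", "kurtosis")
LAWS_FEATURES = ("L3L3", "L3E3", "L3S3", "E3L3", "E3E3", "E3S3", "S3L3", "S3E3", "S3S3")

FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"histogram.{n}" for n in HISTOGRAM_FEATURES)
    + tuple(f"glcm.{n}" for n in GLCM_FEATURES)
    + tuple(f"glrl.{n}" for n in GLRL_FEATURES)
    + tuple(f"glgm.{n}" for n in GLGM_FEATURES)
    + tuple(f"laws.{n}" for n in LAWS_FEATURES)
)
assert len(FEATURE_NAMES) == 41

FAMILY_COUNTS = {"histogram": 12, "glcm": 5, "glrl": 11, "glgm": 4, "laws": 9}

# distance-1 offsets (drow, dcol) for 0, 45, 90, 135 degrees
DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

_L3 = np.array([1.0, 2.0, 1.0])
_E3 = np.array([-1.0, 0.0, 1.0])
_S3 = np.array([-1.0, 2.0, -1.0])
_LAWS_KERNELS = {  # name -> outer(row_kernel, col_kernel)
    f"{a}3{b}3": np.outer(v, w)
    for (a, v) in (("L", _L3), ("E", _E3), ("S", _S3))
    for (b, w) in (("L", _L3), ("E", _E3), ("S", _S3))
}


@dataclass(frozen=True)
class QuantizationSpec:
    """Gray-level quantization for GLCM/GLRL.

    ``range_mode='roi-min-max'`` rescales each slice's ROI to its own min-max
    range (the default; makes the matrices invariant to additive HU shifts);
    ``'fixed'`` uses the given window bounds for every slice.
    """

    n_levels: int = 64
    range_mode: str = "roi-min-max"
    fixed_bounds: tuple[float, float] | None = None

    def __post_init__(self):
        if self.n_levels < 2:
            raise InputError(f"n_levels must be >= 2, got {self.n_levels}")
        if self.range_mode not in ("roi-min-max", "fixed"):
            raise InputError(f"unknown range_mode {self.range_mode!r}")
        if self.range_mode == "fixed":
            if self.fixed_bounds is None or self.fixed_bounds[0] >= self.fixed_bounds[1]:
                raise InputError("fixed range_mode needs ordered fixed_bounds")


@dataclass(frozen=True)
class FeatureVector:
    """The 41 named texture features for one (nodule, energy) pair."""

    nodule_id: str
    energy_keV: float
    values: Mapping[str, float]
    n_slices_used: int = 1

    def __post_init__(self):
        missing = set(FEATURE_NAMES) - set(self.values)
        if missing:
            raise InputError(f"feature vector missing {sorted(missing)}")
        object.__setattr__(self, "values", dict(self.values))

    def as_series(self) -> pd.Series:
        return pd.Series({k: self.values[k] for k in FEATURE_NAMES},
                         name=(self.nodule_id, self.energy_keV))


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------

def quantize(image: np.ndarray, mask: np.ndarray,
             spec: QuantizationSpec = QuantizationSpec()) -> np.ndarray:
    """Map masked HU values to integer levels in [0, n_levels-1].

    The mapping is monotone in HU; a constant ROI maps to level 0.  Values
    outside the window (fixed mode) are clipped into range.  Voxels outside
    the mask are set to -1.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise RoiError("cannot quantize an empty ROI")
    vals = image[mask]
    if spec.range_mode == "fixed":
        lo, hi = spec.fixed_bounds
    else:
        lo, hi = float(vals.min()), float(vals.max())
    levels = np.full(image.shape, -1, dtype=np.int64)
    if hi == lo:
        levels[mask] = 0
        return levels
    scaled = np.floor((vals - lo) / (hi - lo) * spec.n_levels).astype(np.int64)
    levels[mask] = np.clip(scaled, 0, spec.n_levels - 1)
    return levels


# ---------------------------------------------------------------------------
# histogram (first-order) features
# ---------------------------------------------------------------------------

def _population_skew_kurt(x: np.ndarray) -> tuple[float, float]:
    m = x.mean()
    v = ((x - m) ** 2).mean()
    if v == 0:
        return 0.0, 0.0
    skew = (((x - m) ** 3).mean()) / v ** 1.5
    kurt = (((x - m) ** 4).mean()) / v ** 2
    return float(skew), float(kurt)


def histogram_features(values: np.ndarray, n_bins: int = 256) -> dict[str, float]:
    """Twelve first-order statistics of the raw (unquantized) HU values."""
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise RoiError("histogram features need at least one value")
    skew, kurt = _population_skew_kurt(x)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        p = np.array([1.0])
    else:
        counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
        p = counts[counts > 0] / x.size
    q25, q75 = np.percentile(x, [25, 75])
    return {
        "mean": float(x.mean()),
        "median": float(np.median(x)),
        "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
        "variance": float(x.var(ddof=1)) if x.size > 1 else 0.0,
        "skewness": skew,
        "kurtosis": kurt,
        "energy": float((p ** 2).sum()),
        "entropy": float(-(p * np.log2(p)).sum()),
        "min": lo,
        "max": hi,
        "range": hi - lo,
        "iqr": float(q75 - q25),
    }


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int,
                offset: tuple[int, int], distance: int = 1) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix for one offset.

    Counts pairs (p, p+offset*distance) with both voxels in the mask.
    Returns an all-zero matrix when no pair exists.
    """
    dr, dc = offset[0] * distance, offset[1] * distance
    nrow, ncol = levels.shape
    r0 = slice(max(0, -dr), min(nrow, nrow - dr))
    c0 = slice(max(0, -dc), min(ncol, ncol - dc))
    r1 = slice(max(0, dr), min(nrow, nrow + dr))
    c1 = slice(max(0, dc), min(ncol, ncol + dc))
    valid = mask[r0, c0] & mask[r1, c1]
    i = levels[r0, c0][valid]
    j = levels[r1, c1][valid]
    mat = np.zeros((n_levels, n_levels))
    np.add.at(mat, (i, j), 1.0)
    mat = mat + mat.T
    total = mat.sum()
    return mat / total if total > 0 else mat


def _glcm_features_one(p: np.ndarray) -> dict[str, float]:
    n = p.shape[0]
    idx = np.arange(n, dtype=float)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    pi = p.sum(axis=1)
    mu_i = (idx * pi).sum()
    var_i = ((idx - mu_i) ** 2 * pi).sum()
    # symmetric matrix: both marginals coincide
    contrast = ((ii - jj) ** 2 * p).sum()
    if var_i > 0:
        correlation = (((ii - mu_i) * (jj - mu_i) * p).sum()) / var_i
    else:
        correlation = 0.0
    nz = p[p > 0]
    return {
        "contrast": float(contrast),
        "correlation": float(correlation),
        "energy": float((p ** 2).sum()),
        "homogeneity": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "entropy": float(-(nz * np.log2(nz)).sum()),
    }


def glcm_features(levels: np.ndarray, mask: np.ndarray, n_levels: int,
                  distance: int = 1,
                  directions: Sequence[tuple[int, int]] = DIRECTIONS) -> dict[str, float]:
    """Five Haralick-style GLCM features averaged over directions."""
    mask = np.asarray(mask, dtype=bool)
    per_dir = []
    for off in directions:
        mat = glcm_matrix(levels, mask, n_levels, off, distance)
        if mat.sum() > 0:
            per_dir.append(_glcm_features_one(mat))
    if not per_dir:
        raise RoiError("no in-mask voxel pairs at the requested GLCM offsets")
    return {k: float(np.mean([d[k] for d in per_dir])) for k in GLCM_FEATURES}


# ---------------------------------------------------------------------------
# GLRL
# ---------------------------------------------------------------------------

def _lines_along(shape: tuple[int, int], direction: tuple[int, int]):
    """Voxel-index sequences of all maximal lattice lines along a direction."""
    nrow, ncol = shape
    dr, dc = direction
    if (dr, dc) == (0, 1):
        for r in range(nrow):
            yield [(r, c) for c in range(ncol)]
    elif (dr, dc) == (-1, 0):
        for c in range(ncol):
            yield [(r, c) for r in range(nrow)]
    elif (dr, dc) == (-1, 1):  # anti-diagonals, up-right
        for s in range(nrow + ncol - 1):
            line = [(r, s - r) for r in range(nrow - 1, -1, -1) if 0 <= s - r < ncol]
            if line:
                yield line
    elif (dr, dc) == (-1, -1):  # main diagonals traversed up-left
        for s in range(-(ncol - 1), nrow):
            line = [(r, r - s) for r in range(nrow - 1, -1, -1) if 0 <= r - s < ncol]
            if line:
                yield line
    else:
        raise InputError(f"unsupported run direction {direction}")


def glrl_matrix(levels: np.ndarray, mask: np.ndarray,
                n_levels: int, direction: tuple[int, int]) -> np.ndarray:
    """Run-length matrix R[level, run_length-1] for one direction.

    Runs are maximal constant-level segments along the direction, restricted
    to the mask; a gap in the mask terminates the run.
    """
    nrow, ncol = levels.shape
    max_run = max(nrow, ncol)
    R = np.zeros((n_levels, max_run))
    for line in _lines_along(levels.shape, direction):
        run_level, run_len = None, 0
        for (r, c) in line:
            inside = mask[r, c]
            lev = levels[r, c] if inside else None
            if inside and lev == run_level:
                run_len += 1
            else:
                if run_level is not None:
                    R[run_level, run_len - 1] += 1
                run_level, run_len = (lev, 1) if inside else (None, 0)
        if run_level is not None:
            R[run_level, run_len - 1] += 1
    return R


def _glrl_features_one(R: np.ndarray, n_pixels: int) -> dict[str, float]:
    n_levels, max_run = R.shape
    i = np.arange(1, n_levels + 1, dtype=float)[:, None]   # gray index from 1
    j = np.arange(1, max_run + 1, dtype=float)[None, :]
    nr = R.sum()
    if nr == 0:
        raise RoiError("no runs in ROI")
    rl = R.sum(axis=0)  # by run length
    gl = R.sum(axis=1)  # by gray level
    return {
        "SRE": float((R / j ** 2).sum() / nr),
        "LRE": float((R * j ** 2).sum() / nr),
        "GLN": float((gl ** 2).sum() / nr),
        "RLN": float((rl ** 2).sum() / nr),
        "RP": float(nr / n_pixels),
        "LGRE": float((R / i ** 2).sum() / nr),
        "HGRE": float((R * i ** 2).sum() / nr),
        "SRLGE": float((R / (i ** 2 * j ** 2)).sum() / nr),
        "SRHGE": float((R * i ** 2 / j ** 2).sum() / nr),
        "LRLGE": float((R * j ** 2 / i ** 2).sum() / nr),
        "LRHGE": float((R * (i * j) ** 2).sum() / nr),
    }


def glrl_features(levels: np.ndarray, mask: np.ndarray, n_levels: int,
                  directions: Sequence[tuple[int, int]] = DIRECTIONS) -> dict[str, float]:
    """Eleven run-length features averaged over directions."""
    mask = np.asarray(mask, dtype=bool)
    n_pixels = int(mask.sum())
    if n_pixels == 0:
        raise RoiError("empty mask")
    per_dir = [
        _glrl_features_one(glrl_matrix(levels, mask, n_levels, d), n_pixels)
        for d in directions
    ]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in GLRL_FEATURES}


# ---------------------------------------------------------------------------
# GLGM
# ---------------------------------------------------------------------------

def gradient_magnitudes(image: np.ndarray, mask: np.ndarray,
                        spacing: tuple[float, float] = (1.0, 1.0)) -> np.ndarray:
    """Central-difference gradient magnitude at interior mask voxels.

    Interior = voxel and all four 4-neighbours inside the mask, so no
    out-of-ROI intensity leaks into the differences.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    cross = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    interior = ndimage.binary_erosion(mask, structure=cross, border_value=0)
    if not interior.any():
        raise RoiError("ROI has no interior voxel for gradient computation")
    dy, dx = spacing
    rows, cols = np.nonzero(interior)
    gx = (image[rows, cols + 1] - image[rows, cols - 1]) / (2.0 * dx)
    gy = (image[rows + 1, cols] - image[rows - 1, cols]) / (2.0 * dy)
    return np.sqrt(gx ** 2 + gy ** 2)


def glgm_features(image: np.ndarray, mask: np.ndarray,
                  spacing: tuple[float, float] = (1.0, 1.0)) -> dict[str, float]:
    """Mean (MGR), variance (VGR), skewness and kurtosis of gradient magnitudes."""
    g = gradient_magnitudes(image, mask, spacing)
    skew, kurt = _population_skew_kurt(g)
    return {
        "MGR": float(g.mean()),
        "VGR": float(g.var()),
        "skewness": skew,
        "kurtosis": kurt,
    }


# ---------------------------------------------------------------------------
# Laws texture energy
# ---------------------------------------------------------------------------

def laws_features(image: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Mean absolute response of the nine 3x3 Laws kernels over the ROI.

    Intensities are ROI-mean-subtracted first so the pure level kernel (L3L3)
    responds to structure, not to the DC offset.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    support = ndimage.binary_erosion(mask, structure=np.ones((3, 3), bool),
                                     border_value=0)
    if not support.any():
        raise RoiError("ROI has no voxel with full 3x3 support")
    centered = np.where(mask, image - image[mask].mean(), 0.0)
    out = {}
    for name, kernel in _LAWS_KERNELS.items():
        resp = ndimage.correlate(centered, kernel, mode="constant", cval=0.0)
        out[name] = float(np.abs(resp[support]).mean())
    return out


# ---------------------------------------------------------------------------
# per-slice / per-nodule aggregation
# ---------------------------------------------------------------------------

def slice_features(image: np.ndarray, mask: np.ndarray,
                   spec: QuantizationSpec = QuantizationSpec(),
                   spacing: tuple[float, float] = (1.0, 1.0)) -> dict[str, float]:
    """All 41 features for one axial slice."""
    levels = quantize(image, mask, spec)
    out: dict[str, float] = {}
    for k, v in histogram_features(image[np.asarray(mask, bool)]).items():
        out[f"histogram.{k}"] = v
    for k, v in glcm_features(levels, mask, spec.n_levels).items():
        out[f"glcm.{k}"] = v
    for k, v in glrl_features(levels, mask, spec.n_levels).items():
        out[f"glrl.{k}"] = v
    for k, v in glgm_features(image, mask, spacing).items():
        out[f"glgm.{k}"] = v
    for k, v in laws_features(image, mask).items():
        out[f"laws.{k}"] = v
    return out


def usable_slices(mask: RoiMask, min_voxels: int = 9) -> list[int]:
    """Axial slices with enough mask voxels and an interior voxel for 3x3 support."""
    cross = np.ones((3, 3), bool)
    out = []
    for z in range(mask.shape[0]):
        m = mask.data[z]
        if int(m.sum()) < min_voxels:
            continue
        if not ndimage.binary_erosion(m, structure=cross, border_value=0).any():
            continue
        out.append(z)
    return out


def nodule_features(stack: VmiStack, mask: RoiMask, energy_keV: float,
                    spec: QuantizationSpec = QuantizationSpec(),
                    min_voxels: int = 9) -> FeatureVector:
    """Per-ROI feature vector: slice-wise features averaged across usable slices."""
    mask.check_congruent(stack)
    image3d = stack.volume(energy_keV)
    _, dy, dx = stack.spacing
    slices = usable_slices(mask, min_voxels)
    if not slices:
        raise RoiError(
            f"nodule {mask.nodule_id!r}: no usable slice "
            f"(need >= {min_voxels} voxels and 3x3 interior support)"
        )
    per_slice = [
        slice_features(image3d[z], mask.data[z], spec, spacing=(dy, dx))
        for z in slices
    ]
    avg = {k: float(np.mean([s[k] for s in per_slice])) for k in FEATURE_NAMES}
    return FeatureVector(nodule_id=mask.nodule_id, energy_keV=float(energy_keV),
                         values=avg, n_slices_used=len(slices))


def feature_table(records: Sequence[tuple[FeatureVector, str]]) -> pd.DataFrame:
    """Wide feature table: one row per (nodule, energy), 41 feature columns.

    ``records`` pairs each FeatureVector with its class label.
    """
    rows = []
    for fv, label in records:
        row = {"nodule_id": fv.nodule_id, "label": label,
               "energy_keV": fv.energy_keV, "n_slices_used": fv.n_slices_used}
        row.update({k: fv.values[k] for k in FEATURE_NAMES})
        rows.append(row)
    return pd.DataFrame(rows)


def feature_table_long(wide: pd.DataFrame) -> pd.DataFrame:
    """Long-format view: nodule_id, label, energy_keV, feature, value."""
    return wide.melt(
        id_vars=["nodule_id", "label", "energy_keV"],
        value_vars=list(FEATURE_NAMES),
        var_name="feature", value_name="value",
    )
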