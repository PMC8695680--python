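"""Morphological, first-order and gray-level-matrix radiomic features.

Families and cardinalities under the default configuration:

* 14 morphological features, computed from the raw ROI mask in mm units;
* 22 first-order (histogram) features of the LoG-filtered ROI intensities;
* 22 co-occurrence (GLCM), 18 run-length (GLRLM) and 16 size-zone (GLSZM)
  texture features of the LoG-filtered, discretized ROI.

Texture matrices are built per slice in 2-D (distance-1 neighborhoods,
four directions for GLCM/GLRLM, 8-connected zones for GLSZM), restricted
to ROI pixels, and the per-slice descriptor values are averaged over
slices. Exact member lists follow the IBSI reference nomenclature,
selected to the cardinalities above; see ``docs/methods.md``.

Together with the 84 fractal features the full battery is 176 features
per patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure

from .fractal import fractal_feature_set, threshold_pairs
from .imaging import ImageVolume, RoiMask
from .preprocess import EmptyMaskError, log_filter, normalize_roi

# GLCM / GLRLM direction offsets (row, col): 0, 45, 90, 135 degrees.
_DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


@dataclass
class DiscretizationSpec:
    """Fixed-bin-count discretization of ROI intensities."""

    n_bins: int = 32

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


@dataclass
class FeatureVector:
    """Ordered per-patient feature map with family provenance.

    ``values`` maps unique feature names to floats or ``None`` (an
    explicit missing sentinel for undefined descriptors, e.g. GLCM
    correlation of a constant ROI). ``provenance`` records the image the
    family was computed on: ``raw`` (morphology), ``log`` (first-order
    and texture matrices) or ``ib`` (fractal).
    """

    values: dict[str, float | None] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def add(self, family: str, source: str, features: dict[str, float | None]) -> None:
        for name, value in features.items():
            full = f"{family}_{name}" if not name.startswith(family) else name
            if full in self.values:
                raise ValueError(f"duplicate feature name {full!r}")
            self.values[full] = value
            self.provenance[full] = source

    def __len__(self) -> int:
        return len(self.values)

    def names(self) -> list[str]:
        return list(self.values)

    def family_names(self, family: str) -> list[str]:
        return [n for n in self.values if n.startswith(family + "_")]


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------

def morphological_features(mask: RoiMask, spacing_mm: tuple[float, float, float] | None = None) -> dict[str, float]:
    """Fourteen shape descriptors of the ROI in physical (mm) units.

    Surface area comes from a marching-cubes mesh of the padded mask;
    axis lengths derive from the eigenvalues of the voxel-coordinate
    covariance (principal axes), scaled as for an ellipsoid.
    """
    if mask.empty:
        raise EmptyMaskError("morphology requires a non-empty mask")
    spacing = np.asarray(spacing_mm if spacing_mm is not None else mask.spacing_mm, dtype=float)
    voxel_volume = float(np.prod(spacing))
    n = mask.n_voxels
    volume = n * voxel_volume

    # Light Gaussian pre-smoothing (0.5 voxel) suppresses the staircase
    # artifact of meshing a binary raster; without it the surface of a
    # digital ball is overestimated by ~8%.
    padded = ndimage.gaussian_filter(np.pad(mask.voxels.astype(float), 2), sigma=0.5)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    surface = float(measure.mesh_surface_area(verts, faces))

    coords = np.array(np.nonzero(mask.voxels), dtype=float).T * spacing
    if len(coords) >= 4 and not np.allclose(coords, coords[0]):
        try:
            hull = ConvexHull(coords)
            pts = coords[hull.vertices]
        except Exception:  # coplanar/collinear voxel sets
            pts = coords
    else:
        pts = coords
    max_diam = float(pdist(pts).max()) if len(pts) > 1 else 0.0

    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(coords)
    eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eigvals = np.clip(eigvals, 0.0, None)
    major, minor, least = (4.0 * np.sqrt(ev) for ev in eigvals)

    bbox_edges = coords.max(axis=0) - coords.min(axis=0) + spacing
    bbox_volume = float(np.prod(bbox_edges))

    r_equiv = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    sphericity = (np.pi ** (1.0 / 3.0)) * (6.0 * volume) ** (2.0 / 3.0) / surface
    return {
        "volume_mm3": volume,
        "surface_area_mm2": surface,
        "surface_to_volume_ratio": surface / volume,
        "sphericity": float(sphericity),
        "compactness_1": float(volume / (np.sqrt(np.pi) * surface**1.5)),
        "compactness_2": float(36.0 * np.pi * volume**2 / surface**3),
        "spherical_disproportion": float(surface / (4.0 * np.pi * r_equiv**2)),
        "maximum_3d_diameter_mm": max_diam,
        "major_axis_length_mm": float(major),
        "minor_axis_length_mm": float(minor),
        "least_axis_length_mm": float(least),
        "elongation": float(np.sqrt(eigvals[1] / eigvals[0])) if eigvals[0] > 0 else 0.0,
        "flatness": float(np.sqrt(eigvals[2] / eigvals[0])) if eigvals[0] > 0 else 0.0,
        "bounding_box_volume_ratio": volume / bbox_volume,
    }


# ---------------------------------------------------------------------------
# first order
# ---------------------------------------------------------------------------

def first_order_features(
    vol: ImageVolume,
    mask: RoiMask,
    spec: DiscretizationSpec | None = None,
) -> dict[str, float]:
    """Twenty-two histogram/statistics descriptors of the ROI intensities.

    Entropy and uniformity are computed on a fixed-bin-count histogram
    of the ROI range; all other statistics use the raw (continuous)
    intensities. Variance, skewness and kurtosis are population moments
    (kurtosis is excess kurtosis). Moment ratios of a constant ROI are
    defined as 0.
    """
    if mask.empty:
        raise EmptyMaskError("first-order features require a non-empty mask")
    spec = spec or DiscretizationSpec()
    x = vol.voxels[mask.voxels].astype(float)
    n = x.size
    mean = float(x.mean())
    var = float(x.var())
    sd = float(np.sqrt(var))
    cm = x - mean
    skew = float(np.mean(cm**3) / sd**3) if sd > 0 else 0.0
    kurt = float(np.mean(cm**4) / sd**4 - 3.0) if sd > 0 else 0.0
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
    voxel_volume = float(np.prod(vol.spacing_mm))
    energy = float(np.sum(x**2))

    edges = np.histogram_bin_edges(x, bins=spec.n_bins)
    hist, _ = np.histogram(x, bins=edges)
    p = hist[hist > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())

    denom_qcd = p75 + p25
    return {
        "mean": mean,
        "variance": var,
        "standard_deviation": sd,
        "skewness": skew,
        "kurtosis": kurt,
        "median": float(p50),
        "minimum": float(x.min()),
        "maximum": float(x.max()),
        "range": float(np.ptp(x)),
        "percentile_10": float(p10),
        "percentile_90": float(p90),
        "interquartile_range": float(p75 - p25),
        "mean_absolute_deviation": float(np.abs(cm).mean()),
        "robust_mean_absolute_deviation": rmad,
        "median_absolute_deviation": float(np.median(np.abs(x - p50))),
        "energy": energy,
        "total_energy": energy * voxel_volume,
        "root_mean_square": float(np.sqrt(np.mean(x**2))),
        "entropy": entropy,
        "uniformity": uniformity,
        "coefficient_of_variation": sd / mean if mean != 0 else 0.0,
        "quartile_coefficient_of_dispersion": float((p75 - p25) / denom_qcd) if denom_qcd != 0 else 0.0,
    }


# ---------------------------------------------------------------------------
# discretization and matrix builders
# ---------------------------------------------------------------------------

def discretize(vol: ImageVolume, mask: RoiMask, spec: DiscretizationSpec) -> np.ndarray:
    """Bin ROI intensities into 1..n_bins over the global ROI range.

    Returns an int array on the full grid with 0 outside the ROI.
    """
    out = np.zeros(vol.shape, dtype=int)
    x = vol.voxels[mask.voxels]
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        out[mask.voxels] = 1
        return out
    binned = np.floor((vol.voxels[mask.voxels] - lo) / (hi - lo) * spec.n_bins).astype(int)
    out[mask.voxels] = np.clip(binned, 0, spec.n_bins - 1) + 1
    return out


def glcm_matrix(levels: np.ndarray, n_bins: int) -> np.ndarray:
    """Symmetric direction-averaged co-occurrence matrix of one slice.

    ``levels`` is a 2-D int array with 0 outside the ROI and 1..n_bins
    inside. Distance-1 neighbor pairs are accumulated for the four
    unique 2-D directions, symmetrized, summed over directions and
    normalized to unit mass. Returns the zero matrix if no valid pair
    exists.
    """
    acc = np.zeros((n_bins, n_bins), dtype=float)
    for dr, dc in _DIRECTIONS:
        a, b = _shifted_pairs(levels, dr, dc)
        if a.size:
            np.add.at(acc, (a - 1, b - 1), 1.0)
            np.add.at(acc, (b - 1, a - 1), 1.0)
    total = acc.sum()
    return acc / total if total > 0 else acc


def _shifted_pairs(levels: np.ndarray, dr: int, dc: int) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = levels.shape
    r0, r1 = max(0, -dr), min(rows, rows - dr)
    c0, c1 = max(0, -dc), min(cols, cols - dc)
    a = levels[r0:r1, c0:c1]
    b = levels[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    valid = (a > 0) & (b > 0)
    return a[valid], b[valid]


def glrlm_matrix(levels: np.ndarray, n_bins: int) -> np.ndarray:
    """Direction-summed gray-level run-length matrix of one slice.

    Entry (i, l-1) counts maximal runs of length l at gray level i+1,
    accumulated over the four 2-D directions. Runs are broken by ROI
    boundaries (level 0).
    """
    max_run = max(levels.shape)
    acc = np.zeros((n_bins, max_run), dtype=float)
    for dr, dc in _DIRECTIONS:
        for line in _lines(levels, dr, dc):
            _accumulate_runs(line, acc)
    return acc


def _lines(levels: np.ndarray, dr: int, dc: int):
    """Yield the pixel sequences of a slice along direction (dr, dc)."""
    rows, cols = levels.shape
    if (dr, dc) == (0, 1):
        yield from levels
    elif (dr, dc) == (-1, 0):
        yield from levels.T
    elif (dr, dc) == (-1, 1):  # anti-diagonals, traversed up-right
        flipped = np.flipud(levels)
        for off in range(-rows + 1, cols):
            yield np.diagonal(flipped, offset=off)
    else:  # (-1, -1): main diagonals of the left-right flip
        flipped = np.fliplr(np.flipud(levels))
        for off in range(-rows + 1, cols):
            yield np.diagonal(flipped, offset=off)


def _accumulate_runs(line: np.ndarray, acc: np.ndarray) -> None:
    run_val = 0
    run_len = 0
    for v in line:
        if v == run_val and v > 0:
            run_len += 1
        else:
            if run_val > 0:
                acc[run_val - 1, run_len - 1] += 1.0
            run_val = int(v)
            run_len = 1 if v > 0 else 0
    if run_val > 0:
        acc[run_val - 1, run_len - 1] += 1.0


def glszm_matrix(levels: np.ndarray, n_bins: int) -> np.ndarray:
    """Gray-level size-zone matrix of one slice (8-connected zones)."""
    max_zone = int((levels > 0).sum())
    acc = np.zeros((n_bins, max(max_zone, 1)), dtype=float)
    structure = np.ones((3, 3), dtype=int)
    for g in range(1, n_bins + 1):
        labelled, n_zones = ndimage.label(levels == g, structure=structure)
        if n_zones == 0:
            continue
        sizes = np.bincount(labelled.ravel())[1:]
        for s in sizes:
            acc[g - 1, s - 1] += 1.0
    return acc


# ---------------------------------------------------------------------------
# descriptor formulas
# ---------------------------------------------------------------------------

def _glcm_descriptors(P: np.ndarray) -> dict[str, float | None]:
    n = P.shape[0]
    if P.sum() == 0:
        return {k: None for k in GLCM_FEATURE_NAMES}
    i = np.arange(1, n + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())

    d = np.abs(ii - jj)
    s = ii + jj
    p_diff = np.array([P[d == k].sum() for k in range(n)])
    p_sum = np.array([P[s == k].sum() for k in range(2, 2 * n + 1)])
    k_diff = np.arange(n)
    k_sum = np.arange(2, 2 * n + 1)

    nz = P > 0
    joint_entropy = float(-(P[nz] * np.log2(P[nz])).sum())
    nzd = p_diff > 0
    nzs = p_sum > 0
    diff_avg = float((k_diff * p_diff).sum())
    sum_avg = float((k_sum * p_sum).sum())
    corr = None
    if sigma2 > 0:
        corr = float(((ii - mu) * (jj - mu) * P).sum() / sigma2)
    inv_var_mask = d > 0
    inv_var = float((P[inv_var_mask] / d[inv_var_mask] ** 2).sum())
    return {
        "joint_maximum": float(P.max()),
        "joint_average": float((ii * P).sum()),
        "joint_variance": float(((ii - mu) ** 2 * P).sum()),
        "joint_entropy": joint_entropy,
        "angular_second_moment": float((P**2).sum()),
        "contrast": float((d**2 * P).sum()),
        "dissimilarity": float((d * P).sum()),
        "inverse_difference": float((P / (1.0 + d)).sum()),
        "inverse_difference_normalized": float((P / (1.0 + d / n)).sum()),
        "inverse_difference_moment": float((P / (1.0 + d**2)).sum()),
        "inverse_difference_moment_normalized": float((P / (1.0 + (d / n) ** 2)).sum()),
        "inverse_variance": inv_var,
        "correlation": corr,
        "autocorrelation": float((ii * jj * P).sum()),
        "cluster_shade": float(((ii + jj - 2 * mu) ** 3 * P).sum()),
        "cluster_prominence": float(((ii + jj - 2 * mu) ** 4 * P).sum()),
        "sum_average": sum_avg,
        "sum_variance": float(((k_sum - sum_avg) ** 2 * p_sum).sum()),
        "sum_entropy": float(-(p_sum[nzs] * np.log2(p_sum[nzs])).sum()),
        "difference_average": diff_avg,
        "difference_variance": float(((k_diff - diff_avg) ** 2 * p_diff).sum()),
        "difference_entropy": float(-(p_diff[nzd] * np.log2(p_diff[nzd])).sum()),
    }


def _rl_descriptors(M: np.ndarray, n_pixels: int, kind: str) -> dict[str, float | None]:
    """Shared run-length / size-zone descriptor formulas.

    ``kind`` selects the naming: runs ("run") or zones ("zone").
    """
    names = GLRLM_FEATURE_NAMES if kind == "run" else GLSZM_FEATURE_NAMES
    Ns = M.sum()
    if Ns == 0:
        return {k: None for k in names}
    n_g, n_l = M.shape
    i = np.arange(1, n_g + 1, dtype=float)  # gray levels
    l = np.arange(1, n_l + 1, dtype=float)  # run lengths / zone sizes
    ri = M.sum(axis=1)  # per gray level
    rl = M.sum(axis=0)  # per length
    P = M / Ns
    pi = ri / Ns
    pl = rl / Ns
    mu_i = float((i * pi).sum())
    mu_l = float((l * pl).sum())
    nz = P > 0
    entropy = float(-(P[nz] * np.log2(P[nz])).sum())
    out = {
        "short_emphasis": float((rl / l**2).sum() / Ns),
        "long_emphasis": float((rl * l**2).sum() / Ns),
        "gray_level_non_uniformity": float((ri**2).sum() / Ns),
        "gray_level_non_uniformity_normalized": float((ri**2).sum() / Ns**2),
        "length_non_uniformity": float((rl**2).sum() / Ns),
        "length_non_uniformity_normalized": float((rl**2).sum() / Ns**2),
        "percentage": float(Ns / n_pixels) if n_pixels > 0 else None,
        "low_gray_level_emphasis": float((ri / i**2).sum() / Ns),
        "high_gray_level_emphasis": float((ri * i**2).sum() / Ns),
        "short_low_gray_level_emphasis": float((M / np.outer(i**2, l**2)).sum() / Ns),
        "short_high_gray_level_emphasis": float((M * np.outer(i**2, 1.0 / l**2)).sum() / Ns),
        "long_low_gray_level_emphasis": float((M * np.outer(1.0 / i**2, l**2)).sum() / Ns),
        "long_high_gray_level_emphasis": float((M * np.outer(i**2, l**2)).sum() / Ns),
        "gray_level_variance": float((np.outer((i - mu_i) ** 2, np.ones(n_l)) * P).sum()),
        "length_variance": float((np.outer(np.ones(n_g), (l - mu_l) ** 2) * P).sum()),
        "entropy": entropy,
    }
    if kind == "run":
        out["length_mean"] = mu_l
        out["gray_level_mean"] = mu_i
    generic_to_name = _GENERIC_MAP[kind]
    return {generic_to_name[k]: v for k, v in out.items()}


_GENERIC_MAP = {
    "run": {
        "short_emphasis": "short_run_emphasis",
        "long_emphasis": "long_run_emphasis",
        "gray_level_non_uniformity": "gray_level_non_uniformity",
        "gray_level_non_uniformity_normalized": "gray_level_non_uniformity_normalized",
        "length_non_uniformity": "run_length_non_uniformity",
        "length_non_uniformity_normalized": "run_length_non_uniformity_normalized",
        "percentage": "run_percentage",
        "low_gray_level_emphasis": "low_gray_level_run_emphasis",
        "high_gray_level_emphasis": "high_gray_level_run_emphasis",
        "short_low_gray_level_emphasis": "short_run_low_gray_level_emphasis",
        "short_high_gray_level_emphasis": "short_run_high_gray_level_emphasis",
        "long_low_gray_level_emphasis": "long_run_low_gray_level_emphasis",
        "long_high_gray_level_emphasis": "long_run_high_gray_level_emphasis",
        "gray_level_variance": "gray_level_variance",
        "length_variance": "run_length_variance",
        "entropy": "run_entropy",
        "length_mean": "run_length_mean",
        "gray_level_mean": "gray_level_mean",
    },
    "zone": {
        "short_emphasis": "small_zone_emphasis",
        "long_emphasis": "large_zone_emphasis",
        "gray_level_non_uniformity": "gray_level_non_uniformity",
        "gray_level_non_uniformity_normalized": "gray_level_non_uniformity_normalized",
        "length_non_uniformity": "zone_size_non_uniformity",
        "length_non_uniformity_normalized": "zone_size_non_uniformity_normalized",
        "percentage": "zone_percentage",
        "low_gray_level_emphasis": "low_gray_level_zone_emphasis",
        "high_gray_level_emphasis": "high_gray_level_zone_emphasis",
        "short_low_gray_level_emphasis": "small_zone_low_gray_level_emphasis",
        "short_high_gray_level_emphasis": "small_zone_high_gray_level_emphasis",
        "long_low_gray_level_emphasis": "large_zone_low_gray_level_emphasis",
        "long_high_gray_level_emphasis": "large_zone_high_gray_level_emphasis",
        "gray_level_variance": "gray_level_variance",
        "length_variance": "zone_size_variance",
        "entropy": "zone_size_entropy",
    },
}

GLCM_FEATURE_NAMES = (
    "joint_maximum", "joint_average", "joint_variance", "joint_entropy",
    "angular_second_moment", "contrast", "dissimilarity",
    "inverse_difference", "inverse_difference_normalized",
    "inverse_difference_moment", "inverse_difference_moment_normalized",
    "inverse_variance", "correlation", "autocorrelation",
    "cluster_shade", "cluster_prominence", "sum_average", "sum_variance",
    "sum_entropy", "difference_average", "difference_variance",
    "difference_entropy",
)
GLRLM_FEATURE_NAMES = tuple(_GENERIC_MAP["run"].values())
GLSZM_FEATURE_NAMES = tuple(_GENERIC_MAP["zone"].values())


def _per_slice_average(
    levels: np.ndarray,
    mask: RoiMask,
    builder,
    descriptors,
    names: tuple[str, ...],
) -> dict[str, float | None]:
    """Compute descriptors per slice and average over non-empty slices."""
    collected: dict[str, list[float]] = {k: [] for k in names}
    for k in range(levels.shape[0]):
        sl = levels[k]
        if not (sl > 0).any():
            continue
        vals = descriptors(builder(sl), int((sl > 0).sum()))
        for name in names:
            v = vals[name]
            if v is not None:
                collected[name].append(v)
    return {
        name: float(np.mean(vs)) if vs else None for name, vs in collected.items()
    }


def glcm_features(vol: ImageVolume, mask: RoiMask, spec: DiscretizationSpec | None = None) -> dict[str, float | None]:
    """22 co-occurrence features, slice-averaged."""
    spec = spec or DiscretizationSpec()
    if mask.empty:
        raise EmptyMaskError("texture features require a non-empty mask")
    levels = discretize(vol, mask, spec)
    return _per_slice_average(
        levels, mask,
        lambda sl: glcm_matrix(sl, spec.n_bins),
        lambda M, n: _glcm_descriptors(M),
        GLCM_FEATURE_NAMES,
    )


def glrlm_features(vol: ImageVolume, mask: RoiMask, spec: DiscretizationSpec | None = None) -> dict[str, float | None]:
    """18 run-length features, slice-averaged (4 directions summed)."""
    spec = spec or DiscretizationSpec()
    if mask.empty:
        raise EmptyMaskError("texture features require a non-empty mask")
    levels = discretize(vol, mask, spec)
    return _per_slice_average(
        levels, mask,
        lambda sl: glrlm_matrix(sl, spec.n_bins),
        lambda M, n: _rl_descriptors(M, n, "run"),
        GLRLM_FEATURE_NAMES,
    )


def glszm_features(vol: ImageVolume, mask: RoiMask, spec: DiscretizationSpec | None = None) -> dict[str, float | None]:
    """16 size-zone features, slice-averaged (8-connected zones)."""
    spec = spec or DiscretizationSpec()
    if mask.empty:
        raise EmptyMaskError("texture features require a non-empty mask")
    levels = discretize(vol, mask, spec)
    return _per_slice_average(
        levels, mask,
        lambda sl: glszm_matrix(sl, spec.n_bins),
        lambda M, n: _rl_descriptors(M, n, "zone"),
        GLSZM_FEATURE_NAMES,
    )


# ---------------------------------------------------------------------------
# full battery
# ---------------------------------------------------------------------------

def extract_all(
    vol: ImageVolume,
    mask: RoiMask,
    spec: DiscretizationSpec | None = None,
    log_kernel_mm: float = 0.4,
    pairs: list[tuple[float, float]] | None = None,
) -> FeatureVector:
    """Extract the full 176-feature battery for one patient.

    Morphology is computed on the raw mask; first-order and texture
    matrices on the LoG-filtered image; fractal features on the
    percentile-normalized (IB-filtered) raw image. With the default
    configuration the vector holds 92 radiomic features (14 + 22 + 22 +
    18 + 16) and 84 fractal features (21 threshold pairs x 4 slice
    aggregates), 176 in total.
    """
    spec = spec or DiscretizationSpec()
    fv = FeatureVector()
    fv.add("morph", "raw", morphological_features(mask))
    filtered = log_filter(vol, kernel_mm=log_kernel_mm)
    fv.add("firstorder", "log", first_order_features(filtered, mask, spec))
    fv.add("glcm", "log", glcm_features(filtered, mask, spec))
    fv.add("glrlm", "log", glrlm_features(filtered, mask, spec))
    fv.add("glszm", "log", glszm_features(filtered, mask, spec))
    norm = normalize_roi(vol, mask)
    fset = fractal_feature_set(norm, pairs=pairs or threshold_pairs())
    fv.add("fractal", "ib", fset.values)
    return fv
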