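"""Image filters applied before feature extraction.

Two filters are provided: a slice-wise Laplacian-of-Gaussian band-pass
(used before first-order and texture-matrix features) and an
intensity-based (IB) percentile normalization of the ROI histogram with
threshold-level subpopulation masks (used before fractal features).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imaging import ImageVolume, RoiMask


class DegenerateKernelError(ValueError):
    """LoG scale below a tenth of a pixel — response would be numeric noise."""


class EmptyMaskError(ValueError):
    """Operation requires at least one ROI voxel."""


class ThresholdBoundsError(ValueError):
    """Subpopulation bounds must satisfy 0 <= lo < hi <= 1."""


def log_filter(vol: ImageVolume, kernel_mm: float = 0.4) -> ImageVolume:
    """Slice-wise 2-D Laplacian-of-Gaussian filter.

    The Gaussian scale is ``kernel_mm`` converted to pixels through the
    in-plane spacing; each slice is filtered independently because the
    through-plane spacing is typically several times coarser than the
    in-plane resolution.
    """
    if kernel_mm <= 0:
        raise DegenerateKernelError("kernel_mm must be positive")
    row_sp, col_sp = vol.in_plane_spacing
    sigma = (kernel_mm / row_sp, kernel_mm / col_sp)
    if min(sigma) < 0.1:
        raise DegenerateKernelError(
            f"kernel {kernel_mm} mm is below a tenth of a pixel at spacing ({row_sp}, {col_sp})"
        )
    # Gaussian smoothing followed by the exact discrete Laplacian
    # [1,-2,1]/h^2 per axis. Unlike a sampled Gaussian-derivative kernel
    # this is exactly zero on constant images even at sub-pixel sigma.
    lap = np.array([1.0, -2.0, 1.0])
    out = np.empty_like(vol.voxels)
    for k in range(vol.shape[0]):
        smooth = ndimage.gaussian_filter(vol.voxels[k], sigma=sigma, mode="nearest")
        d2r = ndimage.correlate1d(smooth, lap, axis=0, mode="nearest") / row_sp**2
        d2c = ndimage.correlate1d(smooth, lap, axis=1, mode="nearest") / col_sp**2
        out[k] = d2r + d2c
    return ImageVolume(voxels=out, spacing_mm=vol.spacing_mm, origin_mm=vol.origin_mm)


@dataclass
class NormalizedRoi:
    """Percentile-normalized ROI intensities.

    ``values[i]`` is the normalized intensity of the voxel at
    ``indices[:, i]`` (slice, row, col). ``p1``/``p99`` are the clipping
    percentiles of the raw ROI histogram. ``degenerate`` flags a
    constant ROI (p1 == p99), for which every value is set to 0.
    """

    values: np.ndarray
    indices: np.ndarray
    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    p1: float
    p99: float
    degenerate: bool = False

    def as_volume(self, fill: float = np.nan) -> np.ndarray:
        """Scatter normalized values back onto the full grid."""
        out = np.full(self.shape, fill, dtype=float)
        out[tuple(self.indices)] = self.values
        return out


def normalize_roi(
    vol: ImageVolume,
    mask: RoiMask,
    percentiles: tuple[float, float] = (1.0, 99.0),
) -> NormalizedRoi:
    """Clip ROI intensities to the (1st, 99th) percentiles and rescale to [0, 1].

    Invariant under positive affine transforms of the raw intensities:
    percentiles and the affine rescale commute, so ``a*v + b`` (a > 0)
    produces identical output.
    """
    if mask.empty:
        raise EmptyMaskError("cannot normalize an empty ROI")
    indices = np.array(np.nonzero(mask.voxels))
    raw = vol.voxels[tuple(indices)]
    p_lo, p_hi = np.percentile(raw, percentiles)  # linear interpolation
    if p_hi <= p_lo:
        return NormalizedRoi(
            values=np.zeros(raw.shape),
            indices=indices,
            shape=vol.shape,
            spacing_mm=vol.spacing_mm,
            p1=float(p_lo),
            p99=float(p_hi),
            degenerate=True,
        )
    values = (np.clip(raw, p_lo, p_hi) - p_lo) / (p_hi - p_lo)
    return NormalizedRoi(
        values=values,
        indices=indices,
        shape=vol.shape,
        spacing_mm=vol.spacing_mm,
        p1=float(p_lo),
        p99=float(p_hi),
    )


@dataclass
class SubpopulationMask:
    """ROI voxels whose normalized intensity lies in [lo, hi).

    The upper bound is closed when ``hi == 1`` so that masks over a
    partition of [0, 1] tile the ROI exactly.
    """

    lo: float
    hi: float
    voxels: np.ndarray = field(repr=False)

    @property
    def empty(self) -> bool:
        return not bool(self.voxels.any())

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


def subpopulation_mask(norm: NormalizedRoi, lo: float, hi: float) -> SubpopulationMask:
    """Select ROI voxels with normalized intensity in [lo, hi) ([lo, 1] if hi == 1)."""
    if not (0.0 <= lo < hi <= 1.0):
        raise ThresholdBoundsError(f"need 0 <= lo < hi <= 1, got lo={lo}, hi={hi}")
    if hi >= 1.0:
        sel = (norm.values >= lo) & (norm.values <= 1.0)
    else:
        sel = (norm.values >= lo) & (norm.values < hi)
    voxels = np.zeros(norm.shape, dtype=bool)
    voxels[tuple(norm.indices[:, sel])] = True
    return SubpopulationMask(lo=float(lo), hi=float(hi), voxels=voxels)
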