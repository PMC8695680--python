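"""Box-counting fractal dimension of intensity-threshold subpopulations.

The fractal dimension (FD) of a binary slice pattern is estimated as the
least-squares slope of log(occupied boxes) versus log(1/box size). FD is
computed per slice for each threshold-pair subpopulation of the
normalized ROI, then aggregated over slices (min / max / mean / median)
into the fractal feature set. With the default seven threshold levels
this yields 21 pairs x 4 aggregates = 84 features, among them
``fractal_maxFD_30_50`` — the maximum slice FD of the 30%–50% intensity
subpopulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import NormalizedRoi, subpopulation_mask

#: Default normalized-intensity threshold levels. Interior levels step by
#: 20% (10, 30, 50, 70, 90); the outer levels close the range so that all
#: C(7,2) = 21 ordered pairs are formed.
DEFAULT_THRESHOLD_LEVELS: tuple[float, ...] = (0.0, 0.10, 0.30, 0.50, 0.70, 0.90, 1.0)

AGGREGATES = ("min", "max", "mean", "median")


class EmptyPatternError(ValueError):
    """Box counting requires at least one foreground pixel."""


class InsufficientScalesError(ValueError):
    """Fewer than three usable box sizes — a slope cannot be trusted."""


class DegenerateRoiError(ValueError):
    """Every threshold-pair subpopulation is empty on every slice."""


def threshold_pairs(
    levels: tuple[float, ...] = DEFAULT_THRESHOLD_LEVELS,
) -> list[tuple[float, float]]:
    """All ordered (lo, hi) pairs of the threshold levels, lo < hi."""
    lv = sorted(levels)
    return [(lv[i], lv[j]) for i in range(len(lv)) for j in range(i + 1, len(lv))]


@dataclass
class BoxCountingResult:
    """Log-log box-count regression for one binary slice."""

    box_sizes: np.ndarray
    counts: np.ndarray
    fd: float
    r2: float


def box_count(pattern: np.ndarray, box_sizes: list[int] | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Count occupied boxes of a square grid overlaid on a binary raster.

    The grid is anchored at the raster origin; partial cells at the far
    edges count like full cells. ``counts[k]`` is the number of
    ``box_sizes[k]``-pixel cells containing at least one foreground pixel.
    """
    pattern = np.asarray(pattern) > 0
    if pattern.ndim != 2:
        raise ValueError("pattern must be a 2-D raster")
    if not pattern.any():
        raise EmptyPatternError("pattern has no foreground pixels")
    sizes = np.asarray(box_sizes, dtype=int)
    if np.any(sizes < 1):
        raise ValueError("box sizes must be >= 1")
    rows, cols = np.nonzero(pattern)
    counts = np.empty(len(sizes), dtype=int)
    for k, s in enumerate(sizes):
        cells = set(zip((rows // s).tolist(), (cols // s).tolist()))
        counts[k] = len(cells)
    return sizes, counts


def _default_ladder(shape: tuple[int, int]) -> np.ndarray:
    """Powers of 2 from 1 up to half the shorter side."""
    limit = max(min(shape) // 2, 1)
    sizes = [1]
    while sizes[-1] * 2 <= limit:
        sizes.append(sizes[-1] * 2)
    return np.asarray(sizes, dtype=int)


def fd_slice(pattern: np.ndarray, box_sizes: list[int] | None = None) -> BoxCountingResult:
    """Box-counting FD of one binary slice.

    The default size ladder is dyadic (1, 2, 4, ... up to half the
    shorter raster side). For exactly self-similar fixtures a matched
    ladder (e.g. triadic for a Sierpinski carpet) recovers the
    similarity dimension to numerical precision.
    """
    pattern = np.asarray(pattern) > 0
    # Crop to the bounding box so the grid anchors on the pattern itself.
    rows = np.flatnonzero(pattern.any(axis=1))
    cols = np.flatnonzero(pattern.any(axis=0))
    if rows.size == 0:
        raise EmptyPatternError("pattern has no foreground pixels")
    cropped = pattern[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    if box_sizes is None:
        sizes = _default_ladder(cropped.shape)
        if len(sizes) < 3:
            # tiny pattern: extend the ladder beyond the bounding box
            sizes = np.asarray([1, 2, 4], dtype=int)
    else:
        sizes = np.asarray(box_sizes, dtype=int)
    if len(sizes) < 3:
        raise InsufficientScalesError(f"need >= 3 box sizes, got {len(sizes)}")
    sizes, counts = box_count(cropped, sizes)
    x = np.log(1.0 / sizes)
    y = np.log(counts.astype(float))
    if np.ptp(y) == 0.0:  # constant counts (e.g. single pixel) -> FD 0
        return BoxCountingResult(box_sizes=sizes, counts=counts, fd=0.0, r2=1.0)
    slope, _ = np.polyfit(x, y, 1)
    resid = y - np.polyval(np.polyfit(x, y, 1), x)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - float(np.sum(resid**2) / ss_tot) if ss_tot > 0 else 1.0
    return BoxCountingResult(box_sizes=sizes, counts=counts, fd=float(slope), r2=r2)


@dataclass
class FractalFeatureSet:
    """Slice-FD aggregates per threshold pair.

    ``values`` maps feature names like ``fractal_maxFD_30_50`` to floats;
    pairs whose subpopulation is empty on every slice carry ``None``.
    """

    values: dict[str, float | None]
    pairs: list[tuple[float, float]]

    @property
    def maxFD_30_50(self) -> float | None:
        return self.values.get("fractal_maxFD_30_50")

    def __len__(self) -> int:
        return len(self.values)


def _pair_tag(lo: float, hi: float) -> str:
    return f"{round(lo * 100)}_{round(hi * 100)}"


def fractal_feature_set(
    norm: NormalizedRoi,
    pairs: list[tuple[float, float]] | None = None,
) -> FractalFeatureSet:
    """Fractal features of a normalized ROI.

    For each (lo, hi) threshold pair the subpopulation mask is built,
    the FD of each non-empty slice is computed on the default dyadic
    ladder, and min/max/mean/median over slices are emitted. Slices on
    which the subpopulation is empty are skipped (FD of an empty set is
    undefined); a pair empty on all slices yields explicit ``None``
    sentinels.
    """
    if pairs is None:
        pairs = threshold_pairs()
    values: dict[str, float | None] = {}
    any_nonempty = False
    for lo, hi in pairs:
        sub = subpopulation_mask(norm, lo, hi)
        fds = []
        for k in range(sub.voxels.shape[0]):
            sl = sub.voxels[k]
            if sl.any():
                try:
                    fds.append(fd_slice(sl).fd)
                except InsufficientScalesError:
                    continue
        tag = _pair_tag(lo, hi)
        if fds:
            any_nonempty = True
            arr = np.asarray(fds)
            agg = {
                "min": float(arr.min()),
                "max": float(arr.max()),
                "mean": float(arr.mean()),
                "median": float(np.median(arr)),
            }
        else:
            agg = {a: None for a in AGGREGATES}
        for a in AGGREGATES:
            values[f"fractal_{a}FD_{tag}"] = agg[a]
    if not any_nonempty:
        raise DegenerateRoiError("every threshold-pair subpopulation is empty on all slices")
    return FractalFeatureSet(values=values, pairs=list(pairs))
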