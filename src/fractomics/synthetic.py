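"""Synthetic inputs: analytic fractal fixtures, tumor-like phantoms and
outcome cohorts.

Three generators cover everything the pipeline needs without external
data:

* ``make_fractal_fixture`` — binary rasters with known box-counting
  behavior (single pixel, filled square, line, Sierpinski carpet), used
  as exact oracles for the FD estimator.
* ``simulate_tumor_volume`` — an ellipsoidal ROI filled with a
  spectral-synthesis fractional-noise texture whose roughness is
  controlled by a single ``heterogeneity`` knob, emulating intra-tumor
  signal heterogeneity on T2-weighted MRI.
* ``simulate_cohort`` — per-patient feature/outcome tables drawn from a
  logistic model used as generative truth, one table per chemotherapy
  regimen cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .imaging import ImageVolume, RoiMask, write_mask, write_volume
from .stats import LogisticModel, predict_prob

FIXTURE_KINDS = ("single_pixel", "filled_square", "line", "sierpinski_carpet")
REGIMENS = ("OXA", "NO_OXA")


class UnknownFixtureKindError(ValueError):
    """Requested fixture kind is not one of FIXTURE_KINDS."""


@dataclass
class PhantomSpec:
    """Parameters of a synthetic tumor phantom.

    ``heterogeneity`` in [0, 1] controls the roughness of the intra-ROI
    texture (0 = perfectly homogeneous tumor, 1 = maximally rough);
    ``noise_sd`` adds white Gaussian acquisition-like noise on top.
    """

    grid_shape: tuple[int, int, int] = (16, 64, 64)
    spacing_mm: tuple[float, float, float] = (3.0, 0.8, 0.8)
    roi_radius_mm: float = 18.0
    heterogeneity: float = 0.5
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 8 for s in self.grid_shape):
            raise ValueError("grid_shape components must be >= 8")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        if self.roi_radius_mm <= 0:
            raise ValueError("roi_radius_mm must be positive")
        if not 0.0 <= self.heterogeneity <= 1.0:
            raise ValueError("heterogeneity must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        extent = [n * s / 2.0 for n, s in zip(self.grid_shape, self.spacing_mm)]
        if any(self.roi_radius_mm > e for e in extent):
            raise ValueError(
                f"ROI radius {self.roi_radius_mm} mm does not fit inside grid half-extents {extent}"
            )


@dataclass
class CohortSpec:
    """Parameters of a synthetic outcome cohort.

    ``maxFD_30_50`` values are drawn uniformly on [fd_low, fd_high]
    (a slice FD lies in [1, 2] for a planar pattern) and the binary
    5-year disease-free-survival outcome is Bernoulli with probability
    given by ``model``.
    """

    n: int
    model: LogisticModel
    fd_low: float = 1.4
    fd_high: float = 2.0
    regimen_label: str = "OXA"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (1.0 <= self.fd_low < self.fd_high <= 2.0):
            raise ValueError("need 1.0 <= fd_low < fd_high <= 2.0")
        if self.regimen_label not in REGIMENS:
            raise ValueError(f"regimen_label must be one of {REGIMENS}")


def make_fractal_fixture(kind: str, level_or_size: int) -> np.ndarray:
    """Deterministic binary raster of a named pattern.

    ``single_pixel``: a 1x1 foreground raster (argument ignored beyond
    validation). ``filled_square``: an n x n all-foreground raster.
    ``line``: a 1 x n foreground row. ``sierpinski_carpet``: the level-L
    carpet on a 3^L x 3^L grid, with exactly 8^L foreground pixels.
    """
    if level_or_size < 1:
        raise ValueError("level_or_size must be >= 1")
    if kind == "single_pixel":
        return np.ones((1, 1), dtype=bool)
    if kind == "filled_square":
        return np.ones((level_or_size, level_or_size), dtype=bool)
    if kind == "line":
        return np.ones((1, level_or_size), dtype=bool)
    if kind == "sierpinski_carpet":
        pattern = np.ones((1, 1), dtype=bool)
        for _ in range(level_or_size):
            z = np.zeros_like(pattern)
            pattern = np.block([
                [pattern, pattern, pattern],
                [pattern, z, pattern],
                [pattern, pattern, pattern],
            ])
        return pattern
    raise UnknownFixtureKindError(f"unknown kind {kind!r}; expected one of {FIXTURE_KINDS}")


def _spectral_noise(shape: tuple[int, int, int], beta: float, rng: np.random.Generator) -> np.ndarray:
    """Isotropic power-law noise: amplitude spectrum ~ f^(-beta/2).

    Smaller beta means flatter spectrum and rougher field. Synthesized
    by filtering complex white noise in the frequency domain.
    """
    freqs = np.meshgrid(
        *[np.fft.fftfreq(n) for n in shape], indexing="ij"
    )
    f = np.sqrt(sum(g**2 for g in freqs))
    f[0, 0, 0] = np.inf  # zero out the DC gain
    amplitude = f ** (-beta / 2.0)
    phase = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    field = np.real(np.fft.ifftn(amplitude * phase))
    field -= field.mean()
    sd = field.std()
    return field / sd if sd > 0 else field


def simulate_tumor_volume(spec: PhantomSpec) -> tuple[ImageVolume, RoiMask]:
    """Ellipsoidal ROI with tunable fractional-noise texture.

    The intra-ROI texture is a power-law noise field whose spectral
    exponent decreases linearly with ``heterogeneity`` (beta = 4 - 3h),
    so rougher settings raise the estimated fractal dimension of
    intensity subpopulations. Background voxels are 0. Output is
    bit-identical for identical specs.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.grid_shape)
    centers = [(n - 1) / 2.0 for n in shape]
    grids = np.meshgrid(
        *[(np.arange(n) - c) * s for n, c, s in zip(shape, centers, spec.spacing_mm)],
        indexing="ij",
    )
    dist2 = sum((g / spec.roi_radius_mm) ** 2 for g in grids)
    mask_arr = dist2 <= 1.0
    mask = RoiMask(voxels=mask_arr, spacing_mm=spec.spacing_mm)

    base = 100.0
    voxels = np.zeros(shape, dtype=float)
    voxels[mask_arr] = base
    if spec.heterogeneity > 0:
        beta = 4.0 - 3.0 * spec.heterogeneity
        texture = _spectral_noise(shape, beta, rng)
        voxels[mask_arr] += 25.0 * spec.heterogeneity * texture[mask_arr]
    if spec.noise_sd > 0:
        voxels[mask_arr] += spec.noise_sd * rng.standard_normal(int(mask_arr.sum()))
    vol = ImageVolume(voxels=voxels, spacing_mm=spec.spacing_mm)
    return vol, mask


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a per-patient cohort table from a logistic generative model.

    Columns: ``patient_id``, ``maxFD_30_50``, ``dfs5y`` (binary 5-year
    disease-free survival) and ``regimen``.
    """
    rng = np.random.default_rng(spec.seed)
    fd = rng.uniform(spec.fd_low, spec.fd_high, size=spec.n)
    p = predict_prob(spec.model, fd)
    outcome = (rng.uniform(size=spec.n) < p).astype(int)
    return pd.DataFrame(
        {
            "patient_id": [f"{spec.regimen_label}_{i:05d}" for i in range(spec.n)],
            "maxFD_30_50": fd,
            "dfs5y": outcome,
            "regimen": spec.regimen_label,
        }
    )


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as comma-delimited text."""
    table.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort table written by :func:`write_cohort`."""
    return pd.read_csv(path)


def write_phantom(vol: ImageVolume, mask: RoiMask, vol_path: str | Path, mask_path: str | Path) -> None:
    """Write a phantom as a NIfTI volume + NIfTI mask pair."""
    write_volume(vol, vol_path)
    write_mask(mask, mask_path)
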