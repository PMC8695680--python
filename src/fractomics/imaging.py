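"""Image volume and ROI mask containers with NIfTI / DICOM-series I/O.

All in-memory arrays follow one spatial convention: axis 0 is the
through-plane (slice) axis, axes 1 and 2 are in-plane rows and columns.
World coordinates only appear at the I/O boundary; every downstream
computation is raster-local.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom


class ImagingError(Exception):
    """Base class for imaging I/O failures."""


class MissingFileError(ImagingError):
    """Path does not exist or contains no readable image."""


class SpacingInconsistencyError(ImagingError):
    """A DICOM series whose slices are not uniformly spaced."""


class NonScalarPixelError(ImagingError):
    """Pixel data is not scalar (e.g. RGB)."""


class MaskAlignmentError(ImagingError):
    """Mask grid does not match its reference volume grid."""


@dataclass
class ImageVolume:
    """A 3-D scalar raster.

    Parameters
    ----------
    voxels
        Array of shape ``(n_slices, n_rows, n_cols)``; finite values.
    spacing_mm
        Physical voxel size ``(slice, row, col)`` in millimetres.
    origin_mm
        World position of voxel ``(0, 0, 0)``.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ImagingError(f"expected 3-D voxel array, got ndim={self.voxels.ndim}")
        if not np.all(np.isfinite(self.voxels)):
            raise ImagingError("voxel intensities must be finite")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ImagingError(f"spacing must be strictly positive, got {self.spacing_mm}")
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def in_plane_spacing(self) -> tuple[float, float]:
        return self.spacing_mm[1], self.spacing_mm[2]


@dataclass
class RoiMask:
    """Binary region-of-interest on the same grid as its image volume."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    empty: bool = field(init=False)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels) > 0
        if self.voxels.ndim != 3:
            raise ImagingError(f"expected 3-D mask array, got ndim={self.voxels.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.empty = not bool(self.voxels.any())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


def _from_nifti(path: Path) -> ImageVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise NonScalarPixelError(f"{path}: expected 3-D scalar data, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    # NIfTI stores (i, j, k) fastest-to-slowest; move the k (slice) axis first.
    voxels = np.transpose(np.asarray(data, dtype=float), (2, 1, 0))
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return ImageVolume(voxels=voxels, spacing_mm=spacing, origin_mm=origin)


def _from_dicom_series(path: Path) -> ImageVolume:
    files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:
            continue
    if not datasets:
        raise MissingFileError(f"no readable DICOM files in {path}")
    for ds in datasets:
        if int(getattr(ds, "SamplesPerPixel", 1)) != 1:
            raise NonScalarPixelError("DICOM pixel data is not scalar")
    datasets.sort(key=lambda d: float(d.ImagePositionPatient[2]))
    zs = np.array([float(d.ImagePositionPatient[2]) for d in datasets])
    if len(zs) > 1:
        gaps = np.diff(zs)
        if np.ptp(gaps) > 1e-3:
            raise SpacingInconsistencyError(f"slice gaps vary: {gaps.tolist()}")
        dz = float(gaps[0])
    else:
        dz = float(getattr(datasets[0], "SliceThickness", 1.0))
    row_sp, col_sp = (float(v) for v in datasets[0].PixelSpacing)
    slope = float(getattr(datasets[0], "RescaleSlope", 1.0))
    intercept = float(getattr(datasets[0], "RescaleIntercept", 0.0))
    voxels = np.stack([d.pixel_array.astype(float) * slope + intercept for d in datasets])
    pos = datasets[0].ImagePositionPatient
    return ImageVolume(
        voxels=voxels,
        spacing_mm=(dz, row_sp, col_sp),
        origin_mm=(float(pos[2]), float(pos[1]), float(pos[0])),
    )


def read_volume(path: str | Path, format: str = "nifti") -> ImageVolume:
    """Read a scalar volume from a NIfTI file or a DICOM series directory.

    Parameters
    ----------
    path
        ``.nii``/``.nii.gz`` file for ``format="nifti"``; directory of
        single-frame DICOM files for ``format="dicom_series"``.
    format
        One of ``{"nifti", "dicom_series"}``.
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"no such path: {path}")
    if format == "nifti":
        return _from_nifti(path)
    if format == "dicom_series":
        if not path.is_dir():
            raise MissingFileError(f"DICOM series must be a directory: {path}")
        return _from_dicom_series(path)
    raise ValueError(f"unknown format {format!r}; expected 'nifti' or 'dicom_series'")


def write_volume(vol: ImageVolume, path: str | Path) -> None:
    """Write a volume as NIfTI, preserving voxels and spacing."""
    affine = np.diag([vol.spacing_mm[2], vol.spacing_mm[1], vol.spacing_mm[0], 1.0])
    affine[:3, 3] = vol.origin_mm
    data = np.transpose(vol.voxels, (2, 1, 0))
    nib.save(nib.Nifti1Image(data, affine), str(path))


def write_mask(mask: RoiMask, path: str | Path) -> None:
    """Write a binary mask as a uint8 NIfTI label volume."""
    affine = np.diag([mask.spacing_mm[2], mask.spacing_mm[1], mask.spacing_mm[0], 1.0])
    data = np.transpose(mask.voxels.astype(np.uint8), (2, 1, 0))
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_mask(path: str | Path, reference: ImageVolume) -> RoiMask:
    """Read a label volume and binarize it against a reference grid.

    Any strictly positive label becomes foreground. The grid must match
    the reference volume exactly; no resampling is attempted.
    """
    vol = read_volume(path, format="nifti")
    if vol.shape != reference.shape:
        raise MaskAlignmentError(
            f"mask grid {vol.shape} does not match reference grid {reference.shape}"
        )
    mask = RoiMask(voxels=vol.voxels > 0, spacing_mm=reference.spacing_mm)
    if mask.empty:
        warnings.warn("mask contains no foreground voxels", stacklevel=2)
    return mask
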