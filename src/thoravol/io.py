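"""File I/O: NIfTI read/write and single-series DICOM reading.

Every volume is reoriented on load to the canonical LPS-index convention
(see :mod:`thoravol.core`), so rule-based logic downstream never depends on
how a file happened to be stored.  Writing emits NIfTI whose re-read
reproduces labels, spacing and orientation exactly.
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import CANONICAL_AXCODES, ImageVolume, LabelMask, VoxelSpacing

__all__ = ["read_volume", "read_mask", "write_mask", "write_image", "read_dicom_series"]

#: Maximum allowed jitter (mm) between consecutive DICOM slice gaps.
DICOM_SLICE_SPACING_TOLERANCE_MM = 1e-3


def _canonicalize(data: np.ndarray, affine: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Reorient array+affine so voxel axes follow the LPS-increasing convention."""
    current = nib.orientations.io_orientation(affine)
    target = nib.orientations.axcodes2ornt(CANONICAL_AXCODES)
    transform = nib.orientations.ornt_transform(current, target)
    data2 = nib.orientations.apply_orientation(data, transform)
    affine2 = affine @ nib.orientations.inv_ornt_aff(transform, data.shape)
    return np.ascontiguousarray(data2), affine2


def _geometry_from_affine(affine: np.ndarray) -> tuple[VoxelSpacing, tuple[float, float, float]]:
    zooms = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    spacing = VoxelSpacing(*(float(z) for z in zooms))
    origin = tuple(float(v) for v in affine[:3, 3])
    return spacing, origin  # type: ignore[return-value]


def _canonical_affine(spacing: VoxelSpacing, origin: tuple[float, float, float]) -> np.ndarray:
    # Canonical voxel axes (L, P, S) expressed in the RAS world frame.
    aff = np.diag([-spacing.dx, -spacing.dy, spacing.dz, 1.0])
    aff[:3, 3] = origin
    return aff


def _load_nifti(path: Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return _canonicalize(data, img.affine)


def read_volume(path: str | os.PathLike, format: str = "nifti") -> ImageVolume:
    """Read a CT image volume from a NIfTI file or a DICOM series directory.

    Parameters
    ----------
    path
        NIfTI file, or (for ``format="dicom_series"``) a directory holding the
        slices of exactly one series.
    format
        ``"nifti"`` or ``"dicom_series"``.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"volume not found: {p}")
    if format == "nifti":
        data, affine = _load_nifti(p)
    elif format == "dicom_series":
        data, affine = _read_dicom_arrays(p)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'nifti' or 'dicom_series'")
    spacing, origin = _geometry_from_affine(affine)
    return ImageVolume(data.astype(np.float32), spacing, origin)


def read_dicom_series(path: str | os.PathLike) -> ImageVolume:
    """Shorthand for :func:`read_volume` with ``format="dicom_series"``."""
    return read_volume(path, format="dicom_series")


def read_mask(path: str | os.PathLike) -> LabelMask:
    """Read an integer label mask from NIfTI, canonicalized like images."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"mask not found: {p}")
    data, affine = _load_nifti(p)
    spacing, origin = _geometry_from_affine(affine)
    data = np.asarray(data)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise ValueError(f"{p}: mask voxels are not integer-valued")
        data = rounded.astype(np.int32)
    return LabelMask(data, spacing, origin)


def write_mask(mask: LabelMask, path: str | os.PathLike) -> None:
    """Write a label mask as NIfTI; round-trips labels/spacing/orientation exactly."""
    labels = np.asarray(mask.labels)
    maxlab = int(labels.max()) if labels.size else 0
    dtype = np.uint8 if maxlab < 256 else np.int32
    img = nib.Nifti1Image(labels.astype(dtype), _canonical_affine(mask.spacing, mask.origin))
    img.header.set_data_dtype(dtype)
    nib.save(img, str(path))


def write_image(image: ImageVolume, path: str | os.PathLike) -> None:
    """Write a scalar image volume as float32 NIfTI."""
    img = nib.Nifti1Image(
        np.asarray(image.voxels, dtype=np.float32),
        _canonical_affine(image.spacing, image.origin),
    )
    img.header.set_data_dtype(np.float32)
    nib.save(img, str(path))


def _read_dicom_arrays(directory: Path) -> tuple[np.ndarray, np.ndarray]:
    import pydicom

    if not directory.is_dir():
        raise NotADirectoryError(f"DICOM series path must be a directory: {directory}")
    files = sorted(f for f in directory.iterdir() if f.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"no DICOM image slices found in {directory}")
    series_uids = {getattr(ds, "SeriesInstanceUID", None) for ds in slices}
    if len(series_uids) > 1:
        raise ValueError(
            f"{directory} contains {len(series_uids)} series; expected a single-series directory"
        )

    iop = np.asarray(slices[0].ImageOrientationPatient, dtype=float)
    row_dir, col_dir = iop[:3], iop[3:]  # direction of increasing column / row index (LPS)
    normal = np.cross(row_dir, col_dir)
    positions = np.asarray([np.dot(normal, np.asarray(ds.ImagePositionPatient, float)) for ds in slices])
    order = np.argsort(positions)
    slices = [slices[i] for i in order]
    positions = positions[order]

    if len(slices) > 1:
        gaps = np.diff(positions)
        if gaps.min() <= 0:
            raise ValueError(f"{directory}: duplicate or non-monotonic slice positions")
        if gaps.max() - gaps.min() > DICOM_SLICE_SPACING_TOLERANCE_MM:
            raise ValueError(
                f"{directory}: non-uniform slice spacing (gaps {gaps.min():.4f}–{gaps.max():.4f} mm "
                f"exceed tolerance {DICOM_SLICE_SPACING_TOLERANCE_MM} mm); refusing to resample"
            )
        dz = float(gaps.mean())
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0) or 1.0)

    dr, dc = (float(v) for v in slices[0].PixelSpacing)  # (row spacing, column spacing)
    volume = np.stack([ds.pixel_array for ds in slices], axis=0)  # (slice, row, col)

    ipp0 = np.asarray(slices[0].ImagePositionPatient, dtype=float)
    # Affine columns map (slice, row, col) index steps to LPS mm.
    lps = np.eye(4)
    lps[:3, 0] = normal * dz
    lps[:3, 1] = col_dir * dr
    lps[:3, 2] = row_dir * dc
    lps[:3, 3] = ipp0
    # nibabel affines are RAS: flip the first two world axes.
    ras = np.diag([-1.0, -1.0, 1.0, 1.0]) @ lps
    return _canonicalize(volume, ras)
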