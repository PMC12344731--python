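"""Canonical 3D volume/mask data model and voxel-level primitives.

All volumes in this package live on a single canonical axis convention:

* axis 0 (X) increases toward the patient's **left**,
* axis 1 (Y) increases toward the patient's **posterior**,
* axis 2 (Z) increases toward the patient's **superior**.

File readers (:mod:`thoravol.io`) reorient on load so that every downstream
rule — in particular the anterior/posterior test of the lesion-location
cascade — is deterministic regardless of how a file was stored on disk.
Voxel indices are 0-based and bounding boxes are half-open ``[lower, upper)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "CANONICAL_AXCODES",
    "VoxelSpacing",
    "ImageVolume",
    "LabelMask",
    "BoundingBox3D",
    "LesionComponent",
    "connected_structure",
    "connected_components",
    "mask_volume_cm3",
]

#: Canonical orientation code: X→patient left, Y→posterior, Z→superior.
CANONICAL_AXCODES = ("L", "P", "S")


@dataclass(frozen=True)
class VoxelSpacing:
    """Physical edge lengths of one voxel, in millimeters."""

    dx: float
    dy: float
    dz: float

    def __post_init__(self) -> None:
        for name in ("dx", "dy", "dz"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"VoxelSpacing.{name} must be a positive finite number, got {v!r}")

    @property
    def voxel_volume_cm3(self) -> float:
        """Volume of a single voxel in cm³ (mm³ / 1000)."""
        return self.dx * self.dy * self.dz / 1000.0

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.dx, self.dy, self.dz)

    def isclose(self, other: "VoxelSpacing", rtol: float = 1e-5) -> bool:
        return bool(np.allclose(self.as_tuple(), other.as_tuple(), rtol=rtol))


def _check_3d(arr: np.ndarray, what: str) -> None:
    if arr.ndim != 3:
        raise ValueError(f"{what} must be a 3D array, got ndim={arr.ndim}")
    if min(arr.shape) < 1:
        raise ValueError(f"{what} must have at least 1 voxel per axis, got shape {arr.shape}")


@dataclass
class ImageVolume:
    """A 3D scalar CT volume (HU-like intensities) with physical metadata.

    ``origin`` is the physical position (mm, RAS frame as used by the NIfTI
    affine) of voxel (0, 0, 0); ``orientation`` records the axis convention
    the voxel array obeys — always ``"LPS"`` after canonicalization on load.
    """

    voxels: np.ndarray
    spacing: VoxelSpacing
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = "".join(CANONICAL_AXCODES)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        _check_3d(self.voxels, "ImageVolume.voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def same_geometry(self, other: "ImageVolume | LabelMask") -> bool:
        return self.shape == other.shape and self.spacing.isclose(other.spacing)


@dataclass
class LabelMask:
    """Integer-labeled 3D mask geometrically paired to an :class:`ImageVolume`.

    Label 0 is background.  A *binary* mask has labels ⊆ {0, 1}; several
    operations treat any nonzero voxel as foreground.
    """

    labels: np.ndarray
    spacing: VoxelSpacing
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = "".join(CANONICAL_AXCODES)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        _check_3d(self.labels, "LabelMask.labels")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.issubdtype(self.labels.dtype, np.bool_):
                raise ValueError(f"LabelMask.labels must be integer-typed, got {self.labels.dtype}")
            self.labels = self.labels.astype(np.int16)
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("LabelMask.labels must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def foreground(self) -> np.ndarray:
        """Boolean array of nonzero voxels."""
        return self.labels != 0

    def is_binary(self) -> bool:
        return bool(np.isin(np.unique(self.labels), (0, 1)).all())

    def same_geometry(self, other: "ImageVolume | LabelMask") -> bool:
        return self.shape == other.shape and self.spacing.isclose(other.spacing)

    def require_same_geometry(self, other: "ImageVolume | LabelMask", what: str = "mask") -> None:
        if self.shape != other.shape:
            raise ValueError(
                f"geometry mismatch: {what} shapes differ ({self.shape} vs {other.shape})"
            )
        if not self.spacing.isclose(other.spacing):
            raise ValueError(
                f"geometry mismatch: {what} spacings differ "
                f"({self.spacing.as_tuple()} vs {other.spacing.as_tuple()})"
            )

    def with_labels(self, labels: np.ndarray) -> "LabelMask":
        """New mask with the same geometry and different voxel content."""
        return LabelMask(labels, self.spacing, self.origin, self.orientation)


@dataclass(frozen=True)
class BoundingBox3D:
    """Axis-aligned voxel-index box, half-open ``[lower, upper)`` per axis."""

    lower: tuple[int, int, int]
    upper: tuple[int, int, int]

    def __post_init__(self) -> None:
        for lo, hi in zip(self.lower, self.upper):
            if lo >= hi:
                raise ValueError(f"BoundingBox3D requires lower < upper on every axis, got {self}")

    @classmethod
    def from_mask(cls, foreground: np.ndarray) -> "BoundingBox3D":
        """Tight box around the nonzero voxels of ``foreground``."""
        coords = np.nonzero(foreground)
        if coords[0].size == 0:
            raise ValueError("cannot take the bounding box of an empty mask")
        lower = tuple(int(c.min()) for c in coords)
        upper = tuple(int(c.max()) + 1 for c in coords)
        return cls(lower, upper)  # type: ignore[arg-type]

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(hi - lo for lo, hi in zip(self.lower, self.upper))  # type: ignore[return-value]

    @property
    def center(self) -> tuple[float, float, float]:
        """Box center ``(lower + upper − 1) / 2`` per axis; may be fractional."""
        return tuple((lo + hi - 1) / 2.0 for lo, hi in zip(self.lower, self.upper))  # type: ignore[return-value]

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in zip(self.lower, self.upper))  # type: ignore[return-value]

    def expand(self, margin: int | Sequence[int]) -> "BoundingBox3D":
        m = np.broadcast_to(np.asarray(margin, dtype=int), (3,))
        return BoundingBox3D(
            tuple(int(lo - mm) for lo, mm in zip(self.lower, m)),  # type: ignore[arg-type]
            tuple(int(hi + mm) for hi, mm in zip(self.upper, m)),  # type: ignore[arg-type]
        )

    def clip(self, shape: Sequence[int]) -> "BoundingBox3D":
        lower = tuple(max(0, min(lo, s)) for lo, s in zip(self.lower, shape))
        upper = tuple(max(0, min(hi, s)) for hi, s in zip(self.upper, shape))
        for lo, hi in zip(lower, upper):
            if lo >= hi:
                raise ValueError(f"bounding box {self} is disjoint from volume of shape {tuple(shape)}")
        return BoundingBox3D(lower, upper)  # type: ignore[arg-type]

    def intersects_volume(self, shape: Sequence[int]) -> bool:
        return all(lo < s and hi > 0 for lo, hi, s in zip(self.lower, self.upper, shape))

    def contains_point(self, idx: Sequence[int]) -> bool:
        return all(lo <= v < hi for v, lo, hi in zip(idx, self.lower, self.upper))


@dataclass
class LesionComponent:
    """One connected tumor region: its voxels, size and bounding box."""

    component_id: int
    voxel_indices: np.ndarray  # (n, 3) int array of voxel indices
    bbox: BoundingBox3D

    def __post_init__(self) -> None:
        self.voxel_indices = np.asarray(self.voxel_indices, dtype=np.intp).reshape(-1, 3)
        if self.voxel_indices.shape[0] < 1:
            raise ValueError("LesionComponent must contain at least one voxel")

    @property
    def size(self) -> int:
        """Voxel count."""
        return int(self.voxel_indices.shape[0])

    @property
    def center(self) -> tuple[float, float, float]:
        """Bounding-box center (Xt, Yt, Zt)."""
        return self.bbox.center

    def linear_indices(self, shape: Sequence[int]) -> np.ndarray:
        """Sorted linear (raveled) voxel indices within a volume of ``shape``."""
        lin = np.ravel_multi_index(tuple(self.voxel_indices.T), tuple(shape))
        return np.sort(lin)

    def to_mask(self, shape: Sequence[int]) -> np.ndarray:
        out = np.zeros(tuple(shape), dtype=bool)
        out[tuple(self.voxel_indices.T)] = True
        return out

    def volume_cm3(self, spacing: VoxelSpacing) -> float:
        return self.size * spacing.voxel_volume_cm3


_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def connected_structure(connectivity: int) -> np.ndarray:
    """3×3×3 structuring element for 6-, 18- or 26-neighborhood connectivity."""
    try:
        rank = _CONNECTIVITY_RANK[int(connectivity)]
    except KeyError:
        raise ValueError(f"connectivity must be one of 6, 18, 26; got {connectivity!r}") from None
    return ndimage.generate_binary_structure(3, rank)


def connected_components(mask: LabelMask | np.ndarray, connectivity: int = 26) -> list[LesionComponent]:
    """Extract connected foreground components of a binary mask.

    Nonzero voxels are treated as foreground.  Components are returned in a
    deterministic order: descending voxel count, ties broken by the smallest
    linear voxel index.  ``component_id`` is the 1-based rank in that order.
    """
    arr = mask.labels if isinstance(mask, LabelMask) else np.asarray(mask)
    fg = arr != 0
    labeled, n = ndimage.label(fg, structure=connected_structure(connectivity))
    if n == 0:
        return []
    objects = ndimage.find_objects(labeled)
    comps: list[tuple[int, int, np.ndarray, BoundingBox3D]] = []
    for lab, slc in enumerate(objects, start=1):
        sub = labeled[slc] == lab
        local = np.argwhere(sub)
        offset = np.array([s.start for s in slc], dtype=np.intp)
        vox = local + offset
        bbox = BoundingBox3D(
            tuple(int(s.start) for s in slc),  # type: ignore[arg-type]
            tuple(int(s.stop) for s in slc),  # type: ignore[arg-type]
        )
        first_linear = int(np.ravel_multi_index(tuple(vox.T), fg.shape).min())
        comps.append((vox.shape[0], first_linear, vox, bbox))
    comps.sort(key=lambda t: (-t[0], t[1]))
    return [
        LesionComponent(component_id=i, voxel_indices=vox, bbox=bbox)
        for i, (_, _, vox, bbox) in enumerate(comps, start=1)
    ]


def mask_volume_cm3(mask: LabelMask) -> float:
    """Foreground volume in cm³: (nonzero voxel count) × voxel volume."""
    return int(np.count_nonzero(mask.labels)) * mask.spacing.voxel_volume_cm3
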