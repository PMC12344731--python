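"""Physician-guided cropping: per-lesion boxes and the lung-relative grid.

Two region-of-interest strategies are implemented.  *Box crops* surround the
maximal extent of an individual lesion, optionally with a small context
margin.  *Cell crops* come from a d×d×d grid (5×5×5 by default) spanning the
bounding box of the lung mask; cells selected for a patient are persisted in
a JSON store and re-applied to later scans by grid *index* — the grid is
rebuilt on each scan's own lungs, which is what keeps cell addresses
approximately anatomically corresponding across scans without registration.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .core import BoundingBox3D, ImageVolume, LabelMask

logger = logging.getLogger(__name__)

__all__ = [
    "GridCell",
    "LungGrid",
    "CropRegion",
    "CellSelectionRecord",
    "SelectionStore",
    "build_lung_grid",
    "cell_of_voxel",
    "cells_containing_mask",
    "box_crop",
    "cell_crop",
    "paste_crop",
    "apply_selection",
]

SELECTION_SCHEMA_VERSION = 1


@dataclass(frozen=True, order=True)
class GridCell:
    """One addressable cell of a lung grid, indexed (i, j, k) per axis."""

    i: int
    j: int
    k: int

    @property
    def label(self) -> str:
        return f"X{self.i}-Y{self.j}-Z{self.k}"

    @classmethod
    def from_label(cls, label: str) -> "GridCell":
        parts = label.split("-")
        if len(parts) != 3 or not all(p[:1] in "XYZ" for p in parts):
            raise ValueError(f"malformed grid-cell label {label!r}")
        return cls(int(parts[0][1:]), int(parts[1][1:]), int(parts[2][1:]))

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.i, self.j, self.k)


@dataclass
class LungGrid:
    """A d×d×d partition of the lung bounding box.

    ``boundaries`` holds, per axis, ``divisions + 1`` real-valued cut
    positions spanning ``[lower, upper]`` of the (optionally padded) lung
    bounding box.  Voxel assignment is half-open per interval with the last
    interval closed, so the cells tile the box exactly.
    """

    lung_bbox: BoundingBox3D
    divisions: int
    boundaries: tuple[np.ndarray, np.ndarray, np.ndarray]

    def __post_init__(self) -> None:
        if self.divisions < 1:
            raise ValueError("divisions must be >= 1")
        for ax, b in enumerate(self.boundaries):
            if len(b) != self.divisions + 1:
                raise ValueError(f"axis {ax}: expected {self.divisions + 1} boundaries, got {len(b)}")
            if not np.all(np.diff(b) > 0):
                raise ValueError(f"axis {ax}: boundaries must be strictly increasing")

    def cells(self) -> Iterator[GridCell]:
        d = self.divisions
        for i in range(d):
            for j in range(d):
                for k in range(d):
                    yield GridCell(i, j, k)

    def cell_bbox(self, cell: GridCell) -> BoundingBox3D:
        """Voxel extent of a cell: real boundaries rounded outward, half-open.

        Adjacent cells share no voxel and the union of all cells is exactly
        the lung bounding box.
        """
        d = self.divisions
        if not all(0 <= v < d for v in cell.as_tuple()):
            raise ValueError(f"cell {cell} outside grid of {d} divisions")
        lower, upper = [], []
        for ax, idx in enumerate(cell.as_tuple()):
            b = self.boundaries[ax]
            lo = self.lung_bbox.lower[ax] if idx == 0 else int(math.ceil(b[idx]))
            hi = self.lung_bbox.upper[ax] if idx == d - 1 else int(math.ceil(b[idx + 1]))
            lower.append(lo)
            upper.append(hi)
        return BoundingBox3D(tuple(lower), tuple(upper))  # type: ignore[arg-type]


@dataclass
class CropRegion:
    """A cropped sub-volume plus where it came from.

    ``provenance`` records the crop kind (``"box"`` or ``"cell"``) and
    identifying metadata (lesion id or cell label, grid parameters).
    """

    bbox: BoundingBox3D
    image_patch: np.ndarray
    mask_patch: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if tuple(self.image_patch.shape) != self.bbox.shape:
            raise ValueError(
                f"image patch shape {self.image_patch.shape} != bbox extents {self.bbox.shape}"
            )
        if self.mask_patch is not None and tuple(self.mask_patch.shape) != self.bbox.shape:
            raise ValueError(
                f"mask patch shape {self.mask_patch.shape} != bbox extents {self.bbox.shape}"
            )

    @property
    def kind(self) -> str:
        return str(self.provenance.get("kind", "box"))


def build_lung_grid(
    lung_mask: LabelMask,
    divisions: int = 5,
    pad_fraction: float | Sequence[float] = 0.0,
) -> LungGrid:
    """Build the grid over the (optionally padded) lung bounding box.

    ``pad_fraction`` expands the tight lung bounding box by that fraction of
    the axis span on *each side*, clipped to the volume bounds.
    """
    fg = lung_mask.foreground
    if not fg.any():
        raise ValueError("cannot build a lung grid from an empty lung mask")
    tight = BoundingBox3D.from_mask(fg)
    pads = np.broadcast_to(np.asarray(pad_fraction, dtype=float), (3,))
    lower, upper = [], []
    for ax in range(3):
        span = tight.upper[ax] - tight.lower[ax]
        pad = int(round(pads[ax] * span))
        lower.append(max(0, tight.lower[ax] - pad))
        upper.append(min(lung_mask.shape[ax], tight.upper[ax] + pad))
    bbox = BoundingBox3D(tuple(lower), tuple(upper))  # type: ignore[arg-type]
    boundaries = tuple(
        np.linspace(bbox.lower[ax], bbox.upper[ax], divisions + 1) for ax in range(3)
    )
    return LungGrid(bbox, divisions, boundaries)  # type: ignore[arg-type]


def cell_of_voxel(grid: LungGrid, voxel_index: Sequence[int]) -> GridCell | None:
    """Grid cell containing a voxel, or ``None`` when outside the lung bbox.

    Interval assignment is half-open (a voxel sitting exactly on an interior
    boundary belongs to the *upper* interval); the last interval is closed.
    """
    idx = []
    for ax, v in enumerate(voxel_index):
        if not (grid.lung_bbox.lower[ax] <= v < grid.lung_bbox.upper[ax]):
            return None
        b = grid.boundaries[ax]
        i = int(np.searchsorted(b, v, side="right")) - 1
        idx.append(min(i, grid.divisions - 1))
    return GridCell(*idx)


def cells_containing_mask(grid: LungGrid, lesion_mask: LabelMask) -> set[GridCell]:
    """Exactly the cells containing ≥1 foreground voxel of ``lesion_mask``.

    A lesion spanning several cells yields several cells.  Lesion voxels
    outside the lung bounding box contribute nothing; a lesion entirely
    outside yields the empty set plus a logged warning.
    """
    coords = np.argwhere(lesion_mask.foreground)
    if coords.shape[0] == 0:
        return set()
    inside = np.ones(coords.shape[0], dtype=bool)
    for ax in range(3):
        inside &= (coords[:, ax] >= grid.lung_bbox.lower[ax]) & (
            coords[:, ax] < grid.lung_bbox.upper[ax]
        )
    if not inside.any():
        logger.warning("lesion mask lies entirely outside the lung grid bounding box")
        return set()
    coords = coords[inside]
    per_axis = []
    for ax in range(3):
        i = np.searchsorted(grid.boundaries[ax], coords[:, ax], side="right") - 1
        per_axis.append(np.minimum(i, grid.divisions - 1))
    triples = np.unique(np.stack(per_axis, axis=1), axis=0)
    return {GridCell(int(i), int(j), int(k)) for i, j, k in triples}


def box_crop(
    image: ImageVolume,
    lesion_bbox: BoundingBox3D,
    margin_voxels: int | Sequence[int] = 2,
    mask: LabelMask | None = None,
    provenance: dict | None = None,
) -> CropRegion:
    """Crop a box surrounding one lesion's maximal extent plus a margin.

    The crop bbox is the lesion bbox expanded by ``margin_voxels`` per side
    and clipped to the volume; one box corresponds to one lesion.
    """
    if not lesion_bbox.intersects_volume(image.shape):
        raise ValueError(f"lesion bbox {lesion_bbox} is disjoint from volume of shape {image.shape}")
    bbox = lesion_bbox.expand(margin_voxels).clip(image.shape)
    prov = {"kind": "box", "margin_voxels": margin_voxels}
    if provenance:
        prov.update(provenance)
    return CropRegion(
        bbox=bbox,
        image_patch=np.ascontiguousarray(image.voxels[bbox.slices]),
        mask_patch=None if mask is None else np.ascontiguousarray(mask.labels[bbox.slices]),
        provenance=prov,
    )


def cell_crop(
    image: ImageVolume,
    grid: LungGrid,
    cell: GridCell,
    mask: LabelMask | None = None,
    provenance: dict | None = None,
) -> CropRegion:
    """Crop the voxel extent of one grid cell."""
    bbox = grid.cell_bbox(cell)
    prov = {"kind": "cell", "cell": cell.label, "divisions": grid.divisions}
    if provenance:
        prov.update(provenance)
    return CropRegion(
        bbox=bbox,
        image_patch=np.ascontiguousarray(image.voxels[bbox.slices]),
        mask_patch=None if mask is None else np.ascontiguousarray(mask.labels[bbox.slices]),
        provenance=prov,
    )


def paste_crop(
    crop_mask: np.ndarray,
    bbox: BoundingBox3D,
    canvas_shape: Sequence[int] | None = None,
    out: np.ndarray | None = None,
) -> np.ndarray:
    """Paste a binary patch back onto a scan-sized canvas.

    The canvas is zero outside the bbox; repeated pastes onto the same ``out``
    array combine by voxelwise OR (the segmentation task is binary, so
    overlapping crop predictions union).  Returns the canvas.
    """
    crop_mask = np.asarray(crop_mask)
    if tuple(crop_mask.shape) != bbox.shape:
        raise ValueError(f"patch shape {crop_mask.shape} != bbox extents {bbox.shape}")
    if out is None:
        if canvas_shape is None:
            raise ValueError("paste_crop needs canvas_shape or an existing canvas (out=)")
        out = np.zeros(tuple(canvas_shape), dtype=np.uint8)
    for lo, hi, s in zip(bbox.lower, bbox.upper, out.shape):
        if lo < 0 or hi > s:
            raise ValueError(f"bbox {bbox} exceeds canvas of shape {out.shape}")
    region = out[bbox.slices]
    out[bbox.slices] = np.logical_or(region != 0, crop_mask != 0).astype(out.dtype)
    return out


# ---------------------------------------------------------------------------
# Persistent per-patient cell selections
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellSelectionRecord:
    """The grid cells a physician selected for one patient, for reuse."""

    patient_id: str
    cells: frozenset[GridCell]
    source_scan_id: str
    created: str = field(default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat())

    def __post_init__(self) -> None:
        if not self.cells:
            raise ValueError("a cell selection record must contain at least one cell")

    def to_json_obj(self) -> dict:
        return {
            "cells": sorted(c.as_tuple() for c in self.cells),
            "source_scan_id": self.source_scan_id,
            "created": self.created,
        }

    @classmethod
    def from_json_obj(cls, patient_id: str, obj: dict) -> "CellSelectionRecord":
        return cls(
            patient_id=patient_id,
            cells=frozenset(GridCell(*map(int, c)) for c in obj["cells"]),
            source_scan_id=str(obj["source_scan_id"]),
            created=str(obj["created"]),
        )


class SelectionStore:
    """JSON-file store of per-patient cell selections.

    Layout: ``{"schema_version": 1, "patients": {pid: {"active": {...},
    "history": [...]}}}``.  A new save replaces the active record and appends
    the previous one to history.
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)

    def _load(self) -> dict:
        if not self.path.exists():
            return {"schema_version": SELECTION_SCHEMA_VERSION, "patients": {}}
        data = json.loads(self.path.read_text())
        version = data.get("schema_version")
        if version != SELECTION_SCHEMA_VERSION:
            raise ValueError(f"{self.path}: unsupported selection-store schema version {version!r}")
        return data

    def save_selection(self, record: CellSelectionRecord) -> None:
        data = self._load()
        entry = data["patients"].setdefault(record.patient_id, {"active": None, "history": []})
        if entry.get("active"):
            entry["history"].append(entry["active"])
        entry["active"] = record.to_json_obj()
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.path.write_text(json.dumps(data, indent=2, sort_keys=True))

    def load_selection(self, patient_id: str) -> CellSelectionRecord:
        data = self._load()
        entry = data["patients"].get(patient_id)
        if not entry or not entry.get("active"):
            raise KeyError(f"no cell selection stored for patient {patient_id!r} in {self.path}")
        return CellSelectionRecord.from_json_obj(patient_id, entry["active"])

    def history(self, patient_id: str) -> list[CellSelectionRecord]:
        """All records ever saved for the patient, oldest first, active last."""
        data = self._load()
        entry = data["patients"].get(patient_id)
        if not entry:
            return []
        records = [CellSelectionRecord.from_json_obj(patient_id, o) for o in entry.get("history", [])]
        if entry.get("active"):
            records.append(CellSelectionRecord.from_json_obj(patient_id, entry["active"]))
        return records

    def patients(self) -> list[str]:
        return sorted(self._load()["patients"])


def apply_selection(
    new_scan_lung_mask: LabelMask,
    record: CellSelectionRecord,
    image: ImageVolume,
    mask: LabelMask | None = None,
    divisions: int = 5,
    pad_fraction: float | Sequence[float] = 0.0,
) -> list[CropRegion]:
    """Re-apply a stored cell selection to a new scan.

    The grid is rebuilt on the *new* scan's lung mask and the stored cell
    indices — not physical coordinates — are cropped, which is how cell
    addresses carry over between scans of the same patient.  When a lesion
    mask is supplied, lesion voxels falling outside the union of selected
    cells trigger a coverage warning (the tumor may have outgrown the stored
    selection); crops are still returned.
    """
    grid = build_lung_grid(new_scan_lung_mask, divisions=divisions, pad_fraction=pad_fraction)
    crops = [
        cell_crop(image, grid, cell, mask=mask, provenance={"patient_id": record.patient_id})
        for cell in sorted(record.cells)
    ]
    if mask is not None:
        covered = np.zeros(mask.shape, dtype=bool)
        for crop in crops:
            covered[crop.bbox.slices] = True
        outside = int(np.count_nonzero(mask.foreground & ~covered))
        if outside:
            logger.warning(
                "patient %s: %d lesion voxels fall outside the %d stored grid cells "
                "(selection may need updating)",
                record.patient_id,
                outside,
                len(record.cells),
            )
    return crops
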