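"""Rule-based anatomical classification of thoracic lesions.

Each lesion is labeled parenchymal, mediastinal or pleural by a fixed
three-step cascade driven only by the lung segmentation:

1. a lesion that does **not** border the lung boundary is parenchymal
   (it sits inside lung tissue);
2. a bordering lesion whose bounding-box center (Xt, Yt, Zt) lies in the
   central X band (x25 ≤ Xt ≤ x75 of lung voxel X coordinates) and anterior
   of the y75 lung coordinate (Yt ≤ y75 on the canonical
   anterior→posterior-increasing Y axis) is mediastinal — thymic tumors
   arise in the anterior mediastinum, between the lungs;
3. everything else is pleural.

The cascade is total and exclusive: every lesion receives exactly one label.
Because step 2 compares against the *anterior* lung band, results depend on
axis orientation; the canonical-orientation load path makes them invariant
to how files were stored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import LabelMask, LesionComponent, connected_components, connected_structure

logger = logging.getLogger(__name__)

__all__ = [
    "PARENCHYMAL",
    "MEDIASTINAL",
    "PLEURAL",
    "LungQuartiles",
    "LesionLocation",
    "lung_quartiles",
    "lung_boundary_shell",
    "borders_lung_boundary",
    "classify_lesion",
    "classify_all",
]

PARENCHYMAL = "parenchymal"
MEDIASTINAL = "mediastinal"
PLEURAL = "pleural"

RULE_PARENCHYMAL = "no-lung-boundary-contact"
RULE_MEDIASTINAL = "central-X-band-and-anterior-of-y75"
RULE_PLEURAL = "unclassified-default"


@dataclass(frozen=True)
class LungQuartiles:
    """Coordinate quartiles of lung foreground voxels (voxel index units).

    ``x25``/``x75`` bracket the central left–right band (each lung holds half
    the voxel mass, so x25 falls inside one lung and x75 inside the other);
    ``y75`` marks the posterior quartile boundary of the lungs.
    """

    x25: float
    x75: float
    y75: float

    def __post_init__(self) -> None:
        if self.x25 > self.x75:
            raise ValueError(f"x25 ({self.x25}) must be <= x75 ({self.x75})")


@dataclass(frozen=True)
class LesionLocation:
    """Outcome of the cascade for one lesion."""

    category: str
    rule_fired: str
    center_used: tuple[float, float, float]

    def __post_init__(self) -> None:
        expected = {
            RULE_PARENCHYMAL: PARENCHYMAL,
            RULE_MEDIASTINAL: MEDIASTINAL,
            RULE_PLEURAL: PLEURAL,
        }
        if expected.get(self.rule_fired) != self.category:
            raise ValueError(f"category {self.category!r} inconsistent with rule {self.rule_fired!r}")


def lung_quartiles(lung_mask: LabelMask) -> LungQuartiles:
    """Percentiles (linear interpolation) over lung foreground voxel coordinates."""
    coords = np.argwhere(lung_mask.foreground)
    if coords.shape[0] == 0:
        raise ValueError("cannot compute quartiles of an empty lung mask")
    x25, x75 = np.percentile(coords[:, 0], [25, 75])
    y75 = float(np.percentile(coords[:, 1], 75))
    return LungQuartiles(float(x25), float(x75), y75)


def lung_boundary_shell(lung_mask: LabelMask) -> LabelMask:
    """One-voxel boundary shell of the lung: foreground voxels with a
    six-neighbor outside the foreground (volume-edge voxels count as boundary)."""
    fg = lung_mask.foreground
    eroded = ndimage.binary_erosion(fg, structure=connected_structure(6), border_value=0)
    return lung_mask.with_labels((fg & ~eroded).astype(np.uint8))


def borders_lung_boundary(
    lesion: LesionComponent,
    shell: LabelMask,
    strict: bool = False,
) -> bool:
    """Does the lesion touch the lung surface?

    Default mode: true iff any lesion voxel is a shell voxel *or is
    26-adjacent to one* — this admits lesions lying just outside the lung
    mask, which is where pleural and mediastinal disease mostly sits.
    ``strict=True`` requires the lesion to intersect the shell itself.
    """
    shape = shell.shape
    for v, s in zip(lesion.bbox.upper, shape):
        if v > s:
            raise ValueError(f"lesion bbox {lesion.bbox} exceeds lung volume shape {shape}")
    pad = 0 if strict else 1
    lower = [max(0, lo - pad) for lo in lesion.bbox.lower]
    upper = [min(s, hi + pad) for hi, s in zip(lesion.bbox.upper, shape)]
    sub = tuple(slice(lo, hi) for lo, hi in zip(lower, upper))
    lesion_patch = np.zeros(tuple(hi - lo for lo, hi in zip(lower, upper)), dtype=bool)
    rel = lesion.voxel_indices - np.asarray(lower, dtype=np.intp)
    lesion_patch[tuple(rel.T)] = True
    if not strict:
        lesion_patch = ndimage.binary_dilation(lesion_patch, structure=connected_structure(26))
    return bool(np.any(lesion_patch & (shell.labels[sub] != 0)))


def classify_lesion(
    lesion: LesionComponent,
    lung_mask: LabelMask,
    quartiles: LungQuartiles | None = None,
    shell: LabelMask | None = None,
    strict_border: bool = False,
) -> LesionLocation:
    """Run the three-step cascade on one lesion.

    ``quartiles`` and ``shell`` may be precomputed once per scan and shared
    across lesions; they are derived from ``lung_mask`` otherwise.
    """
    if quartiles is None:
        quartiles = lung_quartiles(lung_mask)
    if shell is None:
        shell = lung_boundary_shell(lung_mask)
    center = lesion.center

    if not borders_lung_boundary(lesion, shell, strict=strict_border):
        overlap = lung_mask.labels[tuple(lesion.voxel_indices.T)]
        if not np.any(overlap):
            logger.warning(
                "lesion %d labeled parenchymal but shares no voxel with the lung mask "
                "(it is far from the lungs; the literal rule still applies)",
                lesion.component_id,
            )
        return LesionLocation(PARENCHYMAL, RULE_PARENCHYMAL, center)

    xt, yt, _ = center
    if quartiles.x25 <= xt <= quartiles.x75 and yt <= quartiles.y75:
        return LesionLocation(MEDIASTINAL, RULE_MEDIASTINAL, center)
    return LesionLocation(PLEURAL, RULE_PLEURAL, center)


def classify_all(
    gt_mask: LabelMask,
    lung_mask: LabelMask,
    connectivity: int = 26,
    strict_border: bool = False,
) -> list[tuple[LesionComponent, LesionLocation]]:
    """Classify every lesion of a ground-truth mask.

    A binary mask is split into connected components under ``connectivity``;
    a multi-label mask is treated as one lesion per label (labels may touch).
    """
    gt_mask.require_same_geometry(lung_mask, "lesion/lung masks")
    labels = np.unique(gt_mask.labels)
    labels = labels[labels != 0]
    if labels.size == 0:
        return []
    if labels.size == 1 and labels[0] == 1:
        lesions = connected_components(gt_mask, connectivity=connectivity)
    else:
        lesions = []
        for lab in sorted(int(v) for v in labels):
            vox = np.argwhere(gt_mask.labels == lab)
            lesions.append(LesionComponent(component_id=lab, voxel_indices=vox, bbox=_bbox_of(vox)))
    quartiles = lung_quartiles(lung_mask)
    shell = lung_boundary_shell(lung_mask)
    return [
        (les, classify_lesion(les, lung_mask, quartiles=quartiles, shell=shell, strict_border=strict_border))
        for les in lesions
    ]


def _bbox_of(vox: np.ndarray):
    from .core import BoundingBox3D

    return BoundingBox3D(
        tuple(int(v) for v in vox.min(axis=0)),  # type: ignore[arg-type]
        tuple(int(v) + 1 for v in vox.max(axis=0)),  # type: ignore[arg-type]
    )
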