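"""Seeded synthetic thoracic CT phantoms with known-truth lesions.

The phantom is a deliberately simple thorax: a soft-tissue background
containing two ellipsoidal lung fields (left/right of the midline, air-like
intensity) separated by a mediastinal gap, into which lesions of the three
anatomical categories are carved with exactly known voxel truth:

* **parenchymal** — a sphere strictly interior to one lung, kept at least
  two voxels clear of the lung surface so the boundary-contact rule is
  unambiguous;
* **mediastinal** — an ellipsoid in the inter-lung gap that touches the
  inner (medial) lung surfaces, with bounding-box center in the central
  X band and anterior of the lungs' y75 coordinate;
* **pleural** — a curvilinear cap: a thin spherical-shell segment hugging a
  band of the outer lung surface (the shape pleural metastases take), placed
  laterally by default or at the posterior midline on request.

Intensities are HU-like but arbitrary (the toolkit never interprets absolute
HU): soft tissue ≈ 40, lung ≈ −700, lesions ≈ background + contrast, plus
independent per-voxel Gaussian noise.  A fixed seed reproduces the phantom
byte for byte.  Each generated lesion is validated against the location
cascade's own geometric requirements and generation fails loudly, naming the
lesion, if a spec cannot be realized unambiguously.

The default geometry is 96³ voxels at 2 mm isotropic spacing — large enough
for lesions of clinically plausible volume (a few to tens of cm³), small
enough that whole-cohort runs complete in seconds to minutes on one CPU.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import BoundingBox3D, ImageVolume, LabelMask, LesionComponent, VoxelSpacing
from .cropping import CropRegion
from .localization import (
    MEDIASTINAL,
    PARENCHYMAL,
    PLEURAL,
    classify_lesion,
    lung_boundary_shell,
    lung_quartiles,
)

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "PhantomOutput",
    "generate_phantom",
    "generate_cohort",
    "generate_longitudinal_pair",
    "reference_segmenter",
    "radius_for_volume_cm3",
]


@dataclass(frozen=True)
class LesionSpec:
    """One lesion to carve: anatomical category, size and contrast.

    ``size_voxels`` is the sphere radius (parenchymal), the mean semi-axis
    (mediastinal ellipsoid) or the cap band half-extent (pleural), in voxel
    units.  ``contrast`` is the lesion-minus-background intensity offset.
    ``placement`` tunes where within the category the lesion sits:
    parenchymal/mediastinal accept ``"default"``; pleural accepts
    ``"lateral"`` (default) or ``"posterior_midline"`` (a posterior cap whose
    center falls behind y75 — still pleural, via the cascade's Y test).
    """

    category: str
    size_voxels: float = 4.0
    contrast: float = 20.0
    placement: str = "default"
    center_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.category not in (PARENCHYMAL, MEDIASTINAL, PLEURAL):
            raise ValueError(f"unknown lesion category {self.category!r}")
        if self.size_voxels <= 0:
            raise ValueError("size_voxels must be positive")

    def grown(self, volume_factor: float) -> "LesionSpec":
        """Spec for the same lesion grown by a volume factor (linear scale ∛)."""
        return replace(self, size_voxels=self.size_voxels * volume_factor ** (1.0 / 3.0))


def _default_lesions() -> tuple[LesionSpec, ...]:
    return (
        LesionSpec(PARENCHYMAL, size_voxels=4.0),
        LesionSpec(MEDIASTINAL, size_voxels=7.0),
        LesionSpec(PLEURAL, size_voxels=10.0),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom scan."""

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    lung_centers: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (28.0, 50.0, 48.0),
        (68.0, 50.0, 48.0),
    )
    lung_semiaxes: tuple[float, float, float] = (16.0, 22.0, 30.0)
    background_hu: float = 40.0
    lung_hu: float = -700.0
    fluid_hu: float = 10.0
    noise_sd: float = 4.0
    lesions: tuple[LesionSpec, ...] = field(default_factory=_default_lesions)
    translation: tuple[int, int, int] = (0, 0, 0)
    include_fluid: bool = False
    seed: int = 0

    @property
    def voxel_spacing(self) -> VoxelSpacing:
        return VoxelSpacing(*self.spacing)


@dataclass
class PhantomOutput:
    """A generated phantom: image, masks and the per-lesion truth table.

    ``truth`` columns: label, category, placement, voxel_count, volume_cm3,
    bbox bounds and bounding-box center coordinates.  Volumes are exact voxel
    counts times the voxel volume.
    """

    image: ImageVolume
    lung_mask: LabelMask
    lesion_mask: LabelMask
    truth: pd.DataFrame
    spec: PhantomSpec

    def lesion_component(self, label: int) -> LesionComponent:
        vox = np.argwhere(self.lesion_mask.labels == label)
        if vox.shape[0] == 0:
            raise KeyError(f"no lesion with label {label}")
        bbox = BoundingBox3D(
            tuple(int(v) for v in vox.min(axis=0)),  # type: ignore[arg-type]
            tuple(int(v) + 1 for v in vox.max(axis=0)),  # type: ignore[arg-type]
        )
        return LesionComponent(component_id=label, voxel_indices=vox, bbox=bbox)


def radius_for_volume_cm3(volume_cm3: float, spacing: VoxelSpacing) -> float:
    """Sphere radius (voxel units, isotropic spacing) for a target volume."""
    if abs(spacing.dx - spacing.dy) > 1e-9 or abs(spacing.dx - spacing.dz) > 1e-9:
        raise ValueError("radius_for_volume_cm3 assumes isotropic spacing")
    mm3 = volume_cm3 * 1000.0
    r_mm = (3.0 * mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    return r_mm / spacing.dx


def _grids(shape: Sequence[int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij", sparse=True)


def _ellipsoid_norm(grids, center, semiaxes) -> np.ndarray:
    X, Y, Z = grids
    return np.sqrt(
        ((X - center[0]) / semiaxes[0]) ** 2
        + ((Y - center[1]) / semiaxes[1]) ** 2
        + ((Z - center[2]) / semiaxes[2]) ** 2
    )


def _carve_lesion(
    spec: PhantomSpec,
    lesion: LesionSpec,
    grids,
) -> np.ndarray:
    """Boolean mask for one lesion, per category geometry."""
    t = np.asarray(spec.translation, dtype=float)
    off = np.asarray(lesion.center_offset, dtype=float)
    left, right = (np.asarray(c, dtype=float) + t for c in spec.lung_centers)
    ax = np.asarray(spec.lung_semiaxes, dtype=float)
    r = lesion.size_voxels

    if lesion.category == PARENCHYMAL:
        center = left + np.array([0.0, 0.0, 9.0]) + off
        return _ellipsoid_norm(grids, center, (r, r, r)) <= 1.0

    if lesion.category == MEDIASTINAL:
        midline = (left + right) / 2.0
        center = midline + np.array([0.0, -6.0, 0.0]) + off
        semi = (r, r * 8.0 / 7.0, r * 8.0 / 7.0)
        return _ellipsoid_norm(grids, center, semi) <= 1.0

    # Pleural: thin spherical-shell cap on the lung surface.
    if lesion.placement == "posterior_midline":
        lung_c, band_axis, band_sign = left, 1, +1  # posterior side of left lung
    else:
        lung_c, band_axis, band_sign = right, 0, +1  # lateral (outer) side of right lung
    f = _ellipsoid_norm(grids, lung_c, ax)
    thickness_norm = max(2.0, r / 4.0) / float(ax[band_axis])
    shell = (f >= 0.97) & (f <= 1.0 + thickness_norm)
    X, Y, Z = grids
    coords = (X, Y, Z)
    band = band_sign * (coords[band_axis] - lung_c[band_axis]) >= 0.6 * ax[band_axis]
    for other in range(3):
        if other == band_axis:
            continue
        half = r * (0.9 if other != 2 else 0.7)
        band = band & (np.abs(coords[other] - lung_c[other]) <= half)
    return shell & band


def _validate_lesion(
    label: int,
    lesion_spec: LesionSpec,
    lesion_arr: np.ndarray,
    lung_mask: LabelMask,
    quartiles,
    shell: LabelMask,
    component: LesionComponent,
) -> None:
    """Fail loudly if a carved lesion is not unambiguously its category."""
    name = f"lesion {label} ({lesion_spec.category}, placement={lesion_spec.placement})"
    if component.size < 4:
        raise ValueError(f"unrealizable {name}: only {component.size} voxels carved")
    loc = classify_lesion(component, lung_mask, quartiles=quartiles, shell=shell)
    if loc.category != lesion_spec.category:
        raise ValueError(
            f"unrealizable {name}: location cascade classifies it as {loc.category} "
            f"(center {tuple(round(c, 1) for c in component.center)}, "
            f"x25={quartiles.x25:.1f}, x75={quartiles.x75:.1f}, y75={quartiles.y75:.1f})"
        )
    if lesion_spec.category == PARENCHYMAL:
        # require ≥2-voxel interior clearance: no lesion voxel within the
        # two-voxel-thick boundary band of the lung
        from scipy import ndimage

        from .core import connected_structure

        interior = ndimage.binary_erosion(
            lung_mask.foreground, structure=connected_structure(6), iterations=2, border_value=0
        )
        if not interior[tuple(component.voxel_indices.T)].all():
            raise ValueError(f"unrealizable {name}: lesion reaches within 2 voxels of the lung surface")


def generate_phantom(spec: PhantomSpec, validate: bool = True) -> PhantomOutput:
    """Generate one phantom scan deterministically from its spec."""
    shape = tuple(int(s) for s in spec.shape)
    spacing = spec.voxel_spacing
    grids = _grids(shape)
    t = np.asarray(spec.translation, dtype=float)

    lung = np.zeros(shape, dtype=bool)
    for c in spec.lung_centers:
        lung |= _ellipsoid_norm(grids, np.asarray(c, float) + t, spec.lung_semiaxes) <= 1.0
    if not lung.any():
        raise ValueError("phantom spec produced an empty lung mask (lungs outside the volume?)")

    lesion_labels = np.zeros(shape, dtype=np.int16)
    lesion_arrays: list[np.ndarray] = []
    for idx, les in enumerate(spec.lesions, start=1):
        arr = _carve_lesion(spec, les, grids)
        if not arr.any():
            raise ValueError(
                f"unrealizable lesion {idx} ({les.category}): no voxels carved within the volume"
            )
        lesion_labels[arr] = idx  # later lesions win where specs overlap
        lesion_arrays.append(arr)

    image = np.full(shape, spec.background_hu, dtype=np.float64)
    image[lung] = spec.lung_hu
    if spec.include_fluid:
        fluid_center = (np.asarray(spec.lung_centers[1], float) + t) + np.array([0.0, 10.0, -18.0])
        fluid = _ellipsoid_norm(grids, fluid_center, (6.0, 8.0, 5.0)) <= 1.0
        image[fluid] = spec.fluid_hu
    for idx, les in enumerate(spec.lesions, start=1):
        image[lesion_labels == idx] = spec.background_hu + les.contrast
    rng = np.random.default_rng(spec.seed)
    image = image + rng.normal(0.0, spec.noise_sd, size=shape)

    lung_mask = LabelMask(lung.astype(np.uint8), spacing)
    lesion_mask = LabelMask(lesion_labels, spacing)
    image_vol = ImageVolume(image.astype(np.float32), spacing)

    quartiles = lung_quartiles(lung_mask)
    shell = lung_boundary_shell(lung_mask)
    rows = []
    for idx, les in enumerate(spec.lesions, start=1):
        vox = np.argwhere(lesion_labels == idx)
        if vox.shape[0] == 0:
            raise ValueError(
                f"unrealizable lesion {idx} ({les.category}): fully overwritten by a later lesion"
            )
        bbox = BoundingBox3D(
            tuple(int(v) for v in vox.min(axis=0)),  # type: ignore[arg-type]
            tuple(int(v) + 1 for v in vox.max(axis=0)),  # type: ignore[arg-type]
        )
        comp = LesionComponent(component_id=idx, voxel_indices=vox, bbox=bbox)
        if validate:
            _validate_lesion(idx, les, lesion_arrays[idx - 1], lung_mask, quartiles, shell, comp)
        cx, cy, cz = bbox.center
        rows.append(
            {
                "label": idx,
                "category": les.category,
                "placement": les.placement,
                "voxel_count": comp.size,
                "volume_cm3": comp.size * spacing.voxel_volume_cm3,
                "x0": bbox.lower[0],
                "y0": bbox.lower[1],
                "z0": bbox.lower[2],
                "x1": bbox.upper[0],
                "y1": bbox.upper[1],
                "z1": bbox.upper[2],
                "center_x": cx,
                "center_y": cy,
                "center_z": cz,
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "label", "category", "placement", "voxel_count", "volume_cm3",
            "x0", "y0", "z0", "x1", "y1", "z1", "center_x", "center_y", "center_z",
        ],
    )
    return PhantomOutput(image_vol, lung_mask, lesion_mask, truth, spec)


def _jittered_spec(base: PhantomSpec, rng: np.random.Generator,
                   size_jitter: float, center_jitter: float, translation_jitter: int) -> PhantomSpec:
    lesions = tuple(
        replace(
            les,
            size_voxels=les.size_voxels * float(rng.uniform(1 - size_jitter, 1 + size_jitter)),
            center_offset=tuple(float(v) for v in rng.uniform(-center_jitter, center_jitter, 3)),
        )
        for les in base.lesions
    )
    translation = tuple(
        int(v) for v in np.asarray(base.translation) + rng.integers(-translation_jitter, translation_jitter + 1, 3)
    )
    return replace(
        base,
        lesions=lesions,
        translation=translation,  # type: ignore[arg-type]
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_cohort(
    n_scans: int,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
    size_jitter: float = 0.10,
    center_jitter: float = 1.5,
    translation_jitter: int = 3,
) -> tuple[list[PhantomOutput], pd.DataFrame]:
    """Generate a small cohort of jittered phantom scans plus a manifest.

    Each scan stands for one patient: lesion sizes and positions are jittered
    and the whole thorax is rigidly translated per scan.  The manifest mirrors
    every truth table with scan/patient identifiers prepended.
    """
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    outputs, manifest_rows = [], []
    for i in range(n_scans):
        spec_i = _jittered_spec(base, rng, size_jitter, center_jitter, translation_jitter)
        out = generate_phantom(spec_i)
        outputs.append(out)
        t = out.truth.copy()
        t.insert(0, "patient_id", f"pt{i:03d}")
        t.insert(1, "scan_id", f"scan{i:03d}")
        manifest_rows.append(t)
    manifest = pd.concat(manifest_rows, ignore_index=True)
    return outputs, manifest


def generate_longitudinal_pair(
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
    growth_factor: float = 1.59,
    translation: tuple[int, int, int] = (3, -2, 4),
) -> tuple[PhantomOutput, PhantomOutput]:
    """A baseline/follow-up pair: same lesions grown by ``growth_factor`` in
    volume, whole thorax rigidly translated, fresh noise."""
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    baseline_spec = replace(base, seed=int(rng.integers(0, 2**31 - 1)))
    follow_spec = replace(
        base,
        lesions=tuple(les.grown(growth_factor) for les in base.lesions),
        translation=tuple(int(a + b) for a, b in zip(base.translation, translation)),  # type: ignore[arg-type]
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return generate_phantom(baseline_spec), generate_phantom(follow_spec)


def reference_segmenter(
    crop: CropRegion,
    threshold: float = 50.0,
    min_component_voxels: int = 5,
) -> np.ndarray:
    """Deterministic threshold segmenter honoring the binary tumor/background
    contract: threshold the crop's intensities, drop connected components
    (26-connectivity) smaller than ``min_component_voxels``."""
    if crop.image_patch is None:
        raise ValueError("crop has no image patch to segment")
    binary = np.asarray(crop.image_patch) >= threshold
    if not binary.any() or min_component_voxels <= 1:
        return binary
    from .core import connected_components as _cc

    keep = np.zeros_like(binary)
    for comp in _cc(binary.astype(np.uint8), connectivity=26):
        if comp.size >= min_component_voxels:
            keep[tuple(comp.voxel_indices.T)] = True
    return keep
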