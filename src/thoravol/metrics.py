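"""Segmentation-quality and volumetry metrics.

The evaluation vocabulary:

* **DSC** — Dice similarity coefficient, ``2|G∩S| / (|G| + |S|)``, where G is
  the ground-truth mask, S the inference mask and |·| counts foreground
  voxels.  Both-empty masks score 1.0 (the raters agree there is nothing).
* **AVD** — absolute volume difference, ``v · ||G| − |S||`` in cm³ with v the
  single-voxel volume.  It compares *counts*, not overlap: equal-volume
  disjoint masks score 0, by definition.
* **RVD** — relative volume difference, ``||G| − |S|| / |G|``, dimensionless
  and undefined for empty G (an error here, never silently infinite).

Metrics are grouped three ways: per scan (all tumors pooled as foreground),
per crop (each cropped region one evaluation unit), and per ground-truth
tumor (inference connected components matched to the tumors they overlap;
components overlapping no tumor are false positives and are *ignored* for
tumor- and location-level summaries, though they still depress scan DSC).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy import stats as _scipy_stats

from .core import LabelMask, LesionComponent, VoxelSpacing, connected_components

logger = logging.getLogger(__name__)

__all__ = [
    "MetricRecord",
    "MatchResult",
    "RankSumResult",
    "AxisMeasurement",
    "dsc",
    "avd",
    "rvd",
    "scan_dsc",
    "crop_metrics",
    "match_components",
    "tumor_metrics",
    "location_summary",
    "summarize_records",
    "rank_sum_test",
    "axial_axis_measurements",
]


# ---------------------------------------------------------------------------
# Elementary mask metrics
# ---------------------------------------------------------------------------


def _as_bool(mask: LabelMask | np.ndarray) -> np.ndarray:
    arr = mask.labels if isinstance(mask, LabelMask) else np.asarray(mask)
    return arr != 0


def _check_pair(G: LabelMask | np.ndarray, S: LabelMask | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    g, s = _as_bool(G), _as_bool(S)
    if g.shape != s.shape:
        raise ValueError(f"geometry mismatch: mask shapes differ ({g.shape} vs {s.shape})")
    if isinstance(G, LabelMask) and isinstance(S, LabelMask):
        G.require_same_geometry(S, "G/S masks")
    return g, s


def dsc(G: LabelMask | np.ndarray, S: LabelMask | np.ndarray) -> float:
    """Dice similarity coefficient; 1.0 when both masks are empty."""
    g, s = _check_pair(G, S)
    ng, ns = int(g.sum()), int(s.sum())
    if ng + ns == 0:
        return 1.0
    inter = int(np.count_nonzero(g & s))
    return 2.0 * inter / (ng + ns)


def avd(G: LabelMask | np.ndarray, S: LabelMask | np.ndarray, spacing: VoxelSpacing) -> float:
    """Absolute volume difference in cm³: v·||G|−|S||."""
    g, s = _check_pair(G, S)
    return abs(int(g.sum()) - int(s.sum())) * spacing.voxel_volume_cm3


def rvd(G: LabelMask | np.ndarray, S: LabelMask | np.ndarray) -> float:
    """Relative volume difference ||G|−|S||/|G|; error for empty G."""
    g, s = _check_pair(G, S)
    ng = int(g.sum())
    if ng == 0:
        raise ValueError("RVD is undefined for an empty ground-truth mask (|G| = 0)")
    return abs(ng - int(s.sum())) / ng


# ---------------------------------------------------------------------------
# Evaluation units
# ---------------------------------------------------------------------------


@dataclass
class MetricRecord:
    """One evaluation unit's metrics, tagged with its aggregation level."""

    unit: str  # "scan" | "crop" | "tumor"
    unit_id: str
    dsc: float
    avd_cm3: float
    rvd: float | None
    location: str | None = None  # parenchymal | mediastinal | pleural
    crop_provenance: str | None = None  # "cell" | "box"

    def __post_init__(self) -> None:
        if not (0.0 <= self.dsc <= 1.0 + 1e-12):
            raise ValueError(f"dsc must lie in [0, 1], got {self.dsc}")
        if self.avd_cm3 < 0:
            raise ValueError("avd_cm3 must be >= 0")
        if self.rvd is not None and self.rvd < 0:
            raise ValueError("rvd must be >= 0")

    def to_row(self) -> dict:
        return {
            "unit": self.unit,
            "unit_id": self.unit_id,
            "dsc": self.dsc,
            "avd_cm3": self.avd_cm3,
            "rvd": self.rvd,
            "location": self.location,
            "crop_provenance": self.crop_provenance,
        }


def _record(
    unit: str,
    unit_id: str,
    g: np.ndarray,
    s: np.ndarray,
    spacing: VoxelSpacing,
    location: str | None = None,
    provenance: str | None = None,
) -> MetricRecord:
    ng = int(np.count_nonzero(g))
    return MetricRecord(
        unit=unit,
        unit_id=unit_id,
        dsc=dsc(g, s),
        avd_cm3=avd(g, s, spacing),
        rvd=rvd(g, s) if ng > 0 else None,
        location=location,
        crop_provenance=provenance,
    )


def scan_dsc(
    gt_scan_mask: LabelMask,
    inference_scan_mask: LabelMask,
    unit_id: str = "scan",
    crop_provenance: str | None = None,
) -> MetricRecord:
    """Scan-level metrics with all tumors simultaneously pooled as foreground."""
    gt_scan_mask.require_same_geometry(inference_scan_mask, "GT/inference masks")
    return _record(
        "scan",
        unit_id,
        gt_scan_mask.foreground,
        inference_scan_mask.foreground,
        gt_scan_mask.spacing,
        provenance=crop_provenance,
    )


def crop_metrics(
    crops: Sequence[tuple[np.ndarray, np.ndarray]],
    provenance: str,
    spacing: VoxelSpacing,
    unit_ids: Sequence[str] | None = None,
) -> list[MetricRecord]:
    """Per-crop metrics, each cropped volume a separate evaluation unit."""
    if unit_ids is not None and len(unit_ids) != len(crops):
        raise ValueError("unit_ids length must match number of crops")
    records = []
    for i, (g, s) in enumerate(crops):
        uid = unit_ids[i] if unit_ids is not None else f"crop{i:03d}"
        records.append(_record("crop", uid, _as_bool(g), _as_bool(s), spacing, provenance=provenance))
    return records


# ---------------------------------------------------------------------------
# Component matching
# ---------------------------------------------------------------------------


@dataclass
class MatchResult:
    """Assignment of inference connected components to ground-truth tumors.

    ``matches`` maps each GT tumor id to the ids of every inference component
    overlapping it (≥1 shared voxel).  A component overlapping several tumors
    is attributed, whole, to each — counted in ``multi_matched_ids`` and
    logged.  Components overlapping no tumor are false positives; GT tumors
    with no overlapping component are missed.
    """

    gt_tumors: list[LesionComponent]
    inference_components: list[LesionComponent]
    matches: dict[int, list[int]]
    false_positive_ids: list[int]
    missed_gt_ids: list[int]
    multi_matched_ids: list[int]
    shape: tuple[int, int, int]

    @property
    def n_false_positives(self) -> int:
        return len(self.false_positive_ids)


def match_components(
    gt_tumors: Sequence[LesionComponent],
    inference_mask: LabelMask | np.ndarray,
    connectivity: int = 26,
) -> MatchResult:
    """Match overlapping inference components to each ground-truth tumor."""
    inf_arr = _as_bool(inference_mask)
    shape = tuple(inf_arr.shape)
    inf_comps = connected_components(inf_arr, connectivity=connectivity)

    gt_lin = {t.component_id: t.linear_indices(shape) for t in gt_tumors}
    inf_lin = {c.component_id: c.linear_indices(shape) for c in inf_comps}

    matches: dict[int, list[int]] = {t.component_id: [] for t in gt_tumors}
    matched_counts: dict[int, int] = {c.component_id: 0 for c in inf_comps}
    for t in gt_tumors:
        for c in inf_comps:
            if np.intersect1d(gt_lin[t.component_id], inf_lin[c.component_id], assume_unique=True).size:
                matches[t.component_id].append(c.component_id)
                matched_counts[c.component_id] += 1

    fp = [cid for cid, n in matched_counts.items() if n == 0]
    missed = [tid for tid, lst in matches.items() if not lst]
    multi = [cid for cid, n in matched_counts.items() if n > 1]
    if multi:
        logger.info("%d inference component(s) overlap more than one ground-truth tumor: %s", len(multi), multi)
    return MatchResult(
        gt_tumors=list(gt_tumors),
        inference_components=inf_comps,
        matches=matches,
        false_positive_ids=fp,
        missed_gt_ids=missed,
        multi_matched_ids=multi,
        shape=shape,  # type: ignore[arg-type]
    )


def tumor_metrics(
    match: MatchResult,
    spacing: VoxelSpacing,
    locations: dict[int, str] | None = None,
    crop_provenance: str | None = None,
) -> list[MetricRecord]:
    """Per-ground-truth-tumor metrics.

    For each GT tumor, S is the union of its matched inference components
    (false positives never enter); a missed tumor scores DSC 0 and RVD 1.
    The tumor-level summary statistic is the *unweighted* mean over tumors.
    """
    inf_by_id = {c.component_id: c for c in match.inference_components}
    records = []
    for t in match.gt_tumors:
        g = t.to_mask(match.shape)
        s = np.zeros(match.shape, dtype=bool)
        for cid in match.matches[t.component_id]:
            s[tuple(inf_by_id[cid].voxel_indices.T)] = True
        records.append(
            _record(
                "tumor",
                f"tumor{t.component_id}",
                g,
                s,
                spacing,
                location=None if locations is None else locations.get(t.component_id),
                provenance=crop_provenance,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    # Sample SD (ddof=1); a single observation has SD 0 by convention so
    # summary tables never carry NaN.
    if values.size == 0:
        return (float("nan"), float("nan"))
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return mean, sd


def summarize_records(records: Iterable[MetricRecord]) -> dict:
    """Mean/SD of DSC, AVD and RVD over a set of records."""
    recs = list(records)
    out: dict = {"n": len(recs)}
    for name, getter in (("dsc", lambda r: r.dsc), ("avd_cm3", lambda r: r.avd_cm3), ("rvd", lambda r: r.rvd)):
        vals = np.asarray([getter(r) for r in recs if getter(r) is not None], dtype=float)
        mean, sd = _mean_sd(vals)
        out[f"{name}_mean"] = mean
        out[f"{name}_sd"] = sd
    return out


def location_summary(records: Iterable[MetricRecord]) -> pd.DataFrame:
    """Per-location (plus overall) mean/SD tables, keyed by crop provenance.

    Locations with no records simply have no row — they are never
    zero-filled.
    """
    recs = [r for r in records]
    rows = []
    provenances = sorted({r.crop_provenance for r in recs}, key=str)
    for prov in provenances:
        sub = [r for r in recs if r.crop_provenance == prov]
        groups = [("overall", sub)]
        for loc in ("parenchymal", "mediastinal", "pleural"):
            loc_recs = [r for r in sub if r.location == loc]
            if loc_recs:
                groups.append((loc, loc_recs))
        for loc, loc_recs in groups:
            if not loc_recs:
                continue
            row = {"crop_provenance": prov, "location": loc}
            row.update(summarize_records(loc_recs))
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rank-sum test (cell vs box comparison)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RankSumResult:
    p_value: float
    u_statistic: float
    method: str  # "exact-enumeration" | "normal-approximation"


#: Largest combined sample size for which the exact branch enumerates.
EXACT_ENUMERATION_MAX_N = 12


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    # U for sample a: #(a_i > b_j) + 0.5·#(a_i == b_j)
    diff = a[:, None] - b[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def rank_sum_test(
    a: Sequence[float],
    b: Sequence[float],
    method: str = "auto",
) -> RankSumResult:
    """Two-sided Mann–Whitney–Wilcoxon rank-sum test.

    For combined n ≤ 12 (or ``method="exact"``) the null distribution of U is
    enumerated over all group relabelings of the pooled sample, which handles
    ties exactly; the two-sided p is the null probability of a U at least as
    far from its mean mn/2 as observed.  Larger samples use the tie-corrected
    normal approximation.
    """
    a_arr = np.asarray(list(a), dtype=float)
    b_arr = np.asarray(list(b), dtype=float)
    if a_arr.size == 0 or b_arr.size == 0:
        raise ValueError("rank_sum_test requires two non-empty samples")
    n_a, n_b = a_arr.size, b_arr.size
    if method not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown method {method!r}")
    use_exact = method == "exact" or (method == "auto" and n_a + n_b <= EXACT_ENUMERATION_MAX_N)

    u_obs = _u_statistic(a_arr, b_arr)
    if use_exact:
        pooled = np.concatenate([a_arr, b_arr])
        center = n_a * n_b / 2.0
        dev_obs = abs(u_obs - center)
        total = 0
        extreme = 0
        for idx in itertools.combinations(range(pooled.size), n_a):
            mask = np.zeros(pooled.size, dtype=bool)
            mask[list(idx)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - center) >= dev_obs - 1e-12:
                extreme += 1
        return RankSumResult(extreme / total, u_obs, "exact-enumeration")

    res = _scipy_stats.mannwhitneyu(a_arr, b_arr, alternative="two-sided", method="asymptotic")
    return RankSumResult(float(res.pvalue), u_obs, "normal-approximation")


# ---------------------------------------------------------------------------
# Axial axis measurement (RECIST-style)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AxisMeasurement:
    major_mm: float
    minor_mm: float
    slice_index: int


def _slice_axes(coords_mm: np.ndarray) -> tuple[float, float]:
    """Major/minor extents (mm) of one axial slice's voxel centers."""
    n = coords_mm.shape[0]
    if n < 2:
        return 0.0, 0.0
    d = pdist(coords_mm)
    major = float(d.max())
    if major == 0.0:
        return 0.0, 0.0
    # Deterministic pair choice: smallest (i, j) among ties, points in
    # lexicographic order (callers pass sorted coordinates).
    pair_iter = itertools.combinations(range(n), 2)
    best = None
    for dist, (i, j) in zip(d, pair_iter):
        if abs(dist - major) <= 1e-9 * max(1.0, major):
            best = (i, j)
            break
    assert best is not None
    u = coords_mm[best[1]] - coords_mm[best[0]]
    u = u / np.linalg.norm(u)
    perp = np.array([-u[1], u[0]])
    proj = coords_mm @ perp
    minor = float(proj.max() - proj.min())
    return major, minor


def axial_axis_measurements(lesion: LesionComponent, spacing: VoxelSpacing) -> AxisMeasurement:
    """Longest in-plane axis of the lesion across axial (constant-Z) slices.

    Per slice, the major axis is the maximum pairwise distance between
    foreground voxel centers in physical mm; the minor axis is the maximum
    extent perpendicular to the realized major-axis direction within the same
    slice.  The slice maximizing the major axis is returned; ties break to
    the lowest slice index.
    """
    vox = lesion.voxel_indices
    best: AxisMeasurement | None = None
    for z in sorted(int(v) for v in np.unique(vox[:, 2])):
        sl = vox[vox[:, 2] == z][:, :2].astype(float)
        sl = sl[np.lexsort((sl[:, 1], sl[:, 0]))]
        coords = sl * np.array([spacing.dx, spacing.dy])
        major, minor = _slice_axes(coords)
        if best is None or major > best.major_mm + 1e-12:
            best = AxisMeasurement(major, minor, z)
    assert best is not None  # lesion is non-empty by construction
    return best
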