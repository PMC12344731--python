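"""End-to-end evaluation and longitudinal tracking pipelines.

`evaluate_scan` runs one scan through the full analysis path — lesion
extraction and anatomical classification, box/cell cropping, segmentation
(from a supplied inference mask, per-crop prediction files, or a pluggable
segmenter callable), crop reassembly, and metric computation at the scan,
crop and tumor levels.  `run_evaluate` wraps it with file I/O and report
writing; `run_track` re-applies a patient's stored grid-cell selection to a
sequence of scans and tabulates per-lesion volumes and axial axes.

Every report embeds a provenance block (package version, configuration,
orientation convention, seed) sufficient to re-run its deterministic stages
bit-identically, and summary tables are exactly recomputable from the
emitted per-unit records.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .core import CANONICAL_AXCODES, ImageVolume, LabelMask, connected_components
from .cropping import (
    CropRegion,
    SelectionStore,
    apply_selection,
    box_crop,
    build_lung_grid,
    cell_crop,
    cells_containing_mask,
    paste_crop,
)
from .io import read_mask, read_volume
from .localization import classify_all
from .metrics import (
    MetricRecord,
    axial_axis_measurements,
    crop_metrics,
    location_summary,
    match_components,
    rank_sum_test,
    scan_dsc,
    summarize_records,
    tumor_metrics,
)
from .phantom import reference_segmenter

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ScanInputs", "EvaluationReport", "evaluate_scan", "run_evaluate", "run_track"]

Segmenter = Callable[[CropRegion], np.ndarray]


@dataclass
class RunConfig:
    """Configuration for the `evaluate` / `track` pipelines.

    Loadable from a YAML or JSON file; flag overrides are applied by the CLI.
    """

    image: str | None = None
    lung_mask: str = ""
    gt_mask: str | None = None
    inference_mask: str | None = None
    predictions_dir: str | None = None
    selection_store: str | None = None
    output_dir: str = "thoravol_out"
    strategy: str = "both"  # box | cell | both
    divisions: int = 5
    margin_voxels: int = 2
    pad_fraction: float = 0.0
    connectivity: int = 26
    strict_border: bool = False
    segmenter_threshold: float | None = None
    segmenter_min_component_voxels: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in ("box", "cell", "both"):
            raise ValueError(f"strategy must be box, cell or both; got {self.strategy!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        p = Path(path)
        text = p.read_text()
        if p.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{p}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    @property
    def strategies(self) -> tuple[str, ...]:
        return ("box", "cell") if self.strategy == "both" else (self.strategy,)

    def provenance(self) -> dict:
        cfg = dataclasses.asdict(self)
        digest = hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
        return {
            "package": "thoravol",
            "version": _version,
            "orientation_convention": "".join(CANONICAL_AXCODES),
            "percentile_method": "linear-interpolation",
            "config": cfg,
            "config_hash": digest,
            "seed": self.seed,
        }


@dataclass
class ScanInputs:
    """In-memory inputs for one scan."""

    scan_id: str
    image: ImageVolume
    lung_mask: LabelMask
    gt_mask: LabelMask
    inference_mask: LabelMask | None = None
    segmenter: Segmenter | None = None


@dataclass
class EvaluationReport:
    """Per-unit records plus the summaries derived from them."""

    records: list[MetricRecord]
    summaries: dict
    p_values: dict
    counts: dict
    provenance: dict
    warnings: list[str] = field(default_factory=list)

    def records_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_row() for r in self.records])

    def to_json_obj(self) -> dict:
        return {
            "summaries": self.summaries,
            "p_values": self.p_values,
            "counts": self.counts,
            "warnings": self.warnings,
            "provenance": self.provenance,
        }

    def text_table(self) -> str:
        lines = ["thoravol evaluation report", "=" * 60]
        lines.append(f"orientation: {self.provenance.get('orientation_convention')}")
        for level, summ in self.summaries.items():
            lines.append("")
            lines.append(f"[{level}]")
            if isinstance(summ, list):
                df = pd.DataFrame(summ)
                lines.append(df.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
            else:
                for k, v in summ.items():
                    lines.append(f"  {k}: {v:.2f}" if isinstance(v, float) else f"  {k}: {v}")
        if self.p_values:
            lines.append("")
            lines.append("[cell vs box comparison]")
            for k, v in self.p_values.items():
                lines.append(f"  {k}: p = {v:.4g}" if isinstance(v, float) else f"  {k}: {v}")
        if self.counts:
            lines.append("")
            lines.append("[counts]")
            for k, v in self.counts.items():
                lines.append(f"  {k}: {v}")
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines) + "\n"


def _build_crops(
    strategy: str,
    inputs: ScanInputs,
    divisions: int,
    margin_voxels: int,
    pad_fraction: float,
    connectivity: int,
) -> list[CropRegion]:
    if strategy == "box":
        comps = connected_components(inputs.gt_mask, connectivity=connectivity)
        return [
            box_crop(
                inputs.image,
                c.bbox,
                margin_voxels=margin_voxels,
                mask=inputs.gt_mask,
                provenance={"lesion_id": c.component_id, "scan_id": inputs.scan_id},
            )
            for c in comps
        ]
    grid = build_lung_grid(inputs.lung_mask, divisions=divisions, pad_fraction=pad_fraction)
    cells = sorted(cells_containing_mask(grid, inputs.gt_mask))
    return [
        cell_crop(inputs.image, grid, cell, mask=inputs.gt_mask, provenance={"scan_id": inputs.scan_id})
        for cell in cells
    ]


def _predict(crop: CropRegion, inputs: ScanInputs) -> np.ndarray:
    if inputs.inference_mask is not None:
        return np.asarray(inputs.inference_mask.labels[crop.bbox.slices] != 0)
    if inputs.segmenter is not None:
        return np.asarray(inputs.segmenter(crop)) != 0
    raise ValueError(f"scan {inputs.scan_id}: no inference mask and no segmenter supplied")


def evaluate_scan(
    inputs: ScanInputs,
    strategies: Sequence[str] = ("box", "cell"),
    divisions: int = 5,
    margin_voxels: int = 2,
    pad_fraction: float = 0.0,
    connectivity: int = 26,
    strict_border: bool = False,
) -> tuple[list[MetricRecord], dict]:
    """Evaluate one scan; returns per-unit records and FP/missed counts.

    Scan- and tumor-level metrics are computed per strategy from that
    strategy's predictions reassembled (pasted by OR) onto a scan-sized
    canvas.  When a full-scan inference mask is supplied, predictions are its
    restriction to each crop, so all strategies see the same segmentation.
    """
    inputs.gt_mask.require_same_geometry(inputs.lung_mask, "GT/lung masks")
    if inputs.inference_mask is not None:
        inputs.gt_mask.require_same_geometry(inputs.inference_mask, "GT/inference masks")

    classified = classify_all(
        inputs.gt_mask, inputs.lung_mask, connectivity=connectivity, strict_border=strict_border
    )
    gt_comps = [c for c, _ in classified]
    locations = {c.component_id: loc.category for c, loc in classified}

    records: list[MetricRecord] = []
    counts = {"false_positive_components": 0, "missed_tumors": 0, "multi_matched_components": 0}
    spacing = inputs.gt_mask.spacing

    for strategy in strategies:
        crops = _build_crops(strategy, inputs, divisions, margin_voxels, pad_fraction, connectivity)
        assembled = np.zeros(inputs.gt_mask.shape, dtype=np.uint8)
        pairs, unit_ids = [], []
        for i, crop in enumerate(crops):
            pred = _predict(crop, inputs)
            pairs.append((crop.mask_patch, pred))
            cid = crop.provenance.get("cell", crop.provenance.get("lesion_id", i))
            unit_ids.append(f"{inputs.scan_id}:{strategy}:{cid}")
            paste_crop(pred, crop.bbox, out=assembled)
        records.extend(crop_metrics(pairs, strategy, spacing, unit_ids=unit_ids))

        assembled_mask = inputs.gt_mask.with_labels(assembled)
        records.append(
            scan_dsc(inputs.gt_mask, assembled_mask, unit_id=f"{inputs.scan_id}:{strategy}", crop_provenance=strategy)
        )
        match = match_components(gt_comps, assembled_mask, connectivity=connectivity)
        trecs = tumor_metrics(match, spacing, locations=locations, crop_provenance=strategy)
        for r in trecs:
            r.unit_id = f"{inputs.scan_id}:{strategy}:{r.unit_id}"
        records.extend(trecs)
        counts["false_positive_components"] += match.n_false_positives
        counts["missed_tumors"] += len(match.missed_gt_ids)
        counts["multi_matched_components"] += len(match.multi_matched_ids)
    return records, counts


def build_report(
    all_records: list[MetricRecord],
    counts: dict,
    provenance: dict,
    warnings: list[str] | None = None,
) -> EvaluationReport:
    """Aggregate per-unit records into the summary tables and p-values."""
    summaries: dict = {}
    p_values: dict = {}
    for unit in ("scan", "crop", "tumor"):
        by_prov: list[dict] = []
        for prov in sorted({r.crop_provenance for r in all_records if r.unit == unit}, key=str):
            sub = [r for r in all_records if r.unit == unit and r.crop_provenance == prov]
            entry = {"crop_provenance": prov}
            entry.update(summarize_records(sub))
            by_prov.append(entry)
        if by_prov:
            summaries[unit] = by_prov
    tumor_recs = [r for r in all_records if r.unit == "tumor" and r.location is not None]
    if tumor_recs:
        summaries["by_location"] = location_summary(tumor_recs).to_dict("records")

    for unit in ("crop", "scan"):
        cell = [r.dsc for r in all_records if r.unit == unit and r.crop_provenance == "cell"]
        box = [r.dsc for r in all_records if r.unit == unit and r.crop_provenance == "box"]
        if cell and box:
            res = rank_sum_test(cell, box)
            p_values[f"{unit}_dsc_cell_vs_box"] = res.p_value
            p_values[f"{unit}_dsc_cell_vs_box_method"] = res.method  # type: ignore[assignment]
    return EvaluationReport(
        records=all_records,
        summaries=summaries,
        p_values=p_values,
        counts=counts,
        provenance=provenance,
        warnings=warnings or [],
    )


def run_evaluate(config: RunConfig) -> EvaluationReport:
    """File-based evaluation of one scan per the run configuration.

    Inputs are validated and all results computed before anything is
    written, so a failure never leaves partial outputs behind.
    """
    if not config.lung_mask or not config.gt_mask:
        raise ValueError("run_evaluate requires lung_mask and gt_mask paths in the config")
    lung = read_mask(config.lung_mask)
    gt = read_mask(config.gt_mask)
    try:
        gt.require_same_geometry(lung, f"{config.gt_mask} vs {config.lung_mask}")
    except ValueError as e:
        raise ValueError(str(e)) from None

    image = read_volume(config.image) if config.image else ImageVolume(
        np.zeros(gt.shape, dtype=np.float32), gt.spacing
    )

    inference = None
    segmenter: Segmenter | None = None
    if config.inference_mask:
        inference = read_mask(config.inference_mask)
        gt.require_same_geometry(inference, f"{config.gt_mask} vs {config.inference_mask}")
    elif config.predictions_dir:
        inference = _assemble_predictions(Path(config.predictions_dir), gt)
    elif config.segmenter_threshold is not None:
        thr, mcv = config.segmenter_threshold, config.segmenter_min_component_voxels
        segmenter = lambda crop: reference_segmenter(crop, threshold=thr, min_component_voxels=mcv)
    else:
        raise ValueError("config must provide inference_mask, predictions_dir or segmenter_threshold")

    inputs = ScanInputs("scan", image, lung, gt, inference_mask=inference, segmenter=segmenter)
    records, counts = evaluate_scan(
        inputs,
        strategies=config.strategies,
        divisions=config.divisions,
        margin_voxels=config.margin_voxels,
        pad_fraction=config.pad_fraction,
        connectivity=config.connectivity,
        strict_border=config.strict_border,
    )
    report = build_report(records, counts, config.provenance())

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    # all content is materialized before any file is opened
    csv_text = report.records_frame().to_csv(index=False)
    json_text = json.dumps(report.to_json_obj(), indent=2, default=_json_default)
    txt = report.text_table()
    (outdir / "records.csv").write_text(csv_text)
    (outdir / "summary.json").write_text(json_text)
    (outdir / "report.txt").write_text(txt)
    return report


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, float) and not np.isfinite(o):
        return None
    raise TypeError(f"not JSON serializable: {type(o)}")


def _assemble_predictions(directory: Path, reference: LabelMask) -> LabelMask:
    """Assemble per-crop prediction patches (NIfTI + JSON bbox sidecars) into
    a scan-level mask by OR-pasting."""
    from .core import BoundingBox3D

    canvas = np.zeros(reference.shape, dtype=np.uint8)
    sidecars = sorted(directory.glob("*.json"))
    if not sidecars:
        raise FileNotFoundError(f"no prediction sidecars (*.json) found in {directory}")
    for sc in sidecars:
        meta = json.loads(sc.read_text())
        bbox = BoundingBox3D(tuple(meta["bbox"]["lower"]), tuple(meta["bbox"]["upper"]))
        patch = read_mask(directory / meta["mask_file"])
        paste_crop(patch.labels, bbox, out=canvas)
    return reference.with_labels(canvas)


def run_track(
    config: RunConfig,
    patient_id: str,
    scans: Sequence[dict],
    bootstrap_gt_mask: str | None = None,
) -> pd.DataFrame:
    """Longitudinal per-lesion volume and axis table for one patient.

    ``scans`` is a sequence of dicts with keys ``scan_id``, ``image`` and
    ``lung_mask`` (paths), ordered or orderable by ``scan_id``.  The
    patient's stored grid-cell selection is re-applied to every scan; if the
    patient is unknown and ``bootstrap_gt_mask`` is given, the selection is
    created from the cells containing that mask on the first scan (manual
    initial selection stands behind this in clinical use) and saved.
    """
    if not config.selection_store:
        raise ValueError("run_track requires a selection_store path in the config")
    store = SelectionStore(config.selection_store)
    scans = sorted(scans, key=lambda s: str(s["scan_id"]))

    try:
        record = store.load_selection(patient_id)
    except KeyError:
        if bootstrap_gt_mask is None:
            raise KeyError(
                f"patient {patient_id!r} not in selection store and no bootstrap mask supplied"
            ) from None
        first = scans[0]
        lung0 = read_mask(first["lung_mask"])
        gt0 = read_mask(bootstrap_gt_mask)
        grid = build_lung_grid(lung0, divisions=config.divisions, pad_fraction=config.pad_fraction)
        cells = cells_containing_mask(grid, gt0)
        if not cells:
            raise ValueError(f"bootstrap mask {bootstrap_gt_mask} selects no grid cells")
        from .cropping import CellSelectionRecord

        record = CellSelectionRecord(patient_id, frozenset(cells), source_scan_id=str(first["scan_id"]))
        store.save_selection(record)

    thr = 50.0 if config.segmenter_threshold is None else config.segmenter_threshold
    rows = []
    for scan in scans:
        image = read_volume(scan["image"])
        lung = read_mask(scan["lung_mask"])
        gt = read_mask(scan["gt_mask"]) if scan.get("gt_mask") else None
        crops = apply_selection(
            lung, record, image, mask=gt, divisions=config.divisions, pad_fraction=config.pad_fraction
        )
        canvas = np.zeros(lung.shape, dtype=np.uint8)
        for crop in crops:
            pred = reference_segmenter(
                crop, threshold=thr, min_component_voxels=config.segmenter_min_component_voxels
            )
            paste_crop(pred, crop.bbox, out=canvas)
        comps = connected_components(canvas, connectivity=config.connectivity)
        for comp in comps:
            axes = axial_axis_measurements(comp, lung.spacing)
            rows.append(
                {
                    "patient_id": patient_id,
                    "scan_id": scan["scan_id"],
                    "lesion_id": comp.component_id,
                    "voxel_count": comp.size,
                    "volume_cm3": comp.volume_cm3(lung.spacing),
                    "major_axis_mm": axes.major_mm,
                    "minor_axis_mm": axes.minor_mm,
                    "axis_slice": axes.slice_index,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "patient_id", "scan_id", "lesion_id", "voxel_count", "volume_cm3",
            "major_axis_mm", "minor_axis_mm", "axis_slice",
        ],
    )
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / f"track_{patient_id}.csv", index=False)
    return table
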