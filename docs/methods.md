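# Methods

## Coordinate model

Every volume is reoriented on load to a single canonical voxel-axis
convention: axis 0 (X) increases toward the patient's left, axis 1 (Y)
toward the posterior, axis 2 (Z) toward the superior. The localization
cascade's anterior test (Yt ≤ y75) is meaningless without a fixed Y
direction, so canonicalization is done once at the I/O boundary (via the
NIfTI affine, or the DICOM orientation/position tags) rather than trusted to
callers. The convention is recorded in every report. Voxel indices are
0-based; bounding boxes are half-open `[lower, upper)`; a box center is
`(lower + upper − 1)/2` per axis and may be fractional.

DICOM series are read strictly: a directory must hold exactly one series,
and consecutive slice gaps may differ by at most 1e-3 mm — beyond that the
reader refuses rather than silently resampling, because resampling would
corrupt volume measurements downstream.

## Cropping

**Box crops** expand a lesion's tight bounding box by a per-side margin
(default 2 voxels — enough local context for a segmenter without swallowing
neighboring structures) and clip to the volume.

**Cell crops** come from a d×d×d grid (default 5, hence 125 cells) over the
lung-mask bounding box. Grid boundaries are real-valued equal partitions of
each axis span; voxels map to cells by half-open interval membership with
the last interval closed, and cell voxel extents are the boundaries rounded
outward. Both rules are driven by the same float boundaries, so the cells
tile the box exactly — no voxel is dropped or double-counted even when a
span is not divisible by d.

The grid's `pad_fraction` (default 0, the tight lung bbox) expands the box
by a fraction of each axis span per side. Pleural disease hugs the *outer*
lung surface, i.e. sits marginally outside the tight bbox; end-to-end runs
in this package therefore use `pad_fraction = 0.1`, which keeps surface caps
inside the grid while leaving the default conservative and reproducible.

Per-patient cell selections are stored in a versioned JSON file (one active
record per patient, prior records retained as history) and re-applied to
later scans by cell **index** on a grid rebuilt from the new scan's lungs.
This is the longitudinal-correspondence mechanism: no registration is
attempted, and rigid anatomy shifts are absorbed because the grid follows
the lungs. When a lesion mask is available at re-application time, lesion
voxels outside the union of stored cells raise a coverage warning (tumor
growth beyond the stored selection is the known failure mode; automatic
selection growth is out of scope).

Per-crop predictions are reassembled to scan level by voxelwise OR — the
segmentation task is binary, so overlapping crops union.

## Localization cascade

Quartiles (x25, x75 of X; y75 of Y) are linear-interpolation percentiles
over the multiset of lung foreground voxel coordinates, computed on the
combined two-lung mask. Each lung holds about half the voxel mass, so x25
falls inside one lung and x75 inside the other; the band between them is the
mediastinum.

1. A lesion that does not border the lung boundary is **parenchymal**.
2. A bordering lesion with bbox center in the central X band and anterior of
   y75 is **mediastinal**.
3. Everything else is **pleural**.

"Borders" means: any lesion voxel lies on, or is 26-adjacent to, the lung
boundary shell (lung voxels with a 6-neighbor outside the lung;
volume-edge voxels included). The 26-adjacency tolerance deliberately admits
lesions lying just *outside* the lung mask, which is where pleural and
mediastinal disease mostly sits; a strict mode requiring shell intersection
is available. The lesion center is the bounding-box center, not the voxel
centroid. A lesion far from the lungs never "borders" and is therefore
parenchymal by the literal rule — a logged warning flags this case, since
the label is anatomically doubtful.

The cascade is total and exclusive by construction. Its outcome depends on
the Y direction; the canonical orientation makes it invariant to file
storage, which is tested by classifying the same volumes stored with flipped
axes.

## Metrics

DSC, AVD and RVD follow their standard voxel-count definitions (README).
Conventions where the definitions are silent: both-empty DSC is 1.0 (both
raters agree there is nothing); RVD with empty ground truth is an error, not
infinity, so undefined values can never leak into means. AVD compares counts
only — equal-volume disjoint masks score 0; that is a property of the
definition, documented rather than "fixed". Summary tables report mean and
sample SD (ddof = 1; a single observation reports SD 0 so tables never carry
NaN); locations with no records have no row.

Tumor-level evaluation matches inference connected components (default
26-connectivity, configurable — diagonal voxels merging is the conservative
choice for tumor identity) to every ground-truth tumor they overlap by at
least one voxel. A component overlapping k > 1 tumors contributes its whole
voxel set to each tumor's S (no splitting rule is invented; occurrences are
counted and logged). Components overlapping nothing are false positives:
excluded from tumor- and location-level summaries, but still present in the
pooled scan-level masks, so scan DSC and tumor DSC deliberately diverge in
their presence. Tumor DSC summarizes as an unweighted mean over tumors.

The cell-vs-box comparison uses a two-sided Mann–Whitney–Wilcoxon test.
For combined n ≤ 12 the null distribution of U (with 0.5 credit for ties) is
enumerated over all group relabelings of the pooled sample — exact under
ties — and the two-sided p is the null probability of a U at least as far
from mn/2 as observed. Larger samples use the tie-corrected normal
approximation; the method used is always reported next to the p-value.

Axial axis measurement: per constant-Z slice, the major axis is the maximum
pairwise distance between foreground voxel centers in physical mm, the minor
axis the maximal extent perpendicular to the realized major-axis direction
within the same slice; the slice maximizing the major axis wins, ties to the
lowest slice index, and tied major pairs resolve to the first pair in scan
order over lexicographically sorted points.

## Phantom generator

The phantom emulates the geometry the toolkit's rules depend on, not CT
physics: two ellipsoidal lungs (semi-axes 16×22×30 voxels) left and right of
the midline in a 96³ volume at 2 mm isotropic spacing, soft-tissue
background ≈ 40, lung ≈ −700, lesions = background + contrast (default 20),
independent per-voxel Gaussian noise (default SD 4 = 20% of contrast). All
intensities are HU-like but arbitrary; the toolkit never interprets absolute
HU.

Lesion recipes: parenchymal = sphere interior to a lung with ≥ 2-voxel
surface clearance; mediastinal = ellipsoid in the inter-lung gap touching
the medial lung surfaces, center in the central X band and anterior of y75;
pleural = a thin spherical-shell cap clipped to a band of the outer lung
surface (curvilinear, as pleural metastases are), lateral by default or
posterior-midline on request (the latter exercises the cascade's Y rule).
Every carved lesion is validated against these geometric requirements at
generation time, and generation fails naming the lesion if a spec cannot be
realized unambiguously — ambiguous placements are a generator error, never a
silent test fixture.

Cohorts jitter lesion sizes (±10%), lesion centers (±1.5 voxels) and rigid
whole-thorax translation (±3 voxels) per scan. Longitudinal pairs grow every
lesion by a stated volume factor (linear dimensions scale by its cube root)
and translate the thorax; truth volumes are exact voxel counts, so measured
growth includes only voxelization error (≲ 1–2% at these sizes).

The reference segmenter is a deterministic threshold-plus-minimum-size rule
(default threshold 50, midway between background and lesion; components
under 5 voxels dropped). It stands in for a learned model so the pipeline is
testable end to end; with noise at 20% of contrast it recovers phantom
lesions at DSC ≈ 0.99.

**What passing phantom tests do not show:** real CT texture, partial-volume
effects, contrast variability, lesions abutting isointense mediastinal
structures, or imperfect lung segmentations. The phantom certifies the
*bookkeeping* — cropping geometry, classification logic, matching and metric
arithmetic — not segmentation difficulty.

## Problem sizes

Default problem sizes throughout: 96³ phantoms; 5-scan cohorts for
end-to-end runs; 50-scan cohorts for localization/grid property checks;
random masks up to 24³ against brute-force oracles (where pure-Python
enumeration stays fast). These sizes were chosen so every check runs in
seconds to a few minutes on a single CPU while still exercising multi-cell
lesions, grid non-divisibility and all three lesion categories.

## Known limitations

* No resampling or registration; masks must share geometry exactly.
* DICOM reading only (no DICOM writing, DICOM-SEG or RTSTRUCT).
* The localization rules inherit any lung-segmentation error; lung masks are
  an input, not a product.
* Selection reuse assumes roughly stable lung anatomy; gross anatomical
  change (effusion collapse, pneumonectomy) breaks cell correspondence and
  surfaces only as a coverage warning.
* RVD is unbounded above and highly unstable for small ground-truth volumes;
  means over small lesions should be read with that in mind.
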