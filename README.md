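# thoravol

Physician-guided volumetric assessment of thoracic tumors on 3D CT.

Metastatic thymic epithelial tumors (TETs) spread along the pleura and
through the mediastinum, where curvilinear, plaque-like lesions make 1D
RECIST calipers a poor proxy for tumor burden. `thoravol` implements the
analysis scaffolding around a pluggable 3D segmenter for this setting:

* **Cropping strategies** — *box crops* around an individual lesion's
  maximal extent, and *cell crops* from a 5×5×5 grid spanned over the lung
  bounding box. A patient's selected cells are persisted in a JSON store and
  re-applied to follow-up scans by grid **index** (the grid is rebuilt on
  each scan's own lungs), which keeps cell addresses anatomically
  corresponding across scans without image registration.
* **Rule-based lesion localization** — each lesion is labeled parenchymal,
  mediastinal or pleural by a fixed cascade on lung-mask coordinate
  quartiles: a lesion not bordering the lung boundary is parenchymal; a
  bordering lesion whose bounding-box center (Xt, Yt, Zt) satisfies
  X25% ≤ Xt ≤ X75% and Yt ≤ Y75% (anterior of the posterior lung quartile)
  is mediastinal; everything else is pleural.
* **Component-matched evaluation** — with G the ground-truth mask, S the
  inference mask and |·| a foreground voxel count:

  * DSC(G,S) = 2|G∩S| / (|G|+|S|)
  * AVD(G,S) = v·||G|−|S|| (cm³, v = single-voxel volume)
  * RVD(G,S) = ||G|−|S|| / |G|

  computed per scan (all tumors pooled), per crop (each cropped region one
  evaluation unit) and per ground-truth tumor (inference connected
  components matched to the tumors they overlap; unmatched components are
  false positives and are excluded from tumor/location-level summaries).
  Cell- vs box-crop performance is compared with a two-sided
  Mann–Whitney–Wilcoxon rank-sum test (exact enumeration at small n).
* **RECIST-style axis measurement** — per axial slice, the major axis is the
  maximum pairwise distance between lesion voxel centers and the minor axis
  the maximal perpendicular extent; the maximizing slice is reported.
* **Synthetic thoracic phantoms** — seeded generation of two-lung phantoms
  with lesions of all three categories (including curvilinear pleural caps)
  and exactly known voxel truth, plus cohorts and longitudinal pairs with
  controlled volume growth. A deterministic threshold segmenter stands in
  for a trained model so the whole pipeline runs end to end.

Volumes are read from NIfTI (or a single-series DICOM directory) and
reoriented on load to a canonical convention (X→patient left, Y→posterior,
Z→superior), making the orientation-sensitive localization rules
deterministic regardless of on-disk storage.

## Worked example

```python
import numpy as np
from thoravol import classify_all
from thoravol.phantom import PhantomSpec, generate_phantom, reference_segmenter
from thoravol.reports import ScanInputs, build_report, evaluate_scan

ph = generate_phantom(PhantomSpec(seed=3))          # 96³ phantom, 2 mm voxels
print(ph.truth[["label", "category", "volume_cm3"]])

gt = ph.lesion_mask.with_labels((ph.lesion_mask.labels != 0).astype(np.uint8))
seg = lambda crop: reference_segmenter(crop, threshold=50.0, min_component_voxels=5)
records, counts = evaluate_scan(
    ScanInputs("scan0", ph.image, ph.lung_mask, gt, segmenter=seg),
    pad_fraction=0.1,
)
report = build_report(records, counts, {"orientation_convention": "LPS"})
for row in report.summaries["scan"]:
    print(row["crop_provenance"], round(row["dsc_mean"], 3))
```

prints

```
   label     category  volume_cm3
0      1  parenchymal       2.056
1      2  mediastinal      14.872
2      3      pleural       7.064
box 0.995
cell 0.996
```

— the three carved lesions with their exact voxel-truth volumes, and the
scan-level Dice agreement between the threshold segmenter's reassembled
output and the ground truth for each cropping strategy (1.0 would be
voxel-perfect recovery).

The same pipeline is scriptable from the shell:

```sh
thoravol phantom out/ --seed 3
thoravol classify out/lesion_mask.nii.gz out/lung_mask.nii.gz lesions.csv
thoravol evaluate config.yaml
thoravol track config.yaml pt000 scans.json --bootstrap-gt-mask out/lesion_mask.nii.gz
```

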