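# hipseg

A toolkit for proximal-hip CT musculoskeletal tissue analysis:

- **phantom** — synthetic hip cross-section generator with known seven-tissue
  ground truth (cortical bone, trabecular bone, haematopoietic bone marrow,
  marrow adipose tissue, muscle, intermuscular and subcutaneous adipose
  tissue), three hydroxyapatite calibration rods, and a configurable second
  "scanner domain" (HU offset / spacing change) for robustness experiments.
- **imaging_io** — CT image / label-mask I/O (NIfTI via nibabel, 16-bit PNG
  with JSON sidecar) and HU→density calibration against the rods
  (150 / 75 / 0 mg/cm³).
- **refseg** — reference segmentation reproducing the manual protocol:
  automatic compartment delineation (body, bone shell, marrow cavity, fascial
  envelope, subcutaneous ring) followed by per-compartment HU thresholding
  (cortical > 300, trabecular 150–300, HBM 50–150, MAT < 50, muscle −30 to
  500, fat < −30; half-open intervals).
- **model** — a Dense U-Net (dense blocks + skip connections, per-pixel
  softmax over 8 classes) implemented from scratch in numpy with hand-written
  backprop, trained with mini-batch Adam on categorical cross-entropy
  (batch size 2; paper preset lr 1e-4 / 200 epochs, desk preset lr 1e-3 /
  20 epochs).
- **evaluation** — per-class DSC, average symmetric surface distance,
  sensitivity/specificity; subject-level k-fold cross-validation (default
  k = 10); cross-domain evaluation with per-class DSC deltas.
- **quantify** — reference-slice selection (thickest femoral neck proxy),
  per-tissue area (cm²), 5-slice volume (cm³), muscle AHU and AHU/h²,
  HBM/TBM and MAT/TBM marrow fractions; cohort CSV export.
- **cli** — `hipseg` subcommands orchestrating all stages with manifest
  JSONs for reproducibility.

Everything runs on CPU with no deep-learning framework dependency.

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` contains the acceptance criteria; its headline
test trains the desk-preset Dense U-Net on 60 synthetic phantoms and verifies
mean DSC ≥ 90% over the seven tissue classes on 20 held-out phantoms
(several CPU-minutes). The remaining tests run in seconds to ~2 minutes.

## CLI quick tour

```bash
hipseg phantom --n 10 --seed 1 --out cohort/           # synthetic cohort
hipseg refseg --image cohort/S0000_image.nii --out ref.nii
hipseg train --cohort cohort/cohort.csv --preset desk --out model.npz
hipseg predict --model model.npz --image cohort/S0001_image.nii --out pred.nii
hipseg evaluate --pred preds/ --truth truths/ --out metrics/
hipseg cv --n 20 --k 10 --oracle --out cv/             # harness check
hipseg robustness --n 24 --hu-offset 40 --out robust/  # cross-domain drop
hipseg quantify --image cohort/S0000_image.nii --mask pred.nii \
    --height 1.75 --out quant.csv
```

Every command writes a `manifest.json` (config, seed, input hashes, package
versions) so outputs are reconstructible.

## Conventions

- Label codes: 0 background, 1 cortical, 2 trabecular, 3 HBM, 4 MAT,
  5 muscle, 6 IMAT, 7 SAT.
- HU is stored as float; PNG16 storage uses a +1024 offset.
- 3-D stacks are ordered superior → inferior; the reference slice for
  quantification is the one with the thickest femoral-neck cross-section
  (ties resolve inferior-most), and volumes integrate the reference ± 2
  slices × slice thickness.
- "Left" femoral neck is the image-right half (radiological convention),
  configurable in `quantify`.
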