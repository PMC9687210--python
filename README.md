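# cxrnodule

Detector-agnostic scaffolding for a chest-radiograph (CXR) lung-nodule
screening pipeline. The package is aimed at researchers who have (or plan
to train) a nodule detector and need everything around it to be correct,
tested and reproducible:

* **Preprocessing** — polarity (inverse-grayscale) correction and brightness
  normalization applied to every image, followed by one of three contrast
  variants: *default* (identity), *gamma* (power law `V_out = A·V_in^γ`,
  default `γ = 3`), or *CLAHE* (contrast-limited adaptive histogram
  equalization, clip limit 2, 8×8 tile grid). Three variants → three
  parallel datasets → three parallel detectors.
* **Lung ROI** — a pluggable segmenter contract with a deterministic
  intensity-based fallback, and construction of a single expanded bounding
  box covering both lungs, the mediastinum and retrocardiac region, and the
  subdiaphragmatic area.
* **Detection** — a detection data model with a JSONL adapter for external
  detector outputs, plus a deterministic multiscale difference-of-Gaussian
  toy detector so the downstream stages are exercisable without trained
  weights.
* **Ensembling** — the threshold-then-union combiner: each member model's
  detections are kept above its own operating threshold (default 0.01),
  pooled, and overlapping boxes merged at IoU ≥ 0.5 so one finding counts
  once.
* **FROC evaluation** — center-in-box hit criterion with optimal
  assignment, the standard descending threshold ladder
  (0.1 … 0.0001), sensitivity vs. false positives per image, normalized
  area over FP ∈ [0, 10], and sensitivity stratified by nodule diameter
  (<6, 6–10, 10–20, 20–30, >30 mm).
* **Temporal analysis** — per-patient time from earliest pre-diagnosis
  detection to diagnosis for radiologist reports, an AI model, and their
  per-record set union (simulated AI-assisted reading); overlap counts,
  median (IQR), an exact Wilcoxon signed-rank test, and a waterfall export
  of the per-patient benefit in days.
* **Synthetic data** — seeded generators for lung-field phantoms with
  inserted nodules of controlled size and contrast, pseudo-detector outputs
  with controlled miss/false-positive rates, and longitudinal cohorts with
  volume-doubling tumor growth. All fixtures are generated, none shipped.

## Worked example

```python
import cxrnodule as cx
from cxrnodule.detection import ToyBlobDetector
from cxrnodule.ensemble import EnsembleConfig, union_ensemble
from cxrnodule.evaluation import froc
from cxrnodule.pipeline import detect_variant

blanks, _, _ = cx.generate_phantoms(cx.PhantomConfig(n_images=6, seed=1, nodules_per_image=(0, 0)))
images, truths, _ = cx.generate_phantoms(cx.PhantomConfig(
    n_images=25, seed=2, nodules_per_image=(1, 2),
    nodule_diameter_mm_range=(7.0, 28.0), nodule_contrast_range=(0.3, 0.45),
))
members = {v: detect_variant(images, v, ToyBlobDetector(), blank_images=blanks)
           for v in cx.VARIANTS}
ensemble = [union_ensemble([members[v][i] for v in cx.VARIANTS], EnsembleConfig())
            for i in range(len(images))]
curve = froc(ensemble, truths)
print(f"{curve.n_nodules} nodules over {curve.n_images} images")
for p in curve.points[3:6]:
    print(f"  threshold {p.threshold:<6g} sensitivity {p.sensitivity:.3f} "
          f"FP/image {p.fp_per_image:.2f}")
print(f"normalized FROC area (FP in [0, {curve.fp_cap:g}]): {curve.area:.3f}")
```

prints

```
35 nodules over 25 images
  threshold 0.02   sensitivity 1.000 FP/image 0.20
  threshold 0.01   sensitivity 1.000 FP/image 0.32
  threshold 0.0075 sensitivity 1.000 FP/image 0.32
normalized FROC area (FP in [0, 10]): 1.000
```

i.e. on these easy phantoms the three-variant union ensemble finds all 35
inserted nodules at the 0.01 operating threshold at the cost of ~0.3 false
positives per image, and its FROC curve saturates the normalized area.

The same workflow is available from the shell:

```bash
cxrnodule simulate phantoms --seed 2 --out raw/
cxrnodule preprocess --variant clahe --clip-limit 2 --grid 8x8 --in raw/ --out pre/
cxrnodule detect --backend toy --in pre/ --out clahe.jsonl
cxrnodule ensemble --members default.jsonl gamma.jsonl clahe.jsonl --out ens.jsonl
cxrnodule froc --detections ens.jsonl --truth raw/ground_truth.csv \
    --out-csv froc.csv --out-json froc.json
cxrnodule temporal --timelines timelines.csv --out temporal/
```

## What this package is not

It does not train or ship lung segmentation or nodule-detection networks,
and it does not reproduce clinical performance figures that depend on
hospital image archives and trained weights. The synthetic phantoms
exercise the pipeline's logic, not the difficulty of real radiographs; see
`docs/methods.md` for what that distinction means when interpreting test
results.
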