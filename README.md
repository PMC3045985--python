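# mmhisto

Multimodal morphological analysis of prostate histology: classify tissue
samples (e.g. tissue-microarray cores) as **cancerous vs. benign** by fusing
a standard H&E-stained brightfield image with a cell-type label map derived
from infrared (FT-IR) spectroscopic imaging of a serial section.

The audience is computational-pathology researchers who have (a) H&E images
at ~1 µm/pixel and (b) per-pixel cell-type classifications at ~6.25 µm/pixel
from an upstream IR classifier, and who want a fully automated, transparent,
morphology-only classification pipeline. H&E alone makes epithelium hard to
delineate reliably across staining conditions; the IR map supplies that
delineation, and everything downstream is classical geometry.

## What it computes

1. **Registration.** Both modalities are binarized (H&E: tissue = not all
   channels > 200; IR: label ≠ background) and aligned with a similarity
   transform — translation (t_x, t_y), rotation θ, isotropic scale s —
   found by Nelder–Mead downhill simplex minimizing
   `Σ |I_reference − f(I_target; t_x, t_y, θ, s)|`,
   the symmetric-difference pixel count of the two masks.
2. **Segmentation.** Lumens are white spaces adjacent to epithelium-rich
   areas (complete lumens inside the tissue; incomplete lumens cut by the
   sample edge, modelled via the tissue's minimum enclosing circle with
   crescent-artifact rejection). Epithelial nuclei are segmented from the
   colour score |R + G − B| (low on blue nuclei) restricted to the
   registered epithelium, with adaptive thresholding, morphological
   closing, and a distance-transform-seeded watershed.
3. **Features.** 17 quantity categories — 8 epithelium-related (areas,
   counts, nucleus–lumen and nucleus–boundary distances, isolated and
   far-from-lumen nuclei, spatial entropy) and 9 lumen-related (area,
   count, roundness `L²_peri/(L_area·r)`, distortion STD(d)/AVG(d),
   bounding-circle and convex-hull ratios, symmetry indices,
   lumen–cytoplasm association) — summarized globally (AVG/STD/TOT) and
   locally over a sliding 100×100 px window (STD/MIN/MAX of window
   AVG/TOT): **67 features** (29 global, 38 local).
4. **Selection.** Two stages: mRMR (minimum-redundancy-maximal-relevance,
   MID form) ranks all features and the best-AUC prefix (≤ 30 features)
   becomes the candidate set; SFFS (sequential floating forward selection)
   refines it with floating add/remove steps under a 20-step budget.
5. **Classification.** RBF-SVM `K(x_i, x_j) = exp(−γ‖x_i − x_j‖²)` with
   cost ratio `C⁺/C⁻ = #negatives/#positives`, evaluated by repeated
   stratified 10-fold cross-validation with the entire feature selection
   nested inside each training fold; reports AUC and specificity at
   90/95/99% sensitivity.

A synthetic-tissue generator (`mmhisto.synthetic`) renders paired
H&E-like / IR-like images with full ground truth and calibrated
benign-vs-cancer morphology, so every stage is testable end to end without
proprietary data. See `docs/methods.md` for models, parameter defaults and
limitations.

## Worked example

```python
import mmhisto as m

pair, truth = m.render_sample(m.cancer_params(seed=7))
reg = m.register(m.binarize_he(pair.he), m.binarize_ir(pair.ir))
print(f"registration: s={reg.params.s:.2f}, theta={reg.params.theta:+.3f} rad, "
      f"residual={reg.objective / m.binarize_he(pair.he).sum():.1%} of tissue area")
seg = m.segment_sample(pair, reg)
print(f"segmented {len(seg.lumens)} lumens and {len(seg.nuclei)} nuclei "
      f"(ground truth: {len(truth.lumen_objects)} / {len(truth.nucleus_objects)})")
vec = m.extract_features(seg, pair.he)
s = vec.to_series()
for name in ("G_AVG_lumen_area", "G_AVG_lumen_roundness", "G_TOT_nucleus_count"):
    print(f"{name} = {s[name]:.3f}")
```

prints

```
registration: s=6.43, theta=+0.007 rad, residual=4.3% of tissue area
segmented 14 lumens and 62 nuclei (ground truth: 14 / 62)
G_AVG_lumen_area = 230.357
G_AVG_lumen_roundness = 1.621
G_TOT_nucleus_count = 62.000
```

The recovered scale (6.43) is close to the physical pixel-size ratio
6.25/0.9636 ≈ 6.49; the 4.3% residual is the irreducible blockiness of the
coarse IR mask. Every ground-truth lumen and nucleus of this cancer-preset
sample is recovered. The mean lumen area (230 px² ≈ an 8.6 px radius) and
the high nucleus count are exactly the "many small round lumens, dense
nuclei" cancer morphology the features are built to capture; a benign-preset
sample scores several-fold larger lumens and fewer nuclei.

## Command line

```bash
mmhisto synth --n-benign 60 --n-cancer 60 --out cohort/ --seed 7
mmhisto run-all --manifest cohort/manifest.csv --out run/ --config cfg.toml
# or stage by stage:
mmhisto register --he a.tif --ir b.png --out params.json
mmhisto segment  --he a.tif --ir b.png --params params.json --out seg/
mmhisto extract  --manifest cohort/manifest.csv --out run/
mmhisto select   --features run/features.csv --out sel.json
mmhisto evaluate --features run/features.csv --mode cv --out report.json
```

Each stage writes resumable artifacts keyed by a hash of the configuration
that produced them; changing e.g. a segmentation constant invalidates that
stage and everything downstream. Samples whose registered epithelium is
smaller than `min_epithelium` (default 100 px) are excluded with a reason
code in `exclusions.csv`.

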