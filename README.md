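# qvasc — quantitative microvasculature morphometry

Malignant tumors grow disorganized, tortuous, densely branched microvessel
networks, while benign lesions keep organized, sparse ones. Contrast-free
high-definition microvasculature ultrasound can resolve these submillimeter
(~300 µm) vessels in 2-D, and the geometry of the resulting vessel map —
not just how much flow there is, but how the network branches, bends and
distributes itself — carries diagnostic signal. `qvasc` turns a segmented
2-D microvessel image of a lesion into that geometry and into a malignancy
score. It is written for researchers working on vascular imaging biomarkers
who need a testable, scriptable reference implementation.

## Biomarkers

From a binary vessel raster, its lesion mask and the pruned vessel skeleton
graph, `qvasc` computes per lesion:

**Initial morphometrics**

- **NB** — number of branch points (skeleton nodes joining ≥ 3 vessel segments);
- **NV** — number of vessel segments;
- **VD** — vessel density, vessel pixels / mask pixels;
- **D** (mm) — vessel diameter, 2 × the distance from centerline to vessel
  border (`D_mean`, `D_max` across segments);
- **DM** — distance metric (tortuosity), path length / straight-line distance
  between segment endpoints, ≥ 1 (`DM_mean`, `DM_max`).

**Structural (novel) biomarkers**

- **MD** — Murray's deviation at each branch,
  `MD = |D_mother³ − Σ D_daughter³| / D_mother³`,
  the departure from the cube law of optimal branching (mother = the incident
  sub-vessel with the largest diameter). If NB = 0, MD = 1.
- **mvFD** — microvessel fractal dimension by box counting: the slope of
  log N_s against log (1/s) over a dyadic ladder of box sizes s, a measure of
  network complexity.
- **BA** (°) — bifurcation angle between the two daughter vessels, from
  straight-line fits of the daughters near the branch. If NB = 0, BA = 180°.
- **VDR / SVP** — vessel density ratio `VDR = VD_center / VD_peripheral` over
  an erosion split of the lesion mask, binarized into the spatial vascularity
  pattern: SVP = 0 if VDR < 1 (peritumoral vascularity), SVP = 1 if VDR > 1
  (intratumoral vascularity).

A multivariable logistic model combines biomarkers into a malignancy
probability `p = logit⁻¹(B + Σ Cₘ Pₘ)` with ROC/AUC analysis (bootstrap CI,
Youden operating point), Wilcoxon rank-sum group comparisons and Pearson
correlation of biomarkers.

Because no patient data ships with the package, a seeded synthetic
vascular-tree generator (`qvasc.synthetic`) produces lesions with exact
ground-truth centerlines, radii, branch angles and radius-scaling exponents;
every stage of the pipeline is validated against it.

## Worked example

```python
import qvasc
from qvasc.biomarkers import extract_all
from qvasc.segmentation import VesselImage

lesion = qvasc.generate_lesion(label="malignant", size_class="medium", seed=11)
bm = extract_all(VesselImage(lesion.image, lesion.pixel_spacing, mask=lesion.mask))
print(bm.NB, bm.NV, round(bm.mvFD, 3), round(bm.MD_mean, 3),
      round(bm.BA_mean, 1), bm.SVP)
```

prints

```
10 22 1.575 0.218 67.4 1.0
```

— a malignant-like 11.3 mm lesion whose raster resolves into 22 vessel
segments joined at 10 branch points, with a fractal dimension of 1.58
(complex network), a mean Murray deviation of 0.22 (clear departure from
cube-law branching), a mean bifurcation angle of 67° (narrow, typical of
sprouting angiogenesis) and SVP 1 (centrally concentrated vessels, the
malignant pattern for small/medium lesions).

The same pipeline is scriptable from the shell:

```bash
qvasc simulate --n-benign 20 --n-malignant 20 --size-class mixed --seed 1 --out cohort/
qvasc extract  --in-dir cohort/ --out extracted/
qvasc classify --cohort extracted/biomarkers.csv --feature-set combined --out model/
qvasc report   --cohort extracted/biomarkers.csv --out report/
```

`classify` prints the fitted model's AUC with a bootstrap 95% CI plus
sensitivity, specificity, PPV and NPV at the Youden operating point, and
writes the model (intercept, coefficients, threshold) as JSON. Feature sets:
`new` (MD, mvFD, BA, SVP), `initial` (NB, NV, VD, D, DM), `combined`, and
`combined_birads` (adds an ordinal BI-RADS column if your cohort table has
one).

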