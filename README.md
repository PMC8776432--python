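# histokurt

Quantitative H&E histology features and survival analysis for clear cell
renal cell carcinoma (ccRCC), built around one interpretable biomarker: the
**excess kurtosis of the hematoxylin concentration in the perinuclear
cytoplasm** (`kurtosis_hC`).

## The problem

ccRCC cells classically carry lipid- and cholesterol-ester-rich "clear"
cytoplasm. When tumors lose that lipid storage — a feature of more
aggressive disease — the cytoplasm fills with stained parenchyma and
organelles, and the distribution of hematoxylin uptake around each nucleus
changes shape: the sharp near-zero spike of clear cytoplasm disappears and
the distribution flattens. Excess kurtosis of the cytoplasmic hematoxylin
channel captures exactly this, so *low* kurtosis flags lipid-poor,
worse-prognosis tumors. This package implements the full measurement chain
from RGB tiles to hazard ratios, plus a synthetic-data module that makes
every stage testable without whole-slide images.

## Pipeline

1. **Region selection** — raster patches; keep tumor patches by user mask,
   external classifier verdicts, or an optical-density tissue heuristic.
2. **Stain separation** — Beer–Lambert optical density
   `OD = -log10(I / I0)`; per-slide stain vectors by the Macenko procedure
   (PCA plane of the OD cloud, extreme angle percentiles); least-squares
   deconvolution into hematoxylin/eosin concentrations `c_h, c_e`;
   per-slide percentile normalization so channels are comparable across
   slides.
3. **Segmentation** — marker-controlled watershed on `c_h` for nuclei; the
   cytoplasm compartment is the ≤ 4 µm perinuclear band, each pixel
   assigned to its *nearest* nucleus, so adjacent cells' rings shrink
   rather than overlap.
4. **Features** — 12 intensity statistics (min, max, mean, median,
   mean−median, SD, IQR, MAD, skewness, excess kurtosis, histogram energy,
   histogram entropy) × 4 blocks (hN, eN, hC, eC = channel × compartment),
   median-aggregated per patient; plus spatial density heatmaps of
   low-kurtosis cells.
5. **Survival** — Cox proportional hazards (Efron ties) for univariate
   screens and stepwise-AIC multivariate models with age/gender/stage;
   optimal dichotomization by the maximally selected log-rank statistic
   with a Brownian-bridge (Lausen-type) multiplicity-adjusted p-value;
   Kaplan–Meier curves and the log-rank test.

The synthetic-data module generates Beer–Lambert H&E scenes (elliptical
nuclei, textured cytoplasm, lipid vacuoles with a tunable area fraction that
controls `kurtosis_hC`) and exponential proportional-hazards cohorts with
known effect sizes, so recovery of every quantity can be checked against
ground truth.

## Worked example

`examples/05_full_pipeline.py` builds a 20-patient × 4-tile cohort in two
vacuole-fraction groups, wires the simulated hazard to each patient's true
cytoplasm kurtosis (log hazard ratio −1.2 per SD, so low kurtosis means
worse prognosis), and runs the whole pipeline:

```text
cutpoint on kurtosis_hC: 3.730 (adjusted p = 0.042)
hazard ratio, high vs low kurtosis: 0.099
log-rank: chi2 = 11.21, p = 8.13e-04 (7 high / 13 low patients)
```

The pipeline blindly recovers the designed structure: splitting patients at
the data-driven kurtosis cutpoint gives the high-kurtosis group a hazard
ratio of ≈ 0.1 (strongly protective) with a log-rank p < 0.001. The other
examples (`examples/01–04`) demonstrate each stage in isolation — scene
generation, stain-vector recovery to ~1°, exact nucleus counts with
Jaccard > 0.9, and Cox/cutpoint estimation on simulated cohorts.

A thin CLI mirrors the library (`histokurt simulate | tile | select |
normalize | segment | survival | run-all`); the importable API is the
primary interface.

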