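# ihcquant

Quantitative digital image analysis (DIA) of brightfield immunohistochemistry
(IHC) stained with hematoxylin and DAB, built for receptor-expression studies
(e.g. somatostatin receptor SST2 in neuroendocrine and pituitary tumors) where
a continuous, operator-reproducible readout is needed alongside — and validated
against — the classic semi-quantitative immunoreactivity score (IRS).

It is aimed at pathology and endocrinology groups who photograph representative
fields from stained slides, outline the tumor tissue, and want per-field,
per-sample and per-observer quantification plus the statistics to prove the
method agrees across observers and with manual scoring.

## What it computes

**Stain separation.** A brightfield RGB field is converted to optical density
(OD = −log₁₀ I/I₀) and deconvolved through the Ruifrok–Johnston H-DAB unit
vectors (Beer–Lambert mixing). Each stain concentration map is scaled by a
fixed saturation OD (2.0) and clipped to [0, 1], so 1 is a reproducible
"maximum staining" ceiling across images.

**Cell detection.** Nuclei are segmented on the hematoxylin channel (Gaussian
smoothing, Otsu threshold inside the region of interest, size filtering,
distance-transform watershed for clumps); whole cells are delimited by
expanding each nucleus up to 10 px toward the nearest nucleus. A cell is
DAB-positive when ≥ 10 % of its pixels exceed DAB 0.15.

**Measures.** For each field with ROI Ω and n cells of which n⁺ are positive:

    %PC = 100 · n⁺ / n
    intensity/area = ( Σ_{p∈Ω} DAB(p) ) / |Ω|   ∈ [0, 1] AU/pixel

Up to four fields are averaged per sample for each selector/analyzer pair
(S1/S2 choose fields, A1/A2 outline the ROI), and pair values can be averaged
across combinations.

**IRS.** The manual score: a %PC category (0: none; 1: <10 %; 2: 10–50 %;
3: >50–80 %; 4: >80 %) times an intensity category (0–3), range 0–12.

**Validation statistics.** Lin's concordance correlation coefficient
ρ_c = 2σ_xy / (σ_x² + σ_y² + (μ_x−μ_y)²) with Fisher-z CI and agreement
categories (≥0.800 acceptable, ≥0.950 strong), Spearman correlation,
Kruskal–Wallis / one-way ANOVA, and ROC analysis with the Youden-index
cut-off (max sensitivity + specificity − 1), DeLong AUC confidence intervals
and the DeLong paired test.

**Synthetic data.** A generator produces H-DAB fields with known cell count,
positive fraction and stain strength via the exact forward model of the
deconvolution, plus observer tables with a closed-form CCC and copula-based
response tables — so every part of the pipeline can be exercised and
calibrated without any slide.

## Worked example

```python
from ihcquant import (FieldSpec, generate_field, analyze_field, irs_from_pct,
                      ObserverModel, generate_observer_tables,
                      concordance_correlation)

image, roi, truth = generate_field(
    FieldSpec(n_cells=300, frac_positive=0.6, dab_level=0.5, seed=42))
metrics, cells, channels = analyze_field(image, roi)
print(f"%PC: {metrics.pct_positive:.1f} (true {truth.true_pct_positive:.1f})")
print(f"intensity/area: {metrics.intensity_per_area:.4f} "
      f"(true {truth.true_intensity_per_area:.4f})")
print(f"IRS: {irs_from_pct(metrics.pct_positive, intensity_score=2).irs}")

tab = generate_observer_tables(60, ObserverModel(selector_sd=3, analyzer_sd=2,
                                                 measurement_sd=3, seed=7))
w = tab.pivot_table(index="sample_id", columns=["selector", "analyzer"],
                    values="value")
r = concordance_correlation(w[("S1", "A1")], w[("S2", "A2")])
print(f"CCC: {r.ccc:.3f} (95% CI {r.ci_low:.3f}-{r.ci_high:.3f}, {r.category})")
```

Output:

```
%PC: 60.3 (true 60.0)
intensity/area: 0.1603 (true 0.1593)
IRS: 6
CCC: 0.898 (95% CI 0.838-0.936, acceptable)
```

The pipeline recovers the generated positive fraction to within a fraction of
a percentage point (302 of 300 planted cells detected, misassignments cancel),
the intensity measure matches the noiseless ground truth to ~0.001 AU/px, and
the observer model's agreement is estimated with a CI that reflects n = 60
samples.

## Command line

```sh
ihcquant simulate --out sim/ --n-fields 4 --seed 1   # synthetic study inputs
ihcquant quantify --manifest manifest.csv --config run.toml --out results/
ihcquant score-irs --in pct.csv --out irs.csv
ihcquant agree --in long.csv --out ccc.csv           # pairwise observer CCCs
ihcquant roc --in scores.csv --out roc/              # AUC, CI, Youden cut-off
```

`quantify` writes per-image, per-sample and per-combination CSVs plus a
run-record JSON (config echo, input hashes, package version) for
reproducibility; failed images are logged and skipped without aborting the run.

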