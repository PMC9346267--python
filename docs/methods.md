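# Methods

## Stain model

A brightfield H-DAB image is modeled as multiplicative light absorption
(Beer–Lambert): for incident intensity I₀ per channel and transmitted
intensity I, the optical density OD = −log₁₀(I/I₀) is linear in the stain
concentrations along fixed unit color vectors. We use the Ruifrok–Johnston
vectors for hematoxylin (0.650, 0.704, 0.286) and DAB (0.268, 0.570, 0.776),
with the residual axis as their normalized cross product; the matrix is
user-overridable (nine floats, row-major) for other stain batches or scanners.

Deconvolved concentrations are divided by a fixed saturation OD of 2.0 and
clipped to [0, 1]. The ceiling makes "1 = maximum staining" a reproducible
constant: at OD 2.0 a pure stain transmits 1 % of incident light, i.e. 2–3
intensity counts in an 8-bit image, which is effectively the darkest staining
a brightfield scanner can distinguish from black. Per-image normalization
(e.g. dividing by the image max) was rejected because it would make
intensity/area incomparable between images.

Numerical guards: ε = 1/white-point inside the log (below quantization
noise); negative concentrations from deconvolution noise are clipped to 0.
The white point defaults to the dtype maximum; an optional estimator takes
the per-channel median of the brightest 1 % of pixels for scanners whose
background is not fully white. The forward synthesis (`recombine`) is exact
up to these clips, which gives the test suite a round-trip oracle: separate ∘
recombine recovers channel maps to < 0.02 absolute error away from
saturation in float images. In 8-bit images the same bound holds for
concentrations up to ~0.7 of saturation; beyond that the darkest pixels carry
only a few counts and quantization dominates.

## Segmentation

Nuclei: Gaussian smoothing (σ = 2 px), Otsu threshold computed over ROI
pixels only, connected components, size filter (40–5000 px), and a
distance-transform watershed seeded from h-maxima (h = 2 px) to split
touching nuclei — the standard declumping construction. An absolute floor of
0.05 on the Otsu threshold prevents a blank field's noise from being split
into "nuclei": below it the field is reported as nucleus-free with a warning.
Objects are kept iff their centroid lies inside the ROI (one rule, no double
standard at the manual outline); their full extent is retained.

Cells: each nucleus is expanded outward up to 10 px; every contested pixel
goes to the nucleus at the smallest Euclidean distance, exact ties to the
lower label id (deterministic, label-ordered — never hash-ordered). The
implementation computes a per-nucleus distance transform on a padded bounding
window and keeps a global best-distance map, which makes the tie-break exact
rather than dependent on a feature transform's scan order. Expanded pixels
are clipped to the ROI; nucleus pixels are always retained, so cell count
equals nucleus count by construction.

Positivity: a cell is DAB-positive iff ≥ 10 % of its pixels have DAB channel
value ≥ 0.15. Both constants are configurable and deliberately global rather
than per-image (an adaptive threshold would manufacture positive cells in a
truly negative field, contradicting the "no positive cells" category of the
manual score). The values are an explicit design choice of this package: at
0.15 of saturation a pixel is visibly brown, and 10 % of pixels distinguishes
whole-cell staining from a stray blob. The whole-cell (membrane +
cytoplasm + nucleus) territory is scored; no compartment separation is
attempted.

## Measures and aggregation

Per field: %PC = 100 · positive/total cells; intensity/area = sum of the DAB
channel over all ROI pixels (stained and unstained) divided by the ROI pixel
count, in [0, 1] AU/pixel. Summing over the whole ROI, not only positive
cells, is intentional: the denominator then reflects the analyzed tissue area
and the measure mixes staining strength with its spatial extent.

A field with zero detected cells has *missing* %PC (0/0 is not "0 % positive")
and missing values propagate into CSV as empty fields; such fields are
excluded from the %PC mean only. Sample values are unweighted means of up to
four fields per selector/analyzer pair; combination means are unweighted
means over the available pairs (≤ 4: S1A1, S1A2, S2A1, S2A2). Duplicated
pairs and mixed sample ids are rejected.

## IRS

Product of the %PC category (0: none; 1: <10; 2: 10–50; 3: >50–80; 4: >80)
and the intensity category (0–3), range 0–12; achievable values are exactly
{0, 1, 2, 3, 4, 6, 8, 9, 12}. The printed bins leave (50, 51) open; we close
them as [10, 50] → 2 and (50, 80] → 3 so the step function is total and
monotone on [0, 100]. The intensity category is always a human input — no
mapping from pixel intensity to the 0–3 scale is defined or implied.

## Agreement and ROC statistics

Lin's CCC uses 1/n moments (the original estimator; a flag switches to the
bias-corrected 1/(n−1) variant). The 95 % CI applies the Fisher
z-transformation with Lin's asymptotic standard error

  SE_z² = [ (1−r²)ρ_c²/((1−ρ_c²)r²) + 2ρ_c³(1−ρ_c)u²/(r(1−ρ_c²)²)
            − ρ_c⁴u⁴/(2r²(1−ρ_c²)²) ] / (n−2),

with u the standardized mean difference and r the Pearson correlation; when
the geometry degenerates (r ≈ 0 or |ρ_c| = 1) the CI falls back to the plain
Fisher SE or collapses to the point estimate. A coverage simulation in the
test suite checks the CI empirically. Agreement categories are inclusive at
both cuts: < 0.800 none, ≥ 0.800 acceptable, ≥ 0.950 strong.

ROC: the AUC is the Mann–Whitney concordance probability (identical to the
trapezoidal area under the empirical curve); its CI and the paired
two-curve test use DeLong's structural components, computed by the mid-rank
formulation. The reported cut-off is the midpoint between consecutive
distinct observed scores maximizing Youden's J, ties resolved to the lower
cut-off — midpoints make the reported threshold independent of which side of
a data value the operating point sits on. If the raw AUC is below 0.5 the
decision direction flips and is reported (`direction="lower"`), so a
negatively associated predictor (e.g. receptor expression vs a hormone level
that falls with response) still yields an interpretable AUC > 0.5 with a
cut-off on the original scale. The paired comparison test is DeLong's; p
values are two-sided everywhere and no multiple-testing correction is
applied.

Kruskal–Wallis uses the tie-corrected H with a χ² p-value; when every pooled
observation is identical the test statistic is defined as 0 with p = 1
(no evidence of shift) instead of erroring.

## Synthetic data

`generate_field` dart-throws nuclei (radius ~ N(8, 1) px, truncated at 3 px)
with centers at least r_i + r_j + 2 px apart inside a rectangular ROI inset
16 px from a 512×512 8-bit frame; placement aborts after 5000 consecutive
rejections (infeasible density). Hematoxylin is deposited on every nucleus at
0.6 of saturation; DAB on positive cells over the nucleus plus a 4 px
perinuclear ring clipped to the cell's own nearest-nucleus territory
(whole-cell staining without bleeding into neighbours). Both maps are blurred
(σ = 1 px) for soft edges, composed to RGB by the forward Beer–Lambert model,
and Gaussian pixel noise (SD 2 counts) is added and clipped. Defaults keep a
field under ~2 s to generate and ~1 s to analyze on a laptop-class CPU.

The generator emulates the geometry and photometry the pipeline measures —
not real histology: no texture, no fibrosis/vessel artifacts, no scanner
color profiles, no overlapping or out-of-focus nuclei, and a rectangular ROI.
Passing recovery tests therefore demonstrates the pipeline's internal
consistency (deconvolution, counting, classification, arithmetic), not
robustness to real-world tissue variability.

`generate_observer_tables` draws a latent truth per sample (default
N(50, 15), a mid-range %PC distribution) and adds per-(sample, selector),
per-(sample, analyzer) and per-measurement Gaussian effects. For two
combinations the implied CCC is (σ_T² + shared effect variances) /
(σ_T² + σ_S² + σ_A² + σ_E²) — equal means and variances make the closed form
exact — giving a parameter-recovery loop with the CCC estimator. Values are
clipped to the measure's range after noise; with defaults the truth is > 3 SD
from both limits, so the attenuation is negligible, but extreme truth
distributions will shrink agreement slightly.

`generate_response_tables` uses a bivariate Gaussian copula with Pearson
parameter r = 2 sin(π ρ_s/6), which yields the requested Spearman correlation
exactly for continuous marginals; the staining measure is uniform on
(0, 0.6) (an intensity/area-like scale) and the response is log-normal with
median 1, so the "normalized" flag splits the cohort roughly in half.

## Known limitations

* The stained-cell criterion (0.15 / 10 %) is a package convention; absolute
  %PC values on real slides depend on it and should be calibrated per study.
* Nuclei counting assumes roughly convex, mostly non-overlapping nuclei;
  heavily confluent tissue will undercount and the watershed h parameter
  needs retuning.
* Whole-slide formats are out of scope; inputs are selected fields (TIFF/PNG)
  with per-field ROI masks.
* The CCC CI is asymptotic; for n < ~15 it is approximate (the coverage test
  runs at n = 50).
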