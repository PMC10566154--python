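# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and what the test suite does and does not demonstrate.

## Ground-photo FVC (two-Gaussian a\* mixture)

An sRGB photo is converted to CIE L\*a\*b\* (D65 white point, standard sRGB
companding). The a\* histogram — 256 equal-width bins over [min, max],
density-normalized — is fitted by bounded nonlinear least squares with the
five free parameters (w₁, β₁, δ₁, β₂, δ₂; w₂ = 1 − w₁). Initialization
takes the two largest local maxima of the smoothed histogram, falling back
to 1-D k-means when fewer than two peaks appear. Vegetation is the
lower-mean component (greener leaves have smaller a\*).

Two estimators are reported: the fitted weight w₁ (headline — unbiased when
the components overlap, because the fit apportions the overlap region) and
the fraction of pixels below the equal-density threshold
w₁N(x; β₁, δ₁) = w₂N(x; β₂, δ₂), solved by Brent's method on (β₁, β₂) with
a midpoint fallback when no crossing exists. A mixture is flagged
*degenerate* when the fitted separation |β₂ − β₁| < 0.75(δ₁ + δ₂) or a
weight collapses below 10⁻³ — the bimodality boundary of a balanced
mixture — and then a manual threshold must be supplied, mirroring field
practice for photos that defeat the fit (waterlogged or nearly single-class
plots). The pipeline uses a fixed fallback cutoff of a\* = −5 for such
photos and for the bare-path reference squares.

## Scale bridging

*Downscaling* uses separable cubic convolution with the kernel
W(x) = |x|³ − 2|x|² + 1 (|x| < 1), −|x|³ + 5|x|² − 8|x| + 4 (1 ≤ |x| ≤ 2).
The pixel-centre mapping src = (dst + 0.5)/factor − 0.5 was chosen because
it makes the centre fine pixel of each block coincide exactly with the
source node for odd factors (so 10 m values survive in the middle of the
2 m blocks — the behaviour the workflow relies on). Borders are handled by
replicate (clamp) padding. A target cell whose 4×4 source window touches
nodata becomes nodata; a flag switches to renormalizing the remaining
weights instead (applied separably per pass). The kernel argument is the
signed node distance; it is never a reflectance value.

*Upscaling* is the zonal mean: a 2 m cell averages the fine pixels whose
centres fall inside it (half-open extents, so ties are impossible);
2 m → 10 m aggregation is the 5×5 block mean with partial blocks set to
nodata.

## FVC_UAS estimators

RFR and SVR stand on scikit-learn estimators behind this module's surface;
grid search is written here so ties break deterministically (lowest CV
RMSE, then fewer trees / smaller cost, then smaller Mtry / gamma). Trees
split on variance reduction and the forest predicts the mean over trees;
SVR z-scores features inside its pipeline. The NDVI dichotomy selects
endmembers as the 5th/95th percentiles of valid NDVI by default, with
literal overrides — on scenes that never reach full canopy the 95th
percentile underestimates NDVI_v and stretches the dichotomy scale, which
is why its wall-to-wall RMSE on the jointing-stage scene is several times
the RFR's (a known weakness of statistical endmember selection, not a code
defect). The half-Gaussian method fits A·exp(−(x−μ)²/2σ²) to the outer
flank of each a\* peak with the mean pinned near the flank's inner edge
(the fit is otherwise ill-posed on truncated tails), reconstructs the two
full Gaussians with weights w = A√(2π)σ, and thresholds at their
equal-density point; flanks populated by fewer than 30 bins are flagged
degenerate.

## Satellite BPNN

Architecture 3–6–1: z-scored green/red/NIR inputs (scalers learned on the
training split), logistic-sigmoid hidden layer, linear output clipped to
[0, 1] at prediction only. With at most 31 weights, training is full-batch
Levenberg–Marquardt: solve (JᵀJ + λ diag JᵀJ)δ = −Jᵀr with analytic
Jacobian, λ starting at 10⁻³, ×10 on a rejected step and ÷10 on acceptance.
Pairs split 8:1:1 (train/validation/test), seeded; weights initialized
U(−0.5, 0.5). Training stops when validation RMSE ≤ 0.06 (the goal), after
15 iterations with relative validation-RMSE change below 10⁻⁵ (patience),
or at 5,000 iterations. A non-finite update halves λ for one retry, then
aborts with diagnostics. The data-volume experiment trains each subsample
to convergence (goal lowered to 10⁻³, 400-iteration cap) so that
sample-size effects are not masked by the goal stop triggering after a
handful of iterations; RMSE is measured on a held-out fraction fixed across
sizes and repeats.

## Synthetic study conditions

The generator's defaults define the conditions every end-to-end figure is
computed under:

* **Scene** (per stage): 300 × 150 m, two wheat fields of 145 × 150 m
  separated by a 10 m bare corridor aligned with the satellite grid; 10 m
  satellite GSD, 2 m target cells. The pipeline rasterizes at a 0.2 m UAS
  working GSD (5 × 10⁵ fine pixels per band per stage; 22,500 2 m cells over
  the two stages), a problem size chosen so a full run completes in tens of
  seconds; `SceneConfig` itself defaults to the sensor-realistic 0.05 m for
  single-scene work.
* **FVC field**: Gaussian-smoothed seeded white noise, min–max rescaled per
  stage (jointing 0.2–0.8, booting 0.7–0.98), correlation length 25 m —
  treatment-plot-scale variation, large enough that within-10 m-pixel
  variance does not dominate the error budget. Paths are bare (FVC 0).
  Cover ramps linearly from 0 at a field edge to its interior level over
  15 m (*edge taper*): real canopies thin toward margins rather than
  stopping in a knife edge, and the taper width of the order of one
  satellite pixel is what makes 2 m truth near boundaries recoverable at
  all from 10 m reflectance. Sharper margins leave an irreducible
  representation error at boundary cells (visible by shrinking
  `edge_taper_m`).
* **Spectra**: vegetation {green 0.08, red 0.03, red edge 0.30, NIR 0.55},
  soil {0.15, 0.20, 0.22, 0.25} — NDVI ≈ 0.90 vs ≈ 0.11, typical canopy and
  dry-soil values; per-band Gaussian sensor noise σ = 0.01 (UAS at the fine
  scale, satellite at the 10 m scale — the satellite render is a pure block
  mean of noiseless fine reflectance with noise added afterwards, so sensor
  noise is not averaged away). An `ndvi_linear` variant equalizes
  vegetation and soil red+NIR sums, making pixel NDVI exactly linear in
  FVC for exactness checks. A `nir_saturation` option adds NIR variance
  that ramps in above a cover knee, emulating the canopy NDVI-saturation
  regime.
* **Photos**: vegetation a\* ~ N(−20, 4), background ~ N(10, 5); L\* and
  b\* constant per class so the a\* histogram is the only information
  channel. Class counts are exact (realized cover within one pixel quantum
  of the target). Out-of-gamut Lab colors are clipped with the clipped
  fraction reported (≈ 0 at the defaults).
* **Ground campaign**: 30 five-point sites per stage placed inside fields,
  plus 10 single 2 m bare-path reference squares per stage — low-cover
  anchors without which the tree-based label model extrapolates flat below
  the sampled FVC range and mislabels corridors. Bare-square photos use the
  fixed manual threshold (they are single-class by construction).

What the generator does **not** emulate: radiative transfer and BRDF,
shadows and specularities, co-registration error, atmospheric residuals,
non-soil backgrounds, within-canopy row structure. Passing tests therefore
demonstrate the correctness and internal consistency of the workflow under
linear mixing with Gaussian noise — not retrieval accuracy on real imagery.

## Evaluation choices

R² is computed as 1 − SS_res/SS_tot (the standard coefficient of
determination for predictions; the ratio-of-sums form coincides with it
only under an OLS fit with intercept). Boundary cells are those whose
centres lie within 5 m of any field perimeter; 150 cells per stratum are
sampled without replacement, per stage. The strategy comparison evaluates
upscale-downscale at 2 m and block-aggregated 10 m, and the upscale-only
comparator (an identical BPNN trained on 10 m reflectance with 10 m zonal
labels) both at 10 m and block-replicated to 2 m — the latter is how a
10 m product is judged against 2 m reference samples and is where the
sub-pixel strategy's advantage at boundaries appears. Percent change is
(RMSE_old − RMSE_new)/RMSE_old × 100.

## Known limitations

* Endmember spectra, photo color statistics and the scene layout are
  configurable stand-ins; none is calibrated to a real sensor.
* The dichotomy baseline's percentile endmembers are biased whenever the
  scene lacks pure cover classes (see above).
* The half-Gaussian threshold is only weakly identified when class spreads
  differ and the inter-mode valley is flat; agreement with the mixture
  threshold is asserted for the symmetric, well-separated case.
* The BPNN input bands default to green/red/NIR; the band list is
  configurable where a red-edge-based variant is wanted.
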