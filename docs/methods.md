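# Methods notes

This note records the models behind `colosig`, the defaults that matter,
what the synthetic-data generator does and does not emulate, and the
numerical choices made where the underlying conventions are not uniquely
determined.

## Reference assay (RID)

A 24-well plate carries three reference sera and up to 21 diluted
colostrum samples (1:5 v/v for IgG, 1:3 for IgA/IgM). Ring diameters map
to well-level concentrations through a per-plate standard curve fitted by
least squares to the three sera; with exactly collinear points this is an
exact interpolation, and with noisy sera it degrades gracefully.

* **Curve model.** Default `mancini` (concentration linear in squared
  diameter), the appropriate form for an endpoint read after 24 h
  incubation; `fahey` (log-linear in diameter, the timed regime) is a
  config option. The functional form of commercial kit "standard
  equations" is not published, so both classical options are provided.
* **Kit range.** Well-level detection ranges are config values defaulting
  to the reference-sera span ±20%; conversions outside the range return
  missing with an `out_of_range` flag (QC rule iv). Rules i–iii
  (no signal, weak ring, elliptical ring) are boolean well annotations.
* **Precision.** `CV_RID` is the mean over samples of replicate SD /
  replicate mean × 100, with the n−1 SD divisor throughout the package;
  a value below 10% justifies single-well determination.

## Spectral pretreatments

Spectra are log(1/R) absorbance on a 400–2499.5 nm grid at 0.5 nm
(4200 points). The treatment grid crosses five scatter options
(none, detrend, SNV, SNV+detrend, MSC) with five derivative codes
(0,0,1,1; 1,4,4,1; 1,8,8,1; 2,5,5,1; 2,10,10,1).

* **Order.** Scatter correction first, derivative second (the WinISI
  convention); `snv_detrend` is SNV then detrend.
* **Detrend** removes a per-spectrum quadratic (the classical Barnes
  detrend). Polynomial spaces are affine-invariant, so detrending against
  a normalised index grid equals detrending against wavelength.
* **MSC** stores the calibration-set mean at fit time; validation and
  prediction spectra are always corrected against that stored mean, never
  their own.
* **Gap–segment derivative** `(d,g,s1,s2)`: running mean over `s1`
  points, then `a[i+⌈g/2⌉] − a[i−⌊g/2⌋]` for d=1 (gap split as evenly as
  possible) or `a[i+g] − 2a[i] + a[i−g]` for d=2, then a running mean
  over `s2`. The exact endpoint semantics of the commercial
  implementation are proprietary; this documented choice is isolated
  behind `PretreatmentSpec` so it can be swapped. Edges where a window is
  incomplete are dropped and the valid grid is narrowed; all model
  fitting uses the common valid grid.

## Modified PLS

`MPLSRegressor` implements univariate NIPALS PLS with the
Shenk–Westerhaus modification: after extracting each factor, the spectral
residual at each wavelength is divided by that wavelength's residual SD
before the next factor is computed. The per-factor SD vectors are stored
and replayed at prediction. With `scale_residuals=False` the algorithm
is exactly textbook PLS1 (verified against scikit-learn to 1e−8), which
serves as the independent oracle in the tests.

* **LV selection.** 20 random cross-validation groups; within each
  training fold the pretreatment statistics (e.g. the MSC mean) are
  refitted so no held-out information leaks. The chosen LV count is the
  smallest whose RMSE_CV is not significantly above the curve minimum by
  a one-sided F test, `F = (RMSE_CV(l)/RMSE_CV(l*))²` against
  `F(α; n, n)` with α = 0.25 (the classical Haaland–Thomas rule); ties in
  the argmin go to fewer LV.
* **Outlier passes.** Up to three refits. Per pass:
  `H = D²/LV` (Mahalanobis distance of the sample's score vector from
  the score centroid, scaled so the calibration mean H is ≈ 1), removed
  above 10; `T = |y − ŷ|/SEC` (standardised calibration residual,
  SEC with `n − LV − 1` degrees of freedom), removed above 3; `X` =
  sample unmodelled spectral sum-of-squares over the calibration average,
  removed above 10. The "T" and "X" rules of commercial NIR software are
  described only qualitatively; these are documented interpretations
  isolated behind function boundaries. Two degenerate-input conventions:
  a numerically perfect calibration (SEC or mean residual SS at round-off
  level) reports T = 0 and X = 0 — a perfect fit has no outliers, and
  ratios of round-off noise are meaningless. Note that on *noisy* but
  clean Gaussian data the T > 3 rule still fires on ≈ 0.3% of samples by
  chance; zero-removal guarantees only hold for noise-free input.
* **Applicability domain.** `GH` is H evaluated for a new spectrum;
  `NH` is the distance to the nearest calibration spectrum in the same
  standardised score metric, divided by LV. Predictions with GH > 3.5 or
  NH > 2.0 are flagged `excluded`; flags never alter the predicted
  values. The GH scale assumes a moderate number of LVs — with very few
  LVs the χ²-like null distribution of H is heavy-tailed and a small
  fraction of calibration samples can exceed 3.5 by chance.
* **Model choice.** One model per grid cell (25 by default); the winner
  has the lowest RMSE_CV at its selected LV. The full leaderboard is
  always reported.

## Animal-model REML

The bivariate animal model treats the reference assay and its NIR
prediction as two traits with block-diagonal fixed-effect design
(parity 1/2/3/4/5+, calving season from the calving month, herd),
additive covariance `G₀ ⊗ A` and residual covariance `R₀ ⊗ I` where the
residual covariance between traits applies only to animals recorded for
both. Records missing one trait enter by exact Gaussian marginalisation
(the observed-data covariance simply lacks their rows), not imputation.

* **Algorithm.** Average-information REML on the observed-data
  likelihood, with step halving whenever a proposed update would lower
  the restricted log-likelihood and eigenvalue projection of `G₀`/`R₀`
  back to the PSD cone (floor 1e−8 of the mean phenotypic variance).
  The log-likelihood path is therefore non-decreasing. Convergence:
  relative log-likelihood change < 1e−8 and relative parameter change
  < 1e−6 (both configurable).
* **Standard errors.** Inverse of the final AI matrix; SEs of h², r_a
  and r_p by the delta method with numerical gradients.
* **Boundary estimates.** When a genetic variance is driven to the PSD
  floor, the corresponding correlation is formally ±1 with an enormous
  SE — this is reported as-is rather than masked, because it is what the
  likelihood says (field software behaves the same way; such runs are
  the analogue of a "not converged" cell in applied reports). Small-h²
  traits also acquire a positive truncation bias in repeated sampling,
  since the PSD constraint folds the sampling distribution at zero.
* **Rescaling.** Low-variance traits (IgA, IgM) may be multiplied by 100
  before fitting to avoid tiny-component convergence trouble; REML is
  equivariant under rescaling (variances × c², ratios unchanged), which
  the tests verify.
* **Which animals carry the predicted trait.** Default: validation-set
  animals only, because calibration animals' self-predictions are
  optimistically accurate; `predicted_records="all"` is available.

## Selection theory

Deterministic two-pathway (sires/dams) engine with generation intervals
6 and 4 years and selection intensity 1.76 (top 10%). Per-generation
pathway responses are `R_g = r_IH · σₐ` and the annual response is
`R_y = i (R_g,bulls + R_g,dams)/(L_s + L_d)` — i.e. the intensity enters
once, at the annual level. The alternative Rendel–Robertson convention
(intensity inside each `R_g`) is selectable and changes only the
reported per-generation numbers, not `R_y`. The additive SD of the
breeding goal used by the shipped scenario set is σₐ = 13.26 g/L, the
value implied by the ratio of per-generation responses to accuracies
across the scenario table. Dam-side accuracies in the shipped scenarios
are inputs (0.480 / 0.330 / 0.486): they are not reproducible as √h²
from the scenario heritabilities, so the engine takes dam accuracy as a
parameter rather than silently forcing either value. The
correlated-response ratio for an indicator trait uses the progeny-test
formula with n = 70 daughters per bull by default and i = 1 (equal
intensities in both programmes cancel).

## Synthetic-data generator

The generator is a stated world, not a tuning knob; its defaults are the
population the pipeline is designed for.

* **Pedigree.** Discrete generations; each generation mates the previous
  generation's females in groups of 4 per sire with 2 offspring per dam,
  giving paternal half-sib families over full-sib families. Defaults
  (192 founders, 3 generations) give ≈ 760 animals. Real pedigree
  depth/connectedness of field populations is unknown; these defaults
  are chosen for statistical power, not demographic realism.
* **Gene drop.** Founders ~ MVN(0, G₀); offspring get the parent average
  plus Mendelian sampling with covariance
  `(1 − 0.25(1+F_s) − 0.25(1+F_d)) G₀` (unknown parents drop their
  term), the standard scheme consistent with `var(a) = A G₀`. Verified
  against the tabular A matrix by 1e5-replicate Monte-Carlo and against
  an independent gene-flow (T D T') decomposition.
* **Phenotypes.** Mean + herd + parity + season + breeding value +
  residual. Targets: IgG 91.77/36.47 g/L (mean/SD), IgA 4.80/3.03,
  IgM 5.07/2.44; h² 0.15/0.13/0.24. The fixed-effect level shifts are
  fixed first; the base mean and the G₀/R₀ diagonals are then solved so
  the marginal moments hit the targets exactly in expectation. Parity
  classes 1–4 and 5+ (pooling 5–8) with proportions
  28.9/29.7/18.4/12.1/10.9%; seasons by calving month (winter Dec–Feb,
  etc.). Every animal carries one record (each animal stands for a cow
  with one colostrum sample). Negative concentrations are floored at
  0.1 g/L and flagged, not resampled, to keep the moments analysable.
* **Spectra.** Linear mixtures of smooth synthetic Gaussian-mixture
  signatures (IgG, IgA, IgM plus water and fat nuisance components)
  with multiplicative scatter `exp(N(0, 0.3))`, additive offset
  N(0, 0.1), a random quadratic drift and white noise (SD 0.003 AU).
  The scatter magnitudes correspond to strong path-length variation in
  a slurry cup and make scatter corrections genuinely load-bearing:
  SNV/MSC reduce RMSE_CV from ≈ 15 to ≈ 12 g/L against raw spectra at
  these settings. What the generator does **not** emulate: sharp real
  absorbance features (its signatures are broad Gaussians, so
  derivative pretreatments mostly amplify white noise and rarely win
  the grid, unlike on real instruments), wavelength-correlated noise,
  instrument drift over time, and any nonlinear detector response.
  A green calibration test therefore establishes the machinery, not
  instrument-grade performance claims.
* **RID plates.** Sample concentrations are diluted, perturbed with
  multiplicative CV noise on the concentration scale, and pushed through
  the inverse standard curve to diameters, so the assay module's forward
  conversion recovers them exactly at zero noise.
* **Determinism.** All stages derive independent child RNG streams from
  one seed via CRC32-keyed `SeedSequence` spawning; identical configs
  give byte-identical datasets.

## Known limitations

* The REML solver is dense (O(N³) per iteration in the number of
  records); fine to a few thousand records, not for national
  evaluations.
* `NH` uses the final model's standardised score metric for both GH and
  NH; commercial neighbourhood definitions differ in unpublished ways.
* The multi-trait index accuracy assumes the criterion covariances are
  known without error; no reduction for estimated-parameter uncertainty.
* Selection scenarios ignore overlapping generations, discounted gene
  flow and inbreeding accumulation.
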