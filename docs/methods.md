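# Methods

This note documents the models behind `phospec`: what the synthetic
generator emulates, how the spectral deconvolution and the regression are
defined, which parameters matter, and where the design was genuinely open.

## Spectral forward model

A simulated spectrum on the instrument grid (600–4000 cm⁻¹ at 2 cm⁻¹
spacing, 1701 points, consistent with a 4 cm⁻¹ instrument resolution) is

```
A(ν) = Σ_b a_b · exp(−(ν − c_b)² / 2σ_b²) + baseline(ν) + ε(ν)
```

with one Gaussian oscillator per biochemical band plus a broad
polysaccharide absorption:

| band | center c (cm⁻¹) | width σ (cm⁻¹) | assignment |
| --- | --- | --- | --- |
| Po | 980 | 12 | P–O–H / P–O–C deformation (organic phosphate) |
| poly | 1000 | 55 | broad polysaccharide C–O–C absorption |
| cellulose | 1160 | 12 | C–O–C ether |
| Pi | 1200 | 10 | phosphoryl P=O stretch (inorganic phosphate) |
| lignin | 1510 | 12 | aromatic C=C |
| amide | 1550 | 12 | Amide II |
| lipid | 1710 | 14 | carbonyl |

Gaussian lineshapes are the default because they are standard for
condensed-phase ATR bands and have the closed-form area a·σ·√(2π);
Lorentzians are available. The baseline is a low-order polynomial in a
normalized wavenumber coordinate with per-plant random coefficients (offset
≤ 0.05, slope ≤ ±0.03, non-negative curvature ≤ 0.05 absorbance units), so
it is smooth and convex — the regime the rubber-band correction targets.
Measurement noise is i.i.d. Gaussian, default SD 0.004 absorbance
(SNR ≈ 100 for typical band amplitudes); technical replicates share their
plant's amplitudes and baseline and differ only in noise.

Cellulose and lignin share one width (12 cm⁻¹) so that equal amplitudes mean
equal areas; with unit Beer coefficients the quantified C/L ratio then
equals the amplitude ratio, which keeps the ratio invariant under
per-spectrum normalization.

## Dose–response model (lab design)

Band amplitudes are deterministic functions of medium P (µM) and N (mM),
times a lognormal plant-level factor (σ = 0.05 on the natural-log scale,
applied independently per component). Writing ℓ = log₁₀(P):

* **C/L ratio**: base + slope·ℓ + jump·logistic((ℓ − 1.82)/0.15). The jump
  height is solved in closed form so the latent C/L at 500 µM is exactly
  3× its mean over {1, 10, 30} µM. The logistic center (~66 µM) places the
  cellulose threshold between 30 and 150 µM.
* **lignin**: 0.45 − 0.02·ℓ, a gradual decline with P supply; the slope is
  deliberately below the C/L log-slope at high P so cellulose
  (= C/L × lignin) remains non-decreasing up to 500 µM.
* **Pi**: 0.08 + 0.42·ℓ/2.7 and **Po**: 0.15 + 0.25·ℓ/2.7 — linear in
  decades of P, rising with supply.
* **lipid and amide**: elevated under severe P starvation (a logistic stress
  term centered near 3 µM) and increasing with N supply.
* **broad polysaccharide**: 0.45 + 0.3 × cellulose amplitude.

All curve shapes are config-exposed (`DoseResponseParams`); only the 3-fold
C/L contrast is a hard calibration.

Two generator parameters were themselves calibrated rather than free: the
plant-level amplitude dispersion (σ = 0.05) and the measurement noise
(0.004). The study conditions this generator stands in for are ones where a
linear spectra→log-P map is nearly interpolating (training R² ≈ 1, 10-fold
MSEP < 0.01 on the bootstrap-augmented design); a seven-band forward model
carries far fewer P-covarying channels than a real leaf spectrum, so the
per-channel dispersion must be modest for the synthetic data to have the
same effective information content. With σ = 0.08 the same pipeline yields
MSEP ≈ 0.0095 and held-out R² ≈ 0.91 — an instructive sensitivity, but not
the regime the analysis assumes.

## Field-season model

Each site draws per-plant latent available P from a lognormal (means 30 µM
and 120 µM, log-SD 0.2); plant amplitudes follow the same dose–response.
Season structure enters through per-timepoint multipliers: Pi rises through
T4 and spikes at T5 on the high-P site (×1.8); Po plateaus near T4 and
declines at T5 there (×0.8); lignin multipliers rise and cellulose
multipliers fall monotonically, so the C/L ratio declines as tissue
lignifies. Each sampling visit adds an independent per-component lognormal
jitter (σ = 0.05) — leaves sampled a month apart are different leaves.
Second-year biomass is 300 + 150·ln(Pi/Po at T5) + N(0, 30) grams, positive
association by construction. A single `site_effect` scalar interpolates all
site differences to zero for null simulations, and the truth table can be
generated without rendering spectra (`simulate_field_truth`), which the
statistical calibration tests use.

What the generator does **not** emulate: water-vapor/CO₂ interference
bands, ATR penetration-depth dispersion, scattering artifacts, correlated
(pink) noise, band-shape changes with matrix composition, and any soil
chemistry. Passing tests therefore demonstrate the pipeline's correctness
and calibration under the stated statistical structure, not robustness to
every instrumental artifact of real ATR-FTIR data.

## Preprocessing

Fixed order: restrict to the modeling region [800, 1800) cm⁻¹ → baseline →
replicate aggregation → normalization. The order matters: per-spectrum
normalization does not commute with replicate averaging unless replicates
share a maximum, so averaging happens first; the applied order is recorded
in the output's provenance metadata.

* **Rubber-band** (default): subtract the lower convex hull of the trace;
  parameter-free, baseline at or below the signal everywhere. Between hull
  touch points a chord sits slightly above a convex baseline, which is why
  the oscillator fits carry a free per-window linear term (below).
* **Asymmetric least squares**: Whittaker smoother with asymmetry p = 0.01
  and smoothness λ = 1e5.
* **Polynomial**: iterative clipping fit, degree 2, 12 iterations.

Normalization scope is per-spectrum maximum over the modeling region for
band-quantification outputs (relative concentrations on a common scale).
The regression path deliberately skips normalization: the model is trained
on baseline-corrected spectra, and dividing by the region maximum — which
sits on the saturating cellulose/polysaccharide complex — was measured to
inject a systematic +0.2-decade prediction bias at the 150 µM level.
Intervals are half-open [lo, hi) throughout, so adjacent windows tile
without double-counting grid points.

## Band deconvolution

One bounded nonlinear least-squares fit per congested window: 900–1300 cm⁻¹
with four oscillators (Po, broad polysaccharide, cellulose, Pi),
1450–1620 cm⁻¹ with two (lignin, amide), 1650–1780 cm⁻¹ with one (lipid).
Initialization: centers at the assignment defaults, widths 10 cm⁻¹
(50 cm⁻¹ for the broad band), amplitudes from the local signal level.
Bounds: amplitudes ≥ 0, widths in [2, 120] cm⁻¹, centers within ±15 cm⁻¹ of
their start. Each window also carries a free linear baseline term (bounded
±0.2) absorbing residual baseline-correction error; this took the median
band-area recovery error on the default lab design from ~1–10% down to
< 0.5% per signature. A fit whose solver ends worse than its start is
rejected (the initial guess is kept and flagged not-converged), so the
reported residual never exceeds the initial one. Band areas are matched to
assignments by nearest fitted center within 15 cm⁻¹; concentrations are
area × Beer coefficient with default coefficients of 1 (relative scale —
the package quantifies normalized absorbance, not molar units). The C/L
ratio requires lignin ≥ 1e-6, the Pi/Po ratio requires Po ≥ 1e-6.

## Regression

PCR via thin SVD of the centered training matrix; scores are orthogonal, so
per-component coefficients decouple, and the cross-validation evaluates all
candidate component counts from one decomposition per fold (cumulative-sum
trick). Component count: first minimum of the 10-fold pooled MSEP, counts
capped at each fold's trainable rank with a logged warning; the default cap
is 41 components for the P model (44 for an N model), letting CV choose
fewer. Targets default to log₁₀ concentration because the design spans 2.7
decades (1–500 µM); MSEP is evaluated on that transformed scale.

Bootstrap training resamples plants (not spectra) with replacement, 6000
draws by default, then selects components by 10-fold CV over the bootstrap
rows and refits at the selected count. Because resampled duplicates of one
plant can land in both training and test folds, this MSEP is an in-design
selection criterion — the quantity the protocol thresholds at 0.01 — not an
across-plant generalization estimate. The non-bootstrap path
(`select_components(groups=...)`) keeps plants whole within folds and gives
the honest generalization curve; held-out-plant R² on the default design is
≈ 0.97.

Prediction refuses a grid mismatch rather than silently interpolating;
`resample_to_grid` is an explicit, separate step. Models serialize to a
versioned JSON container (grid, mean spectrum, loadings, coefficients).

## Seasonal statistics

Two-sample comparisons default to the Welch variant because the generator's
sites have unequal variances by design; the classical pooled-variance
Student test is a switch for protocol fidelity. Consecutive-timepoint
families (T1–T2 … T4–T5) are Holm-adjusted; the consecutive-pair convention
and the adjustment are documented choices, since figure-style pairwise
annotations rarely state either. The biomass association uses Spearman rank
correlation — monotonicity, not linearity, is the claim being tested. Under
a fully null generator (no seasonal effect, no shared plant effects) the
familywise rejection rate of the Holm family is ≈ 0.04 over 200 seeds and
raw p-values pass a Kolmogorov–Smirnov uniformity check; with shared
plant-level effects the two-sample tests are conservative (longitudinal
correlation), which mirrors their use on real repeated-measures field data.

## Numerical choices and degenerate inputs

* Wide-CSV floats are written at %.17g and read with round-trip float
  parsing, so both text formats are lossless.
* SVD uses LAPACK gesdd with a gesvd fallback (bootstrap matrices with many
  duplicated rows occasionally stall gesdd).
* Rank checks use the s₁·max(n,p)·ε tolerance; requesting components beyond
  the centered rank raises rather than returning noise directions.
* Zero spectra fit to zero amplitudes with zero residual and skip the
  solver entirely; identical constant samples in a pooled t-test return
  t = 0, p = 1 instead of 0/0.
* Fold assignment is a seeded uniform shuffle; with group labels, whole
  groups are assigned to folds.
* Per-stage seeds derive from the top-level seed by SHA-256 of
  `"{seed}:{stage}"` (mod 2³¹), so stages are independently reproducible
  and a rerun is byte-identical.

## Problem sizes

Defaults reproduce the study scale end to end: 78 plants × 3 technical
spectra, 6000 bootstrap rows × 500 grid points, 300 field plant-timepoints.
Statistical calibration suites run on generator truth tables (200 null
seeds, 100 association seeds, 50 power seeds); the prediction-bias check
pools 20 train/evaluate replicates at 1500 bootstrap rows each.

## Known limitations

* The linear model carries a small systematic positive bias
  (≈ +0.1 decade) at the 150 µM level, where the cellulose response has
  saturated and the design is dominated by optimal-P plants; it is an
  intrinsic least-squares compromise on a nonlinear dose–response manifold,
  not a bug in the fit.
* Beer coefficients are relative; absolute molar calibration hooks exist
  but ship uncalibrated.
* The bootstrap-CV MSEP is optimistic as a generalization estimate (see
  above); use grouped CV for honest error bars.
* No atmospheric compensation or scatter correction (MSC/SNV); spectra are
  assumed free of those artifacts, as the generator produces them.
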