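# Methods

## Data model and conventions

An EEM is stored `[emission × excitation]` (emission along rows), matching
the usual contour orientation; a stack of EEMs with identical grids forms
the three-way array (excitation × emission × scan) used by PARAFAC. The
instrument grids are 250–450 nm excitation in 5 nm steps (41 points) and
250–600 nm emission in 1 nm steps (351 points). Missing cells are NaN.
Unfolding to the PLS matrix is excitation-major (all emission wavelengths
for the lowest excitation first); the order is recorded in a `VariableMap`
so coefficient and VIP vectors can be folded back into contour maps. The
CSV dialect is strict: UTF-8, comma-separated, `.` decimal, empty cell =
missing; one matrix per file with wavelength headers.

Replicate handling: PARAFAC uses every scan (replicates carry independent
noise and inherit their sample's reference value); for PLS the default is
to average the three analytical replicates per sample before calibration,
configurable to use-all-replicates (`replicate_policy="all"`). Averaging is
the safer default because it prevents replicate leakage across
cross-validation folds.

Missing-data policy for unfolding: columns missing in any scan are dropped
(scatter excision removes the same cells in every scan, so this loses
nothing); mean imputation is available for irregular missingness.

## Scatter removal

Three ridges are handled: first-order Rayleigh (em ≈ ex, half-width
15 nm), second-order Rayleigh (em ≈ 2·ex, 15 nm) and water Raman
(em = 1/(1/ex − Δν·10⁻⁷), Δν = 3400 cm⁻¹, half-width 10 nm). The widths
are conventional EEM-preprocessing values and are configurable; the
instrument-side multi-order-light filter they replace is proprietary, so
both Rayleigh orders are always treated in software. Excise mode (cells →
NaN) feeds PARAFAC, whose masked ALS handles missingness; interpolate mode
(linear along the emission axis between the nearest unmasked neighbours,
constant extension at column ends) feeds PLS, which needs a dense matrix.

## PARAFAC

The trilinear model is fitted by alternating least squares with columnwise
HALS updates, which are monotone in the observed-cell SSE, under
nonnegativity on all three modes by default (spectra and concentrations are
physically nonnegative). Missing cells are imputed from the current model
each iteration (EM style); when the missing pattern is the same in every
scan — the scatter-excision case — imputation and the SSE touch only the
missing fibers and the SSE is computed from Gram matrices, so no full
reconstruction is formed. Because the free-retinol and protein-bound
retinol components have nearly proportional score vectors, plain ALS crawls
through a swamp; each iteration therefore tries a line-search extrapolation
along the last update direction (step = iteration^(1/3), clipped to the
nonnegative orthant) and accepts it only if the SSE decreases, preserving
monotonicity.

Defaults: 10 random nonnegative starts from a seeded generator (best final
SSE wins, ties to fewer iterations), `max_iter` 2500, relative SSE
tolerance 1e-8. Study-scale runs in this repository's tests and examples
use 1–2 starts and 150–800 iterations, which the diagnostics show is
sufficient for those problems. After fitting, spectral loading columns are
normalized to unit Euclidean norm with all magnitude in the scores, and
components are ordered by explained variance.

Component-number selection fits each candidate F and keeps the largest one
whose CORCONDIA — `100·(1 − Σ(g − t)²/F)` with `g` the least-squares Tucker
core given the loadings and `t` the superdiagonal identity — is at least 60
and whose model is non-degenerate (no two components with Tucker congruence
above 0.95 in both spectral modes). If no candidate qualifies the smallest
F is returned with a warning. The threshold of 60 is common practice, and
on the matching four-fluorophore synthetic stack this rule selects exactly
four components — the count cattle-serum EEMs are expected to resolve.
Note that CORCONDIA guards against overfactoring only: on pure-noise
tensors it remains near 100 for F = 1–2, so the selector will not flag
structureless data by itself.

Peak localization is the argmax of each loading (ties to the lowest
wavelength). Score–reference correlation is a Pearson r with a two-sided
t-test (n − 2 df).

## PLS1 calibration

NIPALS PLS1 with X-deflation; for one response the weight extraction is
closed-form per latent variable. y is centred and scaled internally; X is
unit-variance scaled (sample SD, n − 1) with zero-variance columns dropped
and validation rows scaled by the calibration parameters. The regression
vector is `b = W(PᵀW)⁻¹q`; score vectors are mutually orthogonal and the
coefficient form reproduces the deflation recursion to numerical precision
(both property-tested). Rank exhaustion truncates the model with a flag.

Latent-variable selection: 7-fold cross-validation (folds seeded,
stratified by y quantile), `Q²_A = 1 − PRESS_A/SS_tot`, choosing the
maximizer with ties to the smaller count; maximum 10 latent variables.

Metrics follow the conventions of SIMCA-style spectroscopic calibration:
R² is the squared Pearson correlation of observed vs predicted (the
1 − SSE/SST variant is also reported as `r2_alt`);
`RMSEE = sqrt(SSE_cal/(n_cal − 1 − A))`; `RMSEP = sqrt(mean squared
validation error)`; `RPD = SD(y_val; n−1)/RMSEP`, banded as < 1.5
preliminary, 2.0–2.5 satisfactory, > 2.5 good, with the 1.5–2.0 gap that
convention leaves labelled "intermediate".

VIP: `VIP_j = sqrt(p · Σ_a w_ja²·SSY_a / Σ_a SSY_a)` with
`SSY_a = q_a²·t_aᵀt_a`; `mean(VIP²) = 1` holds exactly. VIP map peaks are
local maxima above 1, merged within a 15 nm (ex) × 30 nm (em)
neighbourhood and sorted by VIP descending.

Permutation test: each of `n_perm` (default 100, minimum 20) seeded
permutations of y is refit at the selected A; |corr(y_perm, y)|, training
R² and k-fold Q² are recorded together with the unpermuted anchor at
correlation 1, and R² (and Q²) are regressed on the correlation to report
intercepts at correlation 0. Intercepts below ~0.4 (R²) and ~0.05 (Q²) are
the usual validity reading. Some chemometrics software prints these
intercepts as coordinate pairs; this package reports scalar intercepts.

## Synthetic serum generator

The generator emulates the study conditions: 208 samples × 3 replicates on
the instrument grids, concentrations from a truncated normal (mean 46.7,
SD 25.8, range 11–124 IU/dl, rejection-sampled), five Gaussian-band
fluorophores at the reported band positions. Band widths default to 18 nm
(excitation SD) and 28 nm (emission SD): broad enough that the three
protein bands overlap realistically, narrow enough to stay
PARAFAC-resolvable. Protein amounts are lognormal (SD 0.25 on the log
scale) and independent of retinol, so a calibration cannot shortcut through
protein signal. The free-retinol amount equals the concentration; the
RBP-bound amount is `0.6·concentration + N(0, 2)` floored at zero — the 0.6
linkage and the brightness ratio (bound pool 2× brighter per unit) are
modelling choices, not reported values. Replicates differ by a
multiplicative scalar `1 + 0.01·N(0,1)`; additive noise has
SD = 0.02 × median(noiseless stack); optional Rayleigh ridges (Gaussian
cross-sections, 6 nm SD, amplitudes 0.5/0.25 of the maximum signal) are on
by default. Everything is reproducible from one seed.

What the generator does **not** emulate: inner-filter effects,
photobleaching, baseline drift, wavelength-dependent detector response,
additional serum fluorophores (NADH, FAD, bilirubin), or any covariate
structure (age, sex). Passing tests on these data demonstrate the
correctness of the algorithms and the internal consistency of the
workflow — not instrument-level performance. In particular the synthetic
noise floor is far below that of a plate reader, so calibration metrics on
synthetic data (R² ≈ 0.997, RPD ≈ 18) sit well above what this kind of
assay achieves on real instrument data (R² around 0.95, RPD around 4).

### A known consequence of the low noise floor

Because the additive noise (≈0.01 intensity units) is orders of magnitude
below the retinol signal span (≈26 units·band amplitude), after
unit-variance scaling *every* variable in the retinol band's footprint
correlates almost perfectly with concentration. The VIP surface is
therefore flat to ~1e-3 across a ±60 nm footprint and the location of its
maximum is sampling jitter, not band structure: VIP-peak positions on
synthetic data are not expected to localize the band center to within a
grid step or two, even though the coefficient and VIP maps are correct.
Peak localization of the PARAFAC loadings is unaffected (they are spectral
profiles, not correlation summaries) and recovers the generating centers
to ±5 nm (ex) / ±3 nm (em).

## Numerical choices

* Wavelength-grid construction requires exact divisibility of the range by
  the step (tolerance 1e-9 relative) and keeps both endpoints.
* ALS convergence: relative SSE change < `rel_tol`; non-convergence is a
  reported flag, not an error. Degenerate all-zero columns during HALS are
  reset to a minimal positive entry.
* CORCONDIA uses pseudoinverses of the loading matrices; missing cells are
  imputed from the model before the core is computed.
* Zero-variance y, all-missing tensors, all-zero tensors, and F exceeding a
  tensor mode are hard errors; rank exhaustion in PLS truncates with a flag.
* Flat loadings tie-break peak positions to the lowest wavelength.
* RMSEP = 0 reports an infinite RPD rather than an error.

## Problem sizes used in tests and examples

Unit tests run on coarse grids (10/5 nm steps) and 8–60 samples; the
end-to-end checks run the full 41 × 351 × 624 stack with 1–2 ALS starts
and capped iterations, and the calibration branch at the study's 145/63
split. These sizes are the package's own choices for routine verification;
all of them are configurable upward.
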