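# Methods

This note documents the models, algorithms, numerical choices and known
limitations behind ppikit. Notation: `T` timepoints at sampling interval
`tr` (seconds), `ψ` the 0/1 task boxcar, `H` the lower-triangular
Toeplitz operator of the canonical HRF, `W` the AR(1) whitening matrix.

## Signal model and extraction

A seed region arrives as a T×V matrix of voxel time courses. Extraction
follows the SPM convention: build the discrete-cosine high-pass basis
(cutoff 128 s by default; the retained column count is
`floor(2·T·tr/cutoff + 1) − 1`, constant excluded), estimate an AR(1)
model from the OLS nuisance residuals, whiten data and nuisance columns,
residualize, and summarize the ROI by its first eigenvariate
`u₁·sqrt(s₁/V)` with the sign fixed so that the sum of voxel weights is
positive. The eigenvariate scaling and sign rule are adopted from SPM's
extraction routine. The nuisance set deliberately contains no intercept
(means are handled by the GLM's explicit intercept later), and the AR
coefficient is estimated on internally demeaned residuals so a nonzero
signal mean cannot masquerade as autocorrelation.

With `whitening_inversion` enabled, the *same* `W` used during extraction
is inverted on the eigenvariate (a banded forward substitution), so the
returned series carries the original temporal structure. Because the
confound projection happened in whitened space, the inverted series
equals the data minus a generalized-least-squares (not orthogonal)
projection onto the nuisance space; for a rank-one ROI this makes the
seed regressor plus the design's filter columns span the seed BOLD
exactly.

## Whitening

For lag-1 coefficient ρ, `W[0,0] = sqrt(1 − ρ²)`, `W[t,t] = 1`,
`W[t,t−1] = −ρ`. The stationary first-row scaling preserves the series
length and gives `W Σ(ρ) Wᵀ = σ² I` exactly. ρ estimates use the
Yule–Walker lag-1 ratio `Σ eₜeₜ₋₁ / Σ eₜ²`, clipped to ±0.99 with a
logged warning (clipping preserves invertibility of `W`).

## Deconvolution

The canonical HRF is `g(t; 6, 1) − g(t; 16, 1)/6` (gamma densities;
SPM's default delays, dispersions and 6:1 peak-to-undershoot ratio),
sampled on the scan grid over a 32-s support and normalized to unit sum.
Deconvolution solves the ridge problem
`z = (HᵀH + λI)⁻¹ Hᵀ y` with shrinkage λ = 0.002 on the unit-sum kernel
(the value that approximates the empirical-Bayes behaviour of the
standard software); `h(0) = 0` makes `H` singular, and the penalty is
what renders the inversion well posed.

**Constant-level handling.** The constant level of the neuronal signal is
not identifiable through a causal kernel observed on a finite window,
and subtracting a flat mean from `y` contradicts the zero initial
condition: the mismatch concentrates at the window onset and produces
large spikes in the estimate (measured: correlation with a noiseless
neuronal boxcar drops from 0.98 to 0.77). ppikit instead models the
level as a free, unpenalized multiple of the operator's own steady-state
ramp `u = H·1` and partials it out of `y` and of `H`'s columns
(Frisch–Waugh). This reduces to the familiar special cases — identity
kernel at λ = 0 returns `y − mean(y)`; an invertible kernel at λ = 0
returns `z_true − mean(z_true)` to machine precision — while leaving the
causal boundary intact. The `demean_input` flag carries this semantics.

## PPI design and fitting

The design columns are, in order: interaction, seed main effect
(demeaned), HRF-convolved task regressor (demeaned), confounds including
the high-pass basis, intercept. The interaction is
`H((ψ − c) ⊙ x_n)` with `c = mean(ψ)` when mean-centering is on and 0
otherwise. A numerically zero interaction column aborts with a
diagnostic error rather than returning a zero estimate; constant columns
hidden in the confounds are rejected (the intercept is added exactly
once).

Fitting prewhitens once, correctly: OLS residuals give an initial AR(1)
estimate, data and design are whitened, and the GLM is refit; standard
errors come from `(XwᵀXw)⁻¹` scaled by the whitened residual variance,
with `T − rank(Xw)` degrees of freedom and two-sided t p-values.

**AR refinement.** The initial Yule–Walker estimate from OLS residuals is
biased toward zero when the design contains smooth columns (they absorb
low-frequency noise): at T = 200, ρ = 0.4 the mean estimate is ≈ 0.35,
which under-whitens and inflates the type-I error of the interaction
test to ≈ 0.062 (the true-ρ reference is 0.048). Two deterministic
fixed-point refinements drive the lag-1 autocorrelation of the
*whitened* residuals to zero, composing successive AR filters via
`ρ ← (ρ + r)/(1 + ρ·r)`; the measured rate is then ≈ 0.05. The scheme
remains a closed-form moment method, not iterated ReML.

## Ground-truth simulator

The simulator emulates a block-design language paradigm: TR = 0.9 s,
200 scans, alternating 18-s task/baseline blocks starting with task.
Neuronal level:

```
z_seed   = g·ψ + η_s                       η_s ~ AR(1)(0.5), unit SD
z_target = α·z_seed + γ·ψ + β·(ψ_c ⊙ z_seed) + η_t
```

BOLD level: `b = H z + AR(1) noise` with coefficient `rho_noise` and
*marginal* SD `sigma_noise` (stationary initialization); the ROI is the
seed BOLD plus iid voxel noise in each of `n_roi_voxels` columns. Main
effects use the uncentered 0/1 boxcar — the brain responds to the actual
stimulus stream, so the convolved task component (onset ramp included)
lies exactly in the span of an analysis design column; convolving a
*centered* boxcar instead would inject an onset transient spanned by no
estimable regressor, which measurably inflates null t-statistics. The
interaction uses the centered boxcar `ψ_c`, so β is the modulation of
coupling around its task-average α, matching the mean-centered analysis
convention. The interaction is injected at the neuronal level and then
convolved — the premise of deconvolution-based PPI.

Default parameters (chosen once as representative of a moderate-SNR
block-design study): α = 0.5, β = 0.4, γ = 0.5, g = 1,
`target_latent_sd` = 1, `rho_noise` = 0.4, `sigma_noise` = 0.5,
10 ROI voxels with voxel noise SD 0.5. The latent noises are AR(1) with
coefficient 0.5 at the neuronal level so that deconvolution has
recoverable structure; the degenerate `g`-only case reproduces a pure
boxcar seed. Cohorts draw per-subject β from
N(β, `between_subject_sd`²) on a stream separated from the data seeds;
subject i's data seed is `master_seed + i`.

What the simulator does **not** emulate: spatial structure and smoothing,
motion and physiological confounds beyond an optional sinusoidal drift,
multi-echo acquisition, non-AR(1) (e.g. long-memory) measurement noise,
and behavioral covariates beyond a scalar linearly tied to β. Passing
tests therefore demonstrate correctness of the estimator mechanics and
the misspecification phenomenology, not robustness to every property of
real data.

## Calibration experiments

*Type-I error.* The null world is chosen to satisfy the fitted model's
error assumption: β = 0, α = 0, `target_latent_sd` = 0, so the target's
stochastic part is purely AR(1) (ρ = 0.4) measurement noise. Over 1,000
subject-level replicates the Pipeline-4 interaction rejection rate at
α = 0.05 is ≈ 0.05–0.06 and the p-values are uniform.

*A known limitation, on purpose.* With physiological coupling present
(α ≠ 0), the seed's measurement noise enters the target (scaled by α)
and the interaction regressor (through deconvolution) simultaneously —
an errors-in-variables effect that inflates the subject-level rate to
≈ 0.10 under the default noise levels and that no pipeline switch can
remove. This is a property of regression on estimated regressors, not of
the corrections studied here; group-level inference over per-subject
estimates (the package's seed diagnostic) is far less sensitive to it.

*Seed-location red flag.* Over 200 null cohorts (n = 30, ρ_noise = 0.5,
noisy deconvolution), the group-level flag rate at the seed is ≈ 1.0 for
Pipeline 1, ≈ 0.18 for Pipeline 3 and ≈ 0.05 for Pipeline 4 — the
corrected model's rate sits at its nominal α.

*Power.* `min_sample_size_one_sample_t` evaluates exact noncentral-t
power (noncentrality `d·√n`, dof `n − 1`) and returns the smallest n
reaching the target by exponential-then-bisection search bounded at
n = 10⁶; d = 0.4 at two-sided α = 0.05 and 80% power gives n = 52.

## Numerical choices and degenerate inputs

- Projections use least squares (`lstsq`), so rank-deficient nuisance
  bases are handled by pseudoinverse without error; rank deficiency of
  the *analysis* design is an error that names the collinear columns.
- A matrix is treated as all-zero (degenerate) when its largest absolute
  entry is below 1e−12.
- Kernels longer than the series are truncated with a logged warning.
- The eigenvariate sign convention (positive voxel-weight sum) is a
  tie-break only; no result in this package depends on it.
- Monte-Carlo loops derive replicate seeds as `master + r·100003` so the
  per-subject child seeds of different replicates never collide.

## Scope

Two-condition designs only (generalized ≥3-level PPI is out of scope);
per-series inference only (no volumetric maps, no family-wise-error
cluster correction); AR(1) noise model only (no FAST/AR(p) or ReML
covariance components). Data exchange is TSV/JSON; no NIfTI ingestion.
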