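# Methods

## Model

The package implements a feed-forward chain of indirect-response (turnover)
models for four inflammatory read-outs of LPS-stimulated RAW264.7
macrophages.  TNF-α is produced at a zero-order rate k_in,TNFα (conc·h⁻¹)
from the moment of LPS addition (t = 0) and eliminated first-order
(k_out,TNFα, h⁻¹).  Baicalein, pre-incubated before LPS, reduces TNF-α
production by the fraction f(C) = α·ln C; because the effect model contains
no drug kinetics, the 0.5 h pre-incubation is represented as a constant
inhibition from t = 0, and published sampling times quoted on the
post-baicalein clock (1.5 … 24.5 h) map to 1, 2, 4, 8, 12, 24 h post-LPS.
IL-6 and iNOS production are driven by TNF-α delayed by lag times τ₁ and τ₂;
NO production is proportional to iNOS^δ.  The pre-stimulus history is
TNFα(t) ≡ TNFα₀ for t ≤ 0.

Conventions where the model leaves choices open:

* **Logarithm base** — natural log.  One e-fold of concentration then
  changes the inhibition fraction by exactly α (≈ 8.32% at the reference
  coefficient), matching the standard log-linear effect reading.
* **f at low C** — f(C) = 0 for C ≤ 1 μM.  ln C is undefined at 0 and
  negative below 1 μM, which would predict stimulation; the clamp only
  affects concentrations below the studied 10–40 μM range.  f ≥ 1 (total
  shutdown) raises an error.
* **Baselines** — TNFα₀ and IL-6₀ are the time-0 control values; iNOS₀ = 1
  identically (the immunoblot ratio is self-normalized); NO₀ is a nominal
  1 μM.  Baselines are data, not free parameters, and are fixed during
  fitting.
* **Units** — TNF-α/IL-6 in pg/mL-equivalents, NO in μM-equivalents, iNOS
  dimensionless.  k_in,TNFα multiplies nothing, so it is carried as
  concentration·h⁻¹ even though conventionally printed as h⁻¹.
* **Observed-data caveat** — measured TNF-α time courses in this system peak
  near 1 h and decline, whereas the zero-order-production turnover equation
  is monotone over the fitted window at the reference constants.  The model
  is implemented exactly as specified; the discrepancy is a property of the
  model class, not of this implementation.

## Solution strategy

TNF-α is autonomous and linear, so it has an exact closed form, which also
makes the delayed inputs TNFα(t − τ) exact — no interpolation error enters
the delay terms.  The general solver (`simulate_cascade`) integrates the
remaining three states with LSODA at rtol = atol = 10⁻⁸ (configurable).
For the conventional fitted configuration k_out,iNOS = k_out,NO = 0 a
semi-analytic path (`predict_states`) is used instead: IL-6 has a piecewise
closed form (constant-history segment, then exponential forcing; the
resonant case k_out,IL6 → k_out,TNFα is handled by its analytic limit),
iNOS is a closed-form integral of delayed TNF-α, and NO needs one smooth
quadrature of iNOS^δ, done with 48-point Gauss–Legendre (exact linear-power
segment before τ₂).  The two routes agree to ≤ 10⁻⁶ relative error
(unit-tested); the fast path makes a full likelihood evaluation ≈ 0.5 ms,
which is what keeps the recovery studies desk-scale.

A trajectory state below −10⁻⁹ aborts the run; tiny negative round-off is
clipped to 0 with a logged warning.

## Residual-error models and likelihood

Residuals are Gaussian on the observation scale: additive
(y = f + σ_add·ε), proportional (y = f(1 + σ_prop·ε)) and power
(y = f + σ_add·f^ζ·ε); generated observations are truncated at 0.
"Multiplicative" weighting is read as proportional, the standard convention
behind population-software weighting options.  No between-replicate random
effects are simulated by default: the original population analysis used a
nonlinear mixed-effects estimator (FOCE-ELS) whose random-effects structure
is unreported, so this package deliberately replaces it with **naive-pooled
maximum likelihood** — all records enter one population-level Gaussian
likelihood with a per-analyte residual σ (4 error parameters).  Pooled ML is
the implementable, fully testable analogue when only population estimates
are available; consequences: estimates are population-level only, no
PRED/IPRE distinction exists, and the original study's −2LL/AIC/BIC are not
reproducible without its raw data (its printed BIC is also inconsistent
with the standard penalty p·ln n; the standard formula is implemented).

During optimization the per-analyte σ² are profiled at their closed-form
MLE, σ̂²_a = mean[(obs − pred)²/pred^(2ζ)], so the optimizer works on the 10
structural parameters only.  The profiled variance is floored at 10⁻¹² of
the weighted observation scale (residual CV 10⁻⁶) so an exact fit of
noise-free data has a finite, flat optimum instead of a −∞ cliff; the floor
is orders of magnitude below any realistic assay noise.  AIC = −2LL + 2p
and BIC = −2LL + p·ln n with p = free structural + error parameters.

## Optimization

Rates, baselines and δ are optimized on the log scale; α, τ₁, τ₂ on the
natural scale.  Default bounds: α ∈ [0, min(0.26, 0.995/ln C_max)] (keeps
f < 1 at the largest arm), τ ∈ [0, 6] h, δ ∈ [0.05, 5], rates within ×10³
of their initial values.  Because the cascade is feed-forward, a **staged
warm start** first fits each analyte's own parameters on its own records in
cascade order (TNF-α → IL-6 → iNOS → NO); the lag likelihoods are multimodal
with only five sampling times, so each stage additionally starts its free
lag from a deterministic coarse grid (0.25–5 h).  The joint likelihood is
then polished by bounded L-BFGS-B multi-start (default 8 starts: the staged
point, the raw init, and log-uniform ×[0.5, 2] jitters, seeded).  A fit
fails if no start converges and warns if fewer than two starts reproduce
the best −2LL within 10⁻².

Uncertainty: CV% = 100·SE/estimate from the inverse numerical observed
information of the profiled −2LL (profiling slightly understates the SEs of
weakly identified parameters), or from a within-cell nonparametric
bootstrap (B = 200 default).  The two agree within a factor of 2 on
well-specified synthetic data (tested).

## Synthetic-data conditions

The generator reproduces the statistical skeleton of the original
experiment: 4 LPS-stimulated arms (0/10/20/40 μM baicalein), observation
times {1, 2, 4, 8, 12} h post-LPS (the 24 h point, where treated and
untreated trajectories have converged, is excluded from fitting by default
and re-added with a flag), n = 3 replicates for TNF-α/IL-6/NO and n = 6 for
iNOS — 300 records per dataset.  Recovery and acceptance runs use
proportional error with σ = 0.10, a typical mid-range CV for ELISA/Griess
read-outs and consistent with the original fit's reported parameter
precision (max CV 37%).  What the generator does **not** emulate: plate and
batch effects, ELISA calibration nonlinearity, immunoblot saturation,
between-experiment random effects, and the early TNF-α peak seen in real
data but outside this model class.  Passing recovery tests therefore shows
the estimator is consistent and well-calibrated *under the model*, not that
the model captures every feature of real RAW264.7 data.

The recovery study simulates 20 datasets (seeds 101–120 in the canonical
stream), fits each with baselines and k_out,iNOS/k_out,NO fixed, starting
from the generating truth with 4 multi-starts, and summarizes per-parameter
medians, relative bias, RMSE and Wald 95% coverage.  Medians are computed
over converged fits only (non-convergence is counted and reported; more
than 50% failures aborts).  With the default conditions all 20 fits
converge and every median lands within a few percent of truth — well inside
the ±20% (rates/coefficients/exponent) and ±0.3 h (lags) recovery bands.

Problem sizes used by the default test and acceptance runs — 20 recovery
datasets, 1000 random parameter sets for the closed-form solver oracle, 200
for the quadrature oracle, 150 VPC simulations, B = 40 bootstrap draws in
the cross-method sanity test — were chosen to give stable Monte-Carlo
estimates at desk scale.

## Diagnostics

The GOF table reports per-record predictions, residuals and residuals
standardized by the fitted error model, plus per-analyte
observed-vs-predicted slopes through the origin and mean standardized
residuals.  The VPC simulates replicate datasets from a parameter set and
error model, reduces each design cell to its replicate median, and reports
the 5/50/95% envelope of those medians across simulations; observed cell
medians from a matching dataset fall inside the 90% band at the nominal
rate within binomial tolerance (tested).  Plots (matplotlib) are optional
renderings of the tables; all acceptance-relevant output is tabular.

## Known limitations

* Pooled ML ignores replicate correlation; SEs are approximate when true
  between-replicate variability exists.
* k_out,TNFα is weakly identified over a 12 h window (kt ≈ 0.55), mirroring
  its large published CV; recovery medians remain unbiased but single-fit
  estimates scatter.
* The delay enters as a hard lag; distributed-delay (transit-compartment)
  alternatives are out of scope.
* δ and k_in,NO are correlated through iNOS^δ; joint identification relies
  on the dose contrast across arms.
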