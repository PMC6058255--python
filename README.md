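# pdcascade

Turnover-cascade pharmacodynamic modeling of inflammatory mediator release in
LPS-stimulated RAW264.7 macrophages, and its inhibition by the flavonoid
baicalein.

## The model

Lipopolysaccharide (LPS) triggers rapid, zero-order production of TNF-α in
macrophages; TNF-α then drives — after lag times — the production of IL-6 and
of the enzyme iNOS, whose expression level in turn produces nitric oxide
(NO).  Baicalein reduces TNF-α production by a fraction that grows with the
logarithm of its concentration.  The cascade is a chain of indirect-response
(turnover) equations:

```text
dTNFα/dt = k_in,TNFα · (1 − α·ln C_Bai) − k_out,TNFα · TNFα
dIL6/dt  = k_in,IL6  · TNFα(t − τ₁)     − k_out,IL6  · IL6
diNOS/dt = k_in,iNOS · TNFα(t − τ₂)     − k_out,iNOS · iNOS
dNO/dt   = k_in,NO   · iNOS^δ           − k_out,NO   · NO
```

with TNFα(t) ≡ TNFα₀ for t ≤ 0 and baselines equal to the unstimulated
control values.  iNOS is measured as the immunoblot ratio
(iNOS/GAPDH)/(iNOS₀/GAPDH₀), so iNOS₀ = 1 by construction; k_out,iNOS and
k_out,NO are conventionally fixed to 0 (expression and nitrite accumulate
over the observation window).  The reference coefficient α = 0.0832 means
each e-fold rise in baicalein concentration removes about 8.32% of TNF-α
production.

The package provides:

* **`model`** — closed-form TNF-α solution, general ODE integration of the
  cascade (`simulate_cascade`), a fast semi-analytic prediction path, and the
  immunoblot normalization helper.
* **`datagen`** — the study design (4 arms at 0/10/20/40 μM baicalein ×
  times 1, 2, 4, 8, 12 h post-LPS; n = 3 per analyte, n = 6 for iNOS) and
  synthetic dataset generation under additive, proportional or power
  residual-error models.
* **`estimate`** — pooled (naive-pooled) maximum-likelihood fitting with
  per-analyte profiled error variances, a cascade-ordered staged warm start,
  multi-start bounded optimization, Hessian/bootstrap CV%, AIC/BIC, and
  simulation–refit recovery studies.  Exposed as the scikit-learn style
  `CascadeRegressor`.
* **`diagnostics`** — observed-vs-predicted goodness-of-fit tables,
  predictive-check (VPC) envelopes, dense time-course tables, optional plots.
* **`cli`** — `pdcascade simulate | fit | recover | gof | vpc`.

## Worked example

Simulate one experiment at the reference parameter values with 10%
proportional noise, then refit it:

```python
import pdcascade as pc

params = pc.baicalein_reference_params()
design = pc.default_design()
noise = pc.ErrorModel(kind="proportional", sigma_prop=0.10)
data = pc.generate_dataset(params, design, noise, seed=101)

est = pc.CascadeRegressor(n_starts=4, seed=0).fit(data)
print(f"-2LL = {est.minus2ll_:.2f}, AIC = {est.aic_:.2f}, BIC = {est.bic_:.2f}")
print(f"alpha = {est.params_.alpha:.4f}  (truth 0.0832)")
print(f"tau1  = {est.params_.tau1:.2f} h (truth 1.38)")
print(f"tau2  = {est.params_.tau2:.2f} h (truth 1.41)")
cv = pc.parameter_cv(est.result_, data)
print(f"CV% alpha = {cv['alpha']:.1f}")
```

prints

```text
-2LL = 2424.10, AIC = 2452.10, BIC = 2503.95
alpha = 0.0885  (truth 0.0832)
tau1  = 1.43 h (truth 1.38)
tau2  = 1.38 h (truth 1.41)
CV% alpha = 3.7
```

The fitted inhibition coefficient (0.0885) and both lag times land within a
few percent of the generating truth from a single 300-record experiment, and
the precision of α (CV 3.7%) reflects the strong dose contrast across the
four arms.  The same pipeline runs from the shell:

```sh
pdcascade simulate --config cfg.json --seed 101 -o run/
pdcascade fit --data run/dataset.csv --config cfg.json -o run/
pdcascade recover --config cfg.json --n-sim 20 --seed 100 -o run/
```

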