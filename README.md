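# zicopula

**Zero-inflated log-normal Gaussian-copula modelling and simulation of
microbial community profiles.**

Microbiome sequencing yields compositional count tables with three awkward
properties: most entries are zero (and many of those zeros are biological
absences, not just shallow sequencing), the non-zero abundances span orders
of magnitude, and features covary. `zicopula` is a generative model and
simulator that captures all three, aimed at anyone who needs realistic
synthetic communities with *known* ground truth — for benchmarking
differential-abundance methods, estimating statistical power for a planned
study, or stress-testing correlation-inference tools.

## The model

For a community of `p` features, each sample is generated as:

1. **Latent scores.** `g ~ MVN(0, Ω⁻¹)` with unit-diagonal correlation
   `R = Ω⁻¹`; the precision matrix `Ω` is sparse (conditional-independence
   structure between features).
2. **Absolute abundances.** Each score maps through its feature's
   zero-inflated log-normal marginal: `A_j = 0` if `g_j < Φ⁻¹(π_j)`,
   otherwise `A_j = F_j⁻¹(Φ(g_j))`, so marginally `P(A_j = 0) = π_j` and
   `log A_j | A_j > 0 ~ N(μ_j, σ_j²)`.
3. **Relative abundances.** `X_j = A_j / Σ_k A_k` (compositional by
   construction).
4. **Counts.** Depth `D ~ LogNormal(μ_D, σ_D²)`, then
   `C ~ Multinomial(D, X)` — adding technical zeros on top of the
   biological ones.

Fitting inverts this: the likelihood of an observed relative-abundance
vector integrates the copula density over the latent total `A^Σ`, and a
penalized EM algorithm (graphical-lasso M-step, `λ‖Ω‖₁` with λ chosen by
K-fold cross-validation) estimates `(π, μ, σ, Ω)` under the
identifiability constraint `Σ_j μ_j = 0`.

On top of the fitted model the package provides:

- **Simulation** of all layers (latent, absolute, relative, counts), plus
  KDE-based generation of *new* features that match a community's
  prevalence/abundance/variability profile;
- **Association spike-in** on the absolute-abundance scale: log
  fold-change effects on `μ`, log odds-ratio effects on presence, hidden
  covariates for feature–feature correlation — so "true positive" features
  are unambiguous;
- **Evaluation statistics**: Bray–Curtis dissimilarity, PERMANOVA R²,
  two-sample Kolmogorov–Smirnov, effect-recovery regressions, and a
  power/FDR benchmarking grid with a built-in association test.

## Worked example

```python
import numpy as np
from zicopula import (CommunityProfileModel, FixtureSpec, FitConfig,
                      make_template_table)

# ground-truth community and a counts table simulated from it
truth, table, _ = make_template_table(
    FixtureSpec(p=8, n=400, regime="dense_small", seed=11))

res = CommunityProfileModel(table, FitConfig(max_iter=20)).fit(lambda_=0.05)
print(res.summary())
print("pi MAE:", np.abs(res.community.pi - truth.pi).mean().round(4))
```

prints (abridged):

```
Zero-inflated log-normal copula community model
================================================
features: 8    samples: 400
lambda: 0.05    EM iterations: 7    converged: True
sum(mu): -1.11e-16 (identifiability constraint)
depth: logN(mu_D=9.884, sigma_D=0.302)
non-zero precision off-diagonals: 40

                  pi      mu   sigma
feature_0000  0.1375  0.6315  0.9547
feature_0001  0.3100 -1.9896  0.9560
...
pi MAE: 0.0096
```

`sum(mu)` is pinned at zero by the identifiability constraint; the
per-feature absence probabilities come back within 0.01 of the generating
values, and the depth model is re-estimated from the counts' column
totals. Larger penalties prune more precision off-diagonals (at
`lambda_=None` the penalty is chosen by cross-validation). Simulate new
data with `res.simulate(n=1000, seed=1)`.

The same pipeline is available from the shell:

```bash
zicopula fixture --regime dense_small --p 6 --n 200 --outdir fx
zicopula fit --input fx/counts.tsv --lambda 0.1 --outdir fit
zicopula simulate --model fit/model.tsv --n 500 --seed 2 --outdir sim
zicopula evaluate --table-a fx/counts.tsv --table-b sim/counts.tsv --outdir ev
```

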