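# matchedcc

Matched case–control analysis of **lifetime exposures** — exposures (such as
hormonal contraceptives or menopausal hormone therapy) that largely precede
the baseline of the cohort in which the study is nested. The package provides
the full analysis chain for this design, plus the simulation machinery needed
to study its characteristic selection bias:

- **Synthetic nested-cohort generator** with a *depletion-of-susceptibles*
  mechanism: a per-woman normal frailty shared between a pre-baseline
  (cumulative) and a follow-up asthma stage, so that excluding women with
  prevalent disease at baseline preferentially removes high-risk women from
  one exposure group, increasingly with age.
- **Exact individual matching** (default: exact age in years, place of
  residence, smoking status) with up to 10 controls per case, without
  replacement.
- **Multiple imputation by chained equations** (fully conditional
  specification): Bayesian-draw logistic/multinomial models for categorical
  variables, predictive-mean matching for continuous ones, with convergence
  diagnostics.
- **Conditional logistic regression** — the likelihood for one case per
  stratum, `exp(x_c·β) / Σᵢ exp(xᵢ·β)` — fit by Newton–Raphson, pooled across
  imputations by Rubin's rules (`T = W + (1 + 1/m)·B`), with complete-case
  sensitivity analysis.
- **Bayesian conditional logistic regression** with elicited normal priors on
  the exposure log-OR, adaptive random-walk Metropolis MCMC, posterior mixing
  across imputed datasets, a prior-sensitivity grid, and P(OR > 1)
  statements.
- **E-values**: `E = RR + √(RR(RR−1))`, the minimum strength of unmeasured
  confounding (on the risk-ratio scale, both with exposure and outcome)
  needed to explain away an observed association.
- **Age-cutoff subgroup diagnostics**: nested refits above each baseline-age
  cutoff; a monotone upward drift of the estimated OR with the cutoff is the
  signature of depletion of susceptibles.

## Worked example

```python
import numpy as np
from matchedcc import (
    build_design, fit_clogit, evalue, sample_posterior,
    simulate_matched_design, FLAT_PRIOR,
)

# 500 matched pairs generated under the conditional model at true OR 1.5
pairs = simulate_matched_design(500, np.log(1.5), seed=42)
design = build_design(pairs)

fit = fit_clogit(design)
print(fit.summary().round(3))
#           logOR     se     OR  ci_low  ci_high
# exposure  0.544  0.133  1.722   1.328    2.233

ev = evalue(fit.or_, *fit.conf_int()[0])
print(round(ev.e_point, 3), round(ev.e_ci, 3))   # 2.837 1.989

post = sample_posterior(design, [FLAT_PRIOR], seed=3)
print(round(float(np.median(np.exp(post.exposure))), 3))  # 1.736
```

The frequentist fit recovers an OR of 1.72 (95% CI 1.33–2.23) for data drawn
at a true OR of 1.5; the E-value of 2.84 says a confounder would need
risk-ratio associations of ≥2.8 with both exposure and outcome to explain
the estimate away; and with a flat prior the Bayesian posterior median (1.74)
sits on the maximum-likelihood estimate, as it should.

The full pipeline (simulate → exclude prevalent cases → match → impose item
non-response → impute → frequentist + Bayesian fits → E-values → subgroup
trend) runs from a single config:

```bash
matchedcc run --config study.yaml --out results/
matchedcc evalue --or 2.13 --lo 1.03 --hi 4.38
```

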