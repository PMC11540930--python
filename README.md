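# rpslogit

Bayesian random-parameters spatial logistic models for the fatality risk of
freeway crashes.

## The problem

Emergency medical service (EMS) response time — the minutes between crash
notification and the arrival of EMS personnel — is a post-crash factor with a
direct clinical link to survival. Quantifying its effect on the probability
that a freeway crash is fatal requires a binary severity model that also
handles two features of crash data:

* **spatial correlation** — crashes on adjacent roadway sections share
  unobserved conditions (pavement, enforcement, local weather exposure);
* **unobserved heterogeneity** — a covariate such as truck involvement can
  affect different crashes differently.

`rpslogit` implements the three nested model families used for this kind of
analysis, a Metropolis-within-Gibbs sampler for their Bayesian estimation, a
synthetic-data generator that emulates a two-year crash record from a
154-section Chinese freeway (1,414 crashes, ~2.5% fatal), and the full
reporting stack: odds ratios, heterogeneity shares, average marginal effects,
and DIC model comparison. It is aimed at safety and injury-epidemiology
researchers who want these models outside of WinBUGS, with testable kernels
and reproducible simulation experiments.

## The models

For crash *i* with covariates *x*<sub>*ij*</sub> in freeway section *m*, a
latent utility decides the outcome (*Y*<sub>*i*</sub> = 1 for a fatal crash):

* **logistic**: *U*<sub>*i*</sub> = β₀ + Σ<sub>*j*</sub> β<sub>*j*</sub> *x*<sub>*ij*</sub> + ε<sub>*i*</sub>,
  with logistic ε, so P(*Y*<sub>*i*</sub> = 1) = expit(β₀ + Σ β<sub>*j*</sub> *x*<sub>*ij*</sub>);
* **spatial logistic**: adds a section effect φ<sub>*m*</sub> with a Leroux
  conditional-autoregressive (CAR) prior,
  φ<sub>*m*</sub> | φ<sub>−*m*</sub> ~ N(ρ Σ<sub>*n*</sub> ω<sub>*mn*</sub> φ<sub>*n*</sub> / (1 − ρ + ρ Σ ω<sub>*mn*</sub>), δ² / (1 − ρ + ρ Σ ω<sub>*mn*</sub>)),
  where ω<sub>*mn*</sub> = 1 when sections share a common end; ρ ∈ [0, 1]
  interpolates between independent effects and the intrinsic CAR;
* **random-parameters spatial logistic**: lets selected coefficients vary by
  crash, β<sub>*ij*</sub> = β̄<sub>*j*</sub> + μ<sub>*ij*</sub> with
  μ<sub>*ij*</sub> ~ N(0, σ<sub>*j*</sub>²).

Priors are diffuse: N(0, 10⁴) on coefficients, U(0, 1) on ρ, U(0.01, 10) on
δ and σ<sub>*j*</sub>. Effects are reported as odds ratios exp(β), percent
changes 100·(exp(β) − 1), the heterogeneity share 100·Φ(β̄/σ), and average
marginal effects on the fatality probability. Families are compared by
DIC = D̄ + *p*<sub>D</sub>, with a gap above 10 read as decisive.

## Worked example

```python
from rpslogit import odds_ratio, heterogeneity_share

orv, pct = odds_ratio(0.026)       # EMS response time coefficient, per minute
print(round(float(orv), 3), round(float(pct), 1))   # 1.026 2.6
print(round(heterogeneity_share(0.51, 1.23), 1))    # 66.1
```

One extra minute of EMS response time multiplies the fatality odds by 1.026
(a 2.6% increase), and with a heterogeneous Truck coefficient of mean 0.51
and SD 1.23, 66.1% of truck-involved crashes carry a fatality-increasing
effect. A full simulate → fit → compare run:

```bash
rpslogit simulate --n 1414 --sections 154 --seed 7 --out data/
rpslogit fit --data data/crashes.csv --adjacency data/adjacency.txt \
    --model rp-spatial --iters 100000 --burnin 50000 --seed 7 --out fit_rp/
rpslogit compare fit_rp/dic.json fit_spatial/dic.json fit_logistic/dic.json
```

`fit` writes posterior draws (`draws.csv`), a mean-(SD) summary table with
90/95% significance stars (`report.txt`), trace plots, convergence flags
under the MC-error rule (MC error < 5% of the posterior SD), and a manifest
with the seed and config hash. The `examples/` directory contains short
narrative scripts for each capability (`worked_effects.py`,
`simulate_dataset.py`, `spatial_prior.py`, `fit_and_compare.py`).

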