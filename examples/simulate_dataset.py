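"""Generate a synthetic crash-severity dataset with known truth.

The generator emulates the study conditions: published covariate marginals,
a 154-section freeway chain, Leroux-CAR section effects, a heterogeneous
Truck coefficient, and Bernoulli-logistic fatality outcomes.  The recorded
truth lets any later fit be checked against the parameters that actually
generated the data.
"""

import numpy as np

from rpslogit import GeneratorConfig, generate

d = generate(GeneratorConfig(N=1414, M=154, seed=7))
ds = d.dataset

print(f"crashes: {ds.N}, sections: {d.network.M} (chain, {d.network.n_edges} edges)")
print(f"fatalities: {int(ds.outcome.sum())} (rate {ds.outcome.mean():.4f})")
print(f"EMS response time: mean {ds.covariates['ems_response_time'].mean():.1f} min, "
      f"max {ds.covariates['ems_response_time'].max():.0f} min")
print(f"truck share: {ds.covariates['truck'].mean():.3f}")
print(f"section effects phi: sd {np.std(d.truth.phi):.3f} "
      f"(rho={d.truth.leroux.rho}, delta={d.truth.leroux.delta})")

# the same generator calibrated to the study's observed 2.5% fatality rate
d_cal = generate(GeneratorConfig(N=1414, M=154, seed=7, target_rate=0.025))
print(f"\ncalibrated intercept: {d_cal.truth.beta0:.2f} "
      f"(reference value -7.10) -> rate {d_cal.dataset.outcome.mean():.4f}")
print("The uncalibrated rate sits above 2.5% because independent covariates at "
      "the published effect sizes imply a higher base risk (see docs/methods.md).")
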