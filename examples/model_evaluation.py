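"""Evaluate a fitted model: GOF table, bootstrap CIs, and pc-VPC.

Self-generated data, so the diagnostics should look clean: CWRES
roughly standard normal, bootstrap CIs bracketing the generating
values, and observed pc-VPC percentiles inside the simulated bands.
"""

import numpy as np

from teicopk import (
    CohortConfig, ModelSpec, ResidualModel, bootstrap, final_model, fit,
    generate_cohort, gof, pc_vpc, simulate_observations,
)

cohort = generate_cohort(CohortConfig(n_subjects=25, sampling_design="rich", seed=31))
dataset = simulate_observations(cohort, final_model(), design="rich", seed=32)
start = ModelSpec(theta={"cl": 1.5, "v": 80.0}, omega2={"cl": 0.2, "v": 0.2},
                  residual=ResidualModel("additive", 0.5))
fitted = fit(dataset, start, compute_se=False)

table = gof(dataset, fitted)
print(f"CWRES mean {table.CWRES.mean():+.3f}, sd {table.CWRES.std():.3f} "
      f"(want ~0 and ~1); {100 * (abs(table.CWRES) <= 2).mean():.0f}% within +/-2")

boot = bootstrap(dataset, start, n_resamples=50, seed=33)
row = boot.table.loc["tv_cl"]
print(f"bootstrap tvCL: estimate {row.estimate:.3f}, "
      f"95% CI ({row.ci_lo:.3f}, {row.ci_hi:.3f}) "
      f"[generating value 0.98, converged {boot.n_converged}/50]")

vpc = pc_vpc(dataset, fitted.model, n_replicates=200, bins=4, seed=34)
inside = vpc.observed_inside_band(50)
print(f"pc-VPC: observed median inside the simulated band in "
      f"{int(inside.sum())}/{len(inside)} bins")
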