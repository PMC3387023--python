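"""Recover an observer's parameters by grid maximum likelihood.

Simulates 3,000 trials from the equal-precision optimal observer (EEO),
then maximizes the Monte-Carlo likelihood over a grid spanning the prior
ranges. The printed estimates should land on (or next to) the true values.
"""
import numpy as np

import vpchange as vp

spec = vp.parse_model_code("EEO")
truth = vp.representative_params(spec)

trials = vp.generate_trials(3000, np.random.default_rng(0))
trials = vp.simulate_responses(trials, spec, truth, seed=1)

grid = vp.make_grid(spec, points_per_dim=8)
fit = vp.fit_mle(trials, spec, grid, n_samples=1000, seed=2)

print(f"model: {spec.code}")
for name in truth:
    print(f"  {name:10s} true {truth[name]:7.3f}   estimated {fit.params[name]:7.3f}")
print(f"max log-likelihood: {fit.log_likelihood:.1f}")
print("Each estimate is the arg-max over the grid; with 3,000 trials the")
print("estimates match the generating values to within one grid step.")
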