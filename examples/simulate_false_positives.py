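"""False positives from cultural non-independence, and a model that avoids them.

Simulates nation pairs (y, x) with strong cultural-phylogenetic
autocorrelation (80% of the variance of each trait follows linguistic
proximity) and NO true relationship (r = 0), then compares how often a naive
regression versus a linguistic random-intercept model claims an effect.
"""

import numpy as np

from galton import WorldConfig, make_world, simulate_dataset, fit_method
from galton.simulate import _cholesky

world = make_world(WorldConfig(n_nations=100, seed=1))
Sigma = world.sigma("linguistic")
chol = _cholesky(Sigma)

reps = 50
hits = {"naive": 0, "phylo_ranef": 0}
for rep in range(reps):
    ds = simulate_dataset(Sigma, lambda_=0.8, rho=0.8, r=0.0,
                          seed=np.random.SeedSequence(0, spawn_key=(rep,)),
                          _chol=chol)
    for method in hits:
        hits[method] += fit_method(method, ds, world).excludes_zero

print(f"{reps} simulated worlds, true correlation r = 0, strong cultural "
      "autocorrelation (lambda = rho = 0.8):")
for method, h in hits.items():
    print(f"  {method:12s} false-positive rate: {h / reps:.2f}")
print("\nA 95% test should reject ~5% of the time; the naive regression is "
      "fooled by\nshared ancestry, while random intercepts covarying with "
      "linguistic proximity\nabsorb the confounded variation.")
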