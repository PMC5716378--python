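"""Kernel dependence detection: HSIC distance correlation vs a linear kernel.

A quadratic relationship is invisible to covariance-based measures; the
rbf kernel sees it.  The permutation test calibrates what counts as
"large" for the sample at hand.
"""

import numpy as np

import wntgsa as w

rng = np.random.default_rng(0)
x = rng.uniform(-1, 1, 300)
u = x**2 + 0.05 * rng.normal(size=300)

for family in ("linear", "rbf", "laplace"):
    est = w.hsic_index(x, u, w.KernelSpec(family))
    print(f"R({family:<7}) = {est.value:.3f}")

perm = w.hsic_permutation_test(x, u, w.KernelSpec("rbf"), n_permutations=200, rng_seed=1)
print(f"\nrbf permutation test: R={perm['R']:.3f}, null 95th pct={perm['null_q95']:.3f}, "
      f"p={perm['p_value']:.4f}")
print("The linear-kernel index stays near its noise floor because cov(x, x^2)=0")
print("on symmetric data; the rbf/laplace indices are large and the permutation")
print("p-value confirms the dependence is real, not kernel-scale artefact.")
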