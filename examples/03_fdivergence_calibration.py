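"""Density-based indices on bivariate Gaussians with known divergence.

For a bivariate normal with correlation rho, the KL-divergence index (the
mutual information) is -0.5 ln(1 - rho^2), giving an exact calibration
target for the kernel-density estimator.
"""

import numpy as np

import wntgsa as w

for rho in (0.0, 0.5, 0.9):
    rng = np.random.default_rng(int(rho * 10))
    xy = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=5000)
    est = w.fdiv_index(xy[:, 0], xy[:, 1], "KL")
    truth = -0.5 * np.log(1 - rho**2)
    print(f"rho={rho:.1f}: KL index = {est.value:.3f}   closed form = {truth:.3f}")

rng = np.random.default_rng(99)
x, u = rng.normal(size=5000), rng.normal(size=5000)
for name in ("Hellinger", "TV", "PearsonChi2"):
    print(f"independent data, {name:<12}: {w.fdiv_index(x, u, name).value:.4f}")

print("\nThe KL column tracks the closed form within ~0.1 nats and grows with")
print("rho; on independent data every divergence reads near zero, its")
print("theoretical value.")
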