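"""Validate the five pick-freeze Sobol estimators on the g-function.

The g-function has analytically known sensitivity indices, so the Monte
Carlo estimators can be checked against exact values.  Smaller a_i means a
more important factor.
"""

import numpy as np

import wntgsa as w

a = np.array([0.0, 0.5, 3.0, 9.0, 99.0])
model = w.GFunctionModel(a)
S_true, T_true = w.g_function_analytic_indices(model)
design = w.build_design(n=2**14, d=5, rng_seed=0)

print("factor importances a =", a)
print(f"{'method':<14}" + "".join(f"S{i + 1}={s:.3f}  " for i, s in enumerate(S_true))
      + "(analytic)")
for method in w.SOBOL_METHODS:
    ests = w.estimate_sobol(model, design, method)
    S = [e.value for e in ests if e.order == "first"]
    print(f"{method:<14}" + "".join(f"S{i + 1}={s:.3f}  " for i, s in enumerate(S)))

print("\nEach row is one estimator's first-order indices at n=2^14; all five")
print("should agree with the analytic row to ~0.02.  The ordering mirrors the")
print("coefficients: factor 1 (a=0) dominates, factor 5 (a=99) is inert.")
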