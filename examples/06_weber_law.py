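"""The Bernoulli-to-Weber reduction on fold-change-like stimuli.

Sensation gamma = b log(beta/alpha) implies that the sensation increment
for a stimulus step depends only on the relative step delta_beta/beta; the
Weber ratio k_r recovered from the increment is exactly that relative step,
whatever b or the baseline.
"""

import wntgsa as w

b, alpha = 2.0, 0.5
for beta, delta in ((1.0, 0.25), (4.0, 1.0), (40.0, 10.0)):
    gamma = w.bernoulli_sensation(beta, alpha, b)
    dgamma = w.sensation_increment(beta, delta, b)
    k_r = w.weber_ratio_from_increment(dgamma, b)
    print(f"beta={beta:>5.1f} delta={delta:>5.2f}: gamma={gamma:+.3f} "
          f"dgamma={dgamma:.4f}  k_r={k_r:.4f}  (delta/beta={delta / beta:.4f})")

print("\nAll three rows share delta/beta = 0.25, so they produce the same")
print("sensation increment and the same Weber ratio: the response cares about")
print("relative, not absolute, change -- the rationale for analysing deviations")
print("in fold change rather than fold-change levels.")
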