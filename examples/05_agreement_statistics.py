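"""Method comparison: OLS R-squared and percent-scale Bland-Altman.

Compares a simulated 'AI' volume series against its reference with the same
statistics used to compare readers, AI and MRI measurements.
"""

import numpy as np

import sonotkv as sk

rng = np.random.default_rng(0)
truth = rng.uniform(150, 1400, size=24)            # reference volumes, mL
ai = truth * rng.normal(0.97, 0.05, size=24)       # 3% under-reading + noise

res = sk.compare_methods(ai, truth)
print(f"n = {res.n} paired volumes")
print(f"R^2                 : {res.r2:.3f}")
print(f"bias                : {res.bias_pct:+.2f} %")
print(f"limits of agreement : [{res.loa_low_pct:+.2f}, {res.loa_high_pct:+.2f}] %")
print(f"bias 95% CI         : [{res.bias_ci_low_pct:+.2f}, {res.bias_ci_high_pct:+.2f}] %")
print(f"bias significant    : {res.bias_significant}")
# A significant bias means zero lies outside the CI of the mean percent
# difference: the AI systematically under- or over-measures.
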