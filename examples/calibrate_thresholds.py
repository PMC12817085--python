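"""Calibrate benign/pathogenic score cutoffs with a Gaussian-mixture LR rule.

A two-component Gaussian mixture is fitted to a bimodal score sample; the
cutoffs solve LR(x) = 9 and 1/9, i.e. a 90% likelihood of the respective
class under the component densities.  The operational cutoffs shipped for
real transcriptome-wide scores are 0.30/0.70.
"""

import numpy as np

import stopext as se

rng = np.random.default_rng(11)
scores = np.concatenate([rng.normal(0.25, 0.07, 1500),   # benign-like mode
                         rng.normal(0.78, 0.06, 1000)])  # pathogenic-like mode
scores = np.clip(scores, 0, 1)

fit = se.fit_mixture(scores, seed=11)
print(f"B/LB component: mean {fit.benign.mu:.3f}, sd {fit.benign.sigma2**0.5:.3f}")
print(f"P/LP component: mean {fit.pathogenic.mu:.3f}, sd {fit.pathogenic.sigma2**0.5:.3f}")

th = se.solve_thresholds(fit, ratio=9)
print(f"solved cutoffs: lower {th.lower:.3f}, upper {th.upper:.3f}")
print(f"LR at cutoffs: {se.likelihood_ratio(th.upper, fit):.6f} and "
      f"{se.likelihood_ratio(th.lower, fit):.6f} (should be 9 and 1/9)")

for s in (0.1, 0.5, 0.9):
    print(f"score {s:.2f} -> {se.classify_score(s, th)}")
print("shipped operational cutoffs:", se.DEFAULT_THRESHOLDS)
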