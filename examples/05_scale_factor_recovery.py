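"""Recovering a harmonic frequency scale factor from noisy band pairs.

Published scaled-IR tables rarely state the factor applied; given paired
calculated/experimental bands, the least-squares slope through the origin
recovers an effective factor.  Synthetic pairs with a known factor show
the estimator's accuracy.
"""

import numpy as np

from qcpost import estimate_scale
from qcpost.synthetic import SyntheticSpec, gen_freq_pair

TRUE = 0.9614
ests = []
for seed in range(50):
    calc, exp = gen_freq_pair(SyntheticSpec(seed=seed, true_scale=TRUE,
                                            freq_noise_sd=5.0, n_freqs=30))
    ests.append(estimate_scale(calc, exp))

print(f"true factor: {TRUE}")
print(f"single-seed estimate (seed 0): {ests[0]:.5f}")
print(f"mean over 50 seeds: {np.mean(ests):.5f}  "
      f"(sd {np.std(ests):.5f}, max |err| {np.max(np.abs(np.array(ests) - TRUE)):.5f})")
# With 30 bands and 5 cm-1 noise the factor is recovered to ~1e-3 per
# spectrum and ~1e-4 in the mean - ample for choosing between published
# scale-factor conventions (0.89-0.98 depending on method/basis).
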