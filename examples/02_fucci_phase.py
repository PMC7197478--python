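"""From raw FUCCI scores to circular phase and discrete PAM labels.

Simulates reporter scores with plate and individual structure, removes the
plate effects with the two-factor linear model, maps corrected scores to
angles, and classifies cells into G1/S/G2M.
"""

import numpy as np

from cyclephase import classify_pam, correct_batch, infer_fucci_phase
from cyclephase import simulate as sim

n = 240
theta_true = sim.simulate_phases(n, seed=2)
plates = np.repeat([f"p{i}" for i in range(4)], n // 4)
indivs = np.tile(np.repeat(["NA18855", "NA18511", "NA19160"], n // 12), 4)
scores = sim.simulate_fucci_scores(
    theta_true, plates, indivs, noise_sd=0.1,
    plate_offsets={"p0": 0.3, "p1": -0.2, "p2": 0.0, "p3": 0.5},
    individual_offsets={"NA18855": 0.1, "NA18511": -0.3, "NA19160": 0.2},
    seed=3,
)

corrected, diag = correct_batch(scores)
plate_p = diag["ftests"].query("factor == 'plate'").p_value.min()
print(f"pre-correction plate F-test p (min over channels): {plate_p:.2e}")
# Tiny p: the planted plate offsets are detected before correction.

theta = infer_fucci_phase(corrected)
err = np.abs(np.angle(np.exp(1j * (theta - theta_true)))) / (2 * np.pi)
print(f"mean |recovered - true| phase: {100 * err.mean():.1f}% of the cycle")

labels, counts = classify_pam(corrected)
print(f"PAM counts: {counts}")
# Phases are recovered to a few percent of the cycle; the PAM counts split
# the circle into the three canonical reporter regimes.
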