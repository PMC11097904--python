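"""Run a QUEST staircase against a known synthetic observer.

The staircase keeps a grid posterior over log threshold, places every
trial at its posterior-mean estimate, and after 60 trials its estimate
sits where the observer's true accuracy is ~75% -- the criterion the
whole analysis thresholds at.
"""

import math

import numpy as np
from scipy.special import ndtr

from rotovis import quest_estimate, quest_init, quest_next_intensity, quest_update

MU, SIGMA = 0.3, 0.15  # the observer's true 75% point and slope


def true_p(x: float) -> float:
    return 0.5 + 0.5 * ndtr((x - MU) / SIGMA)


rng = np.random.default_rng(0)
state = quest_init(prior_mean_log=math.log10(0.3), prior_sd_log=0.5)
for t in range(60):
    x = quest_next_intensity(state)
    correct = bool(rng.random() < true_p(x))
    state = quest_update(state, x, correct)
    if t % 10 == 9:
        print(f"trial {t + 1:2d}: placed {x:.3f}, estimate {quest_estimate(state):.3f}")

est = quest_estimate(state)
print(f"\nfinal estimate {est:.3f} (true threshold {MU}); "
      f"observer's true accuracy there: {100 * true_p(est):.1f}% (target 75%)")
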