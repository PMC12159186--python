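"""Find the sensors carrying a reliable tagging response.

The z-transformed baseline-vs-search coherence difference (with the
Fisher bias term 1/(2n-2)) is compared against a permutation null built
by swapping the two segments within trials.  Only the sensors with a
planted 60/67 Hz carrier should exceed 99% of their null distribution.
"""

import numpy as np

from riftsearch import SimConfig, generate_experiment
from riftsearch.sensor_select import select_sensors

config = SimConfig(n_blocks=4, trials_per_block=20, n_sensors=10,
                   signal_sensors=(0, 1, 2), snr=0.5, search_duration=0.8,
                   seed=3)
rec, *_ = generate_experiment(config, with_gaze=False)

result = select_sensors(rec, n_perm=2000, alpha=0.01, seed=9)
print(result.to_frame().to_string(index=False))
print(f"\nselected: {np.flatnonzero(result.selected).tolist()} "
      f"(ground truth: {list(config.signal_sensors)})")
# empirical_z is the bias-corrected z of the coherence increase from
# baseline to search; null_quantile is its rank in the permutation null.
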