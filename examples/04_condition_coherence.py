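"""Trial-averaged coherence per stimulus role, with a temporal cluster test.

Computes the counterbalance-averaged coherence time course for the
guided target colour, the guided distractor colour and the unguided
reference, then tests target boosting (guided target > unguided) over
0.1-0.5 s with a one-tailed cluster-based permutation test across
simulated participants.
"""

import numpy as np

from riftsearch import SimConfig, generate_experiment
from riftsearch.cluster_stats import ClusterTestSpec, compare_coherence_conditions
from riftsearch.coherence import condition_coherence

sensors = [0, 1, 2]
tgt_all, ung_all, times = [], [], None
for subject in range(6):
    cfg = SimConfig(n_blocks=8, trials_per_block=16, n_sensors=6,
                    signal_sensors=tuple(sensors), snr=0.5,
                    search_duration=0.8, seed=subject)
    rec, trials, *_ = generate_experiment(cfg, with_gaze=False)
    times = rec.time
    tgt = condition_coherence(rec, trials, "target", condition="guided",
                              set_size=32)
    ung = condition_coherence(rec, trials, "unguided")
    tgt_all.append(tgt.values[sensors].mean(axis=0))
    ung_all.append(ung.values[sensors].mean(axis=0))

window = (times >= 0.1) & (times <= 0.5)
print(f"mean coherence 0.1-0.5 s: guided target "
      f"{np.array(tgt_all)[:, window].mean():.3f}, "
      f"unguided {np.array(ung_all)[:, window].mean():.3f}")

res = compare_coherence_conditions(
    np.array(tgt_all), np.array(ung_all), times,
    spec=ClusterTestSpec(tail="one", direction=1, n_perm=1000, seed=5))
top = res.clusters[0]
print(f"largest positive cluster: {top.members.size} samples, "
      f"mass {top.mass:.1f}, p = {top.p_value:.4f}")
# A p below 0.05 indicates target boosting: the tagging response to the
# known target colour exceeds the unguided reference in that interval.
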