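"""Behavioural performance: trial exclusion, d-prime and reaction times.

Excludes implausibly fast (<= 0.2 s) and no-response trials, then
summarises sensitivity (d' = z(H) - z(FA)) and mean RT per condition
cell.  Harder searches (larger set size, no colour cue) should show
slower RTs and lower d'.
"""

from riftsearch import SimConfig, generate_experiment
from riftsearch.behaviour import condition_summary, exclude_trials, median_split

_, trials, *_ = generate_experiment(SimConfig(seed=7), with_gaze=False)

kept, log = exclude_trials(trials)
print(f"{len(log)} of {len(trials)} trials excluded "
      f"({(log['reason'] == 'no_response').sum()} no-response, "
      f"{(log['reason'] == 'rt_too_fast').sum()} too fast)\n")

print(condition_summary(kept).to_string(index=False))
# d' is larger for guided search and for set size 16; mean RT shows the
# opposite ordering - the planted difficulty effects.

split = median_split(kept)
print("\nmedian split sizes:", split.value_counts().to_dict())
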