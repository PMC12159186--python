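"""Simulate a small frequency-tagged visual-search experiment.

Generates a blocked guided/unguided design with set sizes 16 and 32,
colour carriers at 60 and 67 Hz whose amplitudes encode target boosting
and distractor suppression, and prints the design structure.
"""

from riftsearch import SimConfig, generate_experiment

config = SimConfig(n_blocks=8, trials_per_block=16, n_sensors=8,
                   signal_sensors=(0, 1, 2), snr=0.5, search_duration=0.8,
                   seed=1)
rec, trials, layouts, gazes = generate_experiment(config)

print(f"recording: {rec.n_sensors} sensors x {rec.n_trials} trials x "
      f"{rec.n_samples} samples at {rec.fs:.0f} Hz")
print(f"epoch: {rec.time[0]:.2f} to {rec.time[-1]:.2f} s "
      "(0 = search-display onset)")
print(f"reference channels at {rec.ref_freqs} Hz\n")
print("trials per condition cell (columns: target present/absent):")
print(trials.groupby(["condition", "set_size"])["target_present"]
      .value_counts().unstack())
print("\nfirst trial's display:", layouts[0].set_size, "items,",
      (layouts[0].colours == "yellow").sum(), "yellow /",
      (layouts[0].colours == "cyan").sum(), "cyan")
# Each cell is balanced and the colour-frequency assignment alternates
# within blocks, so every downstream average is counterbalanced.
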