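"""Synthetic frequency-tagging search experiments with known ground truth.

Every downstream stage (coherence, sensor selection, single-trial GLM,
cluster statistics, gaze controls, DICS) is exercised on data from this
generator, so each trial's sensor signal is built from explicitly planted
components:

- 1/f^alpha Gaussian background noise plus white sensor noise,
- a damped broadband (30-80 Hz) burst at search-display onset emulating
  the early evoked response,
- two sinusoidal tag carriers, one per stimulus colour, present only
  during the search interval, whose amplitude is ``gain * snr`` with the
  gain chosen by the colour's role in the trial (guided target, guided
  distractor, or unguided).

Reference channels carry noiseless sinusoids at the tagging frequencies
with the carriers' phase, extending through the baseline, mirroring the
offline replacement of the photodiode signal by a phase-matched sine.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

from .config import ConfigurationError, SimConfig
from .containers import GazeTrace, StimulusLayout, TaggedRecording

TRIAL_COLUMNS = [
    "trial_index", "block", "condition", "set_size", "target_present",
    "target_colour", "freq_yellow", "freq_cyan", "response", "rt", "tot",
]


# ---------------------------------------------------------------------------
# building blocks


def make_reference(freq, phase, duration, fs, noise_amplitude=0.0, rng=None):
    """Unit-amplitude sinusoid at ``freq`` Hz plus optional white noise.

    With ``noise_amplitude=0`` this is the "perfect sine" reference; a
    small positive amplitude (0.05 in the emulated analysis) gives the
    reference non-zero power away from the tag frequency so that
    coherence spectra/TFRs avoid division by zero.

    Parameters
    ----------
    freq : float
        Frequency in Hz; must be below the Nyquist frequency ``fs / 2``.
    phase : float
        Phase in radians at t = 0.
    duration : float
        Length in seconds; the signal has ``round(duration * fs)`` samples.
    fs : float
        Sampling rate in Hz.
    noise_amplitude : float
        Standard deviation of the additive Gaussian white noise.
    rng : numpy.random.Generator, optional
        Source of the noise; required only when ``noise_amplitude > 0``
        and determinism is desired across calls.
    """
    if not 0 < freq < fs / 2:
        raise ValueError(f"freq {freq} Hz would alias at fs={fs} Hz")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    out = np.sin(2 * np.pi * freq * t + phase)
    if noise_amplitude > 0:
        rng = np.random.default_rng() if rng is None else rng
        out = out + noise_amplitude * rng.standard_normal(n)
    return out


def one_over_f_noise(shape, fs, exponent=1.0, rng=None):
    """Gaussian noise with power spectral density proportional to 1/f^exponent.

    Shaped in the frequency domain; the last axis is time.  Output is
    normalised to unit standard deviation per series.
    """
    rng = np.random.default_rng() if rng is None else rng
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC drift
    shaped = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def evoked_transient(time, fs, amplitude, rng, duration=0.15, band=(30.0, 80.0),
                     n_trials=None):
    """Damped broadband burst at t = 0 (30-80 Hz filtered-noise envelope).

    Emulates the early, frequency-unspecific response at search-display
    onset that shows up across all rows of the coherence TFR.  With
    ``n_trials`` set, returns one independent burst per trial, shape
    ``(n_trials, len(time))``.
    """
    n = time.size
    shape = (n,) if n_trials is None else (n_trials, n)
    burst = rng.standard_normal(shape)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    burst = signal.sosfiltfilt(sos, burst, axis=-1)
    sd = burst.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    burst = burst / sd
    envelope = np.zeros(n)
    post = time >= 0
    envelope[post] = np.exp(-time[post] / (duration / 3.0))
    return amplitude * burst * envelope


# ---------------------------------------------------------------------------
# trial table


def _block_schedule(config: SimConfig, rng: np.random.Generator):
    """Condition/set-size cell and target colour for each block."""
    cells = [(c, s) for c in ("guided", "unguided") for s in config.set_sizes]
    reps, rem = divmod(config.n_blocks, len(cells))
    order = cells * reps + cells[:rem]
    order = [order[i] for i in rng.permutation(len(order))]
    # guided blocks alternate target colour in counterbalanced fashion
    guided_colours = []
    for i in range(config.n_blocks):
        guided_colours.append(config.colours[i % 2])
    return order, guided_colours


def _balanced_bools(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random permutation of n booleans, half True (n//2 rounded up on True)."""
    vals = np.zeros(n, dtype=bool)
    vals[: (n + 1) // 2] = True
    return vals[rng.permutation(n)]


def build_trial_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Blocked, counterbalanced trial table with simulated behaviour.

    Each block holds ``trials_per_block`` trials, half target present and
    half absent, with the colour-to-frequency assignment balanced within
    the block.  In guided blocks the target colour is fixed for the block;
    in unguided blocks it is randomised per trial.  Reaction times follow
    a shifted lognormal whose location increases with set size and
    decreases under guidance; overly long draws become no-response trials.
    """
    order, guided_colours = _block_schedule(config, rng)
    c0, c1 = config.colours
    f0, f1 = config.tag_freqs
    rows = []
    idx = 0
    for block, (condition, set_size) in enumerate(order):
        n = config.trials_per_block
        present = _balanced_bools(n, rng)
        # balanced colour<->frequency assignment: True => c0 tagged at f0
        assign = _balanced_bools(n, rng)
        if condition == "guided":
            target_colours = [guided_colours[block]] * n
        else:
            target_colours = [config.colours[i] for i in rng.integers(0, 2, n)]
        for j in range(n):
            mu = (config.rt_meanlog
                  + config.rt_setsize_slope * (set_size == max(config.set_sizes))
                  + config.rt_guided_slope * (condition == "guided"))
            rt = config.rt_shift + float(rng.lognormal(mu, config.rt_sigmalog))
            p_corr = (config.accuracy_guided if condition == "guided"
                      else config.accuracy_unguided)
            p_corr -= config.accuracy_setsize_drop * (set_size == max(config.set_sizes))
            if rt > config.rt_timeout:
                response, rt = "none", np.nan
            else:
                correct = rng.random() < p_corr
                truth = "present" if present[j] else "absent"
                other = "absent" if present[j] else "present"
                response = truth if correct else other
            rows.append({
                "trial_index": idx,
                "block": block,
                "condition": condition,
                "set_size": set_size,
                "target_present": bool(present[j]),
                "target_colour": target_colours[j],
                "freq_yellow": f0 if assign[j] else f1,
                "freq_cyan": f1 if assign[j] else f0,
                "response": response,
                "rt": rt,
                "tot": 0.0,
            })
            idx += 1
    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    denom = max(len(trials) - 1, 1)
    trials["tot"] = trials["trial_index"] / denom
    return trials


def target_freq(trials: pd.DataFrame) -> np.ndarray:
    """Tag frequency of each trial's target colour."""
    return np.where(trials["target_colour"].to_numpy() == "yellow",
                    trials["freq_yellow"].to_numpy(),
                    trials["freq_cyan"].to_numpy())


def distractor_freq(trials: pd.DataFrame) -> np.ndarray:
    """Tag frequency of each trial's distractor colour."""
    return np.where(trials["target_colour"].to_numpy() == "yellow",
                    trials["freq_cyan"].to_numpy(),
                    trials["freq_yellow"].to_numpy())


# ---------------------------------------------------------------------------
# stimulus layouts


def generate_layout(set_size, target_colour, target_present, rng,
                    colours=("yellow", "cyan"), extent=5.0):
    """Random balanced search display on the 10 x 10 deg grid.

    Items occupy jittered cells of a regular lattice (no overlaps), with
    ``set_size / 2`` items of each colour and at most one target.
    """
    if set_size < 2 or set_size % 2:
        raise ConfigurationError("set_size must be even and >= 2")
    grid_n = int(np.ceil(np.sqrt(set_size * 1.5)))
    centres = np.linspace(-extent + extent / grid_n, extent - extent / grid_n, grid_n)
    xx, yy = np.meshgrid(centres, centres)
    cells = np.column_stack([xx.ravel(), yy.ravel()])
    pick = rng.choice(len(cells), size=set_size, replace=False)
    jitter = rng.uniform(-0.3, 0.3, size=(set_size, 2))
    positions = np.clip(cells[pick] + jitter, -extent, extent)
    colour_arr = np.array([colours[0]] * (set_size // 2) + [colours[1]] * (set_size // 2))
    colour_arr = colour_arr[rng.permutation(set_size)]
    is_target = np.zeros(set_size, dtype=bool)
    if target_present:
        candidates = np.flatnonzero(colour_arr == target_colour)
        is_target[rng.choice(candidates)] = True
    return StimulusLayout(positions=positions, colours=colour_arr, is_target=is_target)


# ---------------------------------------------------------------------------
# gaze


def generate_gaze(layout, duration, fs, colour_bias=0.5, jitter_scale=0.3,
                  seed=None, target_colour=None, saccade_rate=2.0,
                  anisotropy=2.0, blink_rate=0.15, rng=None):
    """Fixational gaze trace for one trial.

    ``colour_bias = 0.5`` yields gaze independent of stimulus colour:
    Gaussian fixational jitter around the display centre with
    microsaccade-like jumps that are predominantly horizontal
    (``anisotropy`` sets the horizontal:vertical amplitude ratio).  As
    ``colour_bias`` approaches 1, the fixation locus drifts toward a
    stimulus of the target colour; at ``colour_bias = 1`` with
    ``jitter_scale = 0`` the gaze is pinned to that stimulus.
    """
    if not 0.0 <= colour_bias <= 1.0:
        raise ValueError("colour_bias must lie in [0, 1]")
    if layout.set_size == 0:  # pragma: no cover - layout forbids this
        raise ValueError("empty layout")
    rng = np.random.default_rng(seed) if rng is None else rng
    n = int(round(duration * fs))
    if target_colour is None:
        if layout.is_target.any():
            target_colour = str(layout.colours[np.argmax(layout.is_target)])
        else:
            target_colour = str(layout.colours[0])
    targets = layout.positions[layout.colours == target_colour]
    if len(targets) == 0:
        anchor = np.zeros(2)
        weight = 0.0
    else:
        anchor = targets[rng.integers(len(targets))]
        weight = max(0.0, 2.0 * colour_bias - 1.0)
    centre = weight * anchor

    # slow drift: smoothed white noise around the fixation locus
    drift = rng.standard_normal((2, n))
    if n > 1:
        win = max(int(0.1 * fs), 1)
        kernel = np.ones(win) / win
        drift = np.stack([np.convolve(d, kernel, mode="same") for d in drift])
        sd = drift.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        drift = drift / sd
    pos = centre[:, None] + jitter_scale * drift

    saccades, offset = [], np.zeros(2)
    n_sacc = rng.poisson(saccade_rate * duration)
    for t0 in np.sort(rng.uniform(0, duration, n_sacc)):
        amp_x = rng.normal(0, 0.4 * anisotropy)
        amp_y = rng.normal(0, 0.4)
        i0 = int(t0 * fs)
        if i0 >= n:
            continue
        # saccade displacements scale with the fixational jitter so that
        # jitter_scale = 0 pins the gaze exactly to the fixation locus
        step = np.array([amp_x, amp_y]) * min(jitter_scale, 1.0)
        pos[:, i0:] += step[:, None] - offset[:, None] * 0.5
        offset = step
        saccades.append((t0, min(t0 + 0.02, duration)))

    blinks = []
    n_blink = rng.poisson(blink_rate * duration)
    for t0 in np.sort(rng.uniform(0, duration, n_blink)):
        blinks.append((t0, min(t0 + rng.uniform(0.1, 0.3), duration)))

    return GazeTrace(x=pos[0], y=pos[1], fs=fs,
                     saccade_events=saccades, blink_events=blinks)


# ---------------------------------------------------------------------------
# full experiment


def _role_gains(trials: pd.DataFrame, config: SimConfig):
    """Per-trial carrier gain for each tag frequency.

    Guided trials: the target colour's frequency carries ``boost_gain``
    and the distractor colour's ``suppress_gain``.  Unguided trials: both
    frequencies carry ``unguided_gain``.
    """
    n = len(trials)
    gains = np.full((n, 2), config.unguided_gain)
    guided = (trials["condition"] == "guided").to_numpy()
    tf = target_freq(trials)
    for fi, f in enumerate(config.tag_freqs):
        gains[guided & (tf == f), fi] = config.boost_gain
        gains[guided & (tf != f), fi] = config.suppress_gain
    return gains


def generate_experiment(config: SimConfig, with_gaze: bool = True):
    """Simulate a full experiment.

    Returns ``(recording, trials, layouts, gazes)``: the sensor/reference
    epochs, the trial table, one stimulus layout per trial and (unless
    ``with_gaze=False``) one gaze trace per trial.  Deterministic for a
    fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    trials = build_trial_table(config, rng)
    n_trials = len(trials)

    n_pre = int(round(config.baseline_duration * fs))
    n_post = int(round(config.search_duration * fs))
    time = np.arange(-n_pre, n_post + 1) / fs
    n_samples = time.size

    phases = rng.uniform(0, 2 * np.pi, size=2)
    ref = np.empty((2, n_trials, n_samples))
    for fi, f in enumerate(config.tag_freqs):
        ref[fi] = np.sin(2 * np.pi * f * time + phases[fi])[None, :]

    data = one_over_f_noise((config.n_sensors, n_trials, n_samples), fs,
                            exponent=config.noise_exponent, rng=rng)
    data += 0.3 * rng.standard_normal(data.shape)  # white sensor noise

    gains = _role_gains(trials, config)
    search = time >= 0
    sig_idx = np.asarray(config.signal_sensors, dtype=int)
    if sig_idx.size and config.snr > 0:
        carriers = np.zeros((n_trials, n_samples))
        for fi in range(2):
            carriers += gains[:, fi, None] * ref[fi] * search[None, :]
        data[sig_idx] += config.snr * carriers[None, :, :]
    if sig_idx.size and config.evoked_amplitude > 0:
        bursts = evoked_transient(time, fs, config.evoked_amplitude, rng,
                                  n_trials=n_trials)
        data[sig_idx] += bursts[None, :, :]

    labels = [f"S{i:03d}" for i in range(config.n_sensors)]
    rec = TaggedRecording(
        data=data, ref=ref, time=time, fs=fs, ref_freqs=tuple(config.tag_freqs),
        sensor_labels=labels,
        candidate_sensors=labels,
    )

    layouts = []
    for _, row in trials.iterrows():
        layouts.append(generate_layout(
            int(row["set_size"]), row["target_colour"], bool(row["target_present"]),
            rng, colours=config.colours))

    gazes = None
    if with_gaze:
        gazes = []
        for (_, row), layout in zip(trials.iterrows(), layouts):
            dur = row["rt"] if np.isfinite(row["rt"]) else config.search_duration
            dur = min(max(dur, 0.5), config.search_duration)
            gazes.append(generate_gaze(layout, dur, fs, colour_bias=0.5,
                                       target_colour=row["target_colour"], rng=rng))

    return rec, trials, layouts, gazes
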