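"""Trial-averaged Hilbert coherence between sensors and the tagging reference.

The core quantity is the per-sample coherence over trials

    coh(t) = | n^-1 sum_k m_meg(t) m_ref(t) exp(i dphi(t)) |
             -----------------------------------------------
             ( n^-1 sum_k |m_meg(t)| ) ( n^-1 sum_k |m_ref(t)| )

with ``m`` the analytic amplitudes after a narrow zero-phase FIR bandpass
and ``dphi`` the sensor-reference phase difference.  This is a
phase-locking-weighted amplitude ratio; with a constant-amplitude
reference it is bounded by 1 (triangle inequality on the numerator) and
it is invariant to positive rescaling of either signal.

Spectra and time-frequency maps evaluate the same quantity on a grid of
centre frequencies against a noise-augmented copy of the reference
sinusoid (noise amplitude 0.05 by default), so the reference has non-zero
power away from the tag frequency and the denominator never vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .containers import TaggedRecording
from .simdata import distractor_freq, make_reference, target_freq

DEFAULT_HALFWIDTH = 3.5  # Hz, passband half-width of the narrow filter


@dataclass
class AnalyticSignal:
    """Complex analytic signal after a zero-phase narrow bandpass.

    ``values`` holds the analytic samples (last axis = time); amplitude
    and phase are views of it.  ``edge_invalid`` counts the samples at
    each epoch edge that lie within one filter length and should not be
    interpreted.
    """

    values: np.ndarray
    fs: float
    centre_freq: float
    bandwidth: float
    edge_invalid: int = 0

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.values)


@dataclass
class CoherenceSeries:
    """Coherence values with their axes.

    ``values`` is (sensors, samples) for a time course or
    (sensors, freqs, samples) for a TFR.
    """

    values: np.ndarray
    time: np.ndarray
    n_trials: int
    freqs: np.ndarray | float
    role: str = ""


def design_bandpass(fs: float, centre: float, halfwidth: float = DEFAULT_HALFWIDTH):
    """Windowed-sinc (Hamming) FIR bandpass taps for centre +/- halfwidth.

    The transition bandwidth equals ``halfwidth``, so the Hamming window's
    ~53 dB stopband is reached by ``centre +/- 2 * halfwidth``.
    """
    nyq = fs / 2.0
    lo, hi = centre - halfwidth, centre + halfwidth
    if lo <= 0 or hi >= nyq:
        raise ValueError(f"band {lo}-{hi} Hz outside (0, {nyq}) Hz")
    numtaps = int(np.ceil(3.3 * fs / halfwidth))
    numtaps += 1 - numtaps % 2  # odd length, symmetric
    return signal.firwin(numtaps, [lo, hi], pass_zero=False,
                         window="hamming", fs=fs)


def _zero_phase_filter(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Two-pass (forward-backward) FIR filtering along the last axis.

    For a symmetric FIR kernel the forward-backward cascade equals a
    single convolution with the kernel's self-convolution, which is what
    is applied here (via overlap-add FFT convolution) after reflection
    padding.
    """
    n = x.shape[-1]
    pad = min(len(taps), n - 1)
    left = x[..., 1:pad + 1][..., ::-1]
    right = x[..., -pad - 1:-1][..., ::-1]
    padded = np.concatenate([left, x, right], axis=-1)
    h2 = np.convolve(taps, taps)
    shape = [1] * (padded.ndim - 1) + [len(h2)]
    y = signal.oaconvolve(padded, h2.reshape(shape), mode="same", axes=-1)
    return y[..., pad:pad + n]


def bandpass_analytic(x, fs: float, centre: float,
                      halfwidth: float = DEFAULT_HALFWIDTH) -> AnalyticSignal:
    """Zero-phase FIR bandpass then Hilbert analytic signal.

    ``x`` may be a :class:`TaggedRecording` (filters ``data``) or any
    array with time on the last axis.
    """
    if isinstance(x, TaggedRecording):
        arr, fs = x.data, x.fs
    else:
        arr = np.asarray(x, dtype=float)
    taps = design_bandpass(fs, centre, halfwidth)
    filtered = _zero_phase_filter(arr, taps)
    analytic = signal.hilbert(filtered, axis=-1)
    return AnalyticSignal(values=analytic, fs=fs, centre_freq=centre,
                          bandwidth=2 * halfwidth,
                          edge_invalid=min(len(taps), arr.shape[-1] - 1))


def coherence_timecourse(meg: AnalyticSignal | np.ndarray,
                         ref: AnalyticSignal | np.ndarray,
                         trial_subset=None,
                         time: np.ndarray | None = None) -> np.ndarray:
    """Per-sample coherence over trials between sensors and a reference.

    ``meg`` values are (..., n_trials, n_samples); ``ref`` values are
    (n_trials, n_samples).  Returns an array (..., n_samples).
    """
    a = meg.values if isinstance(meg, AnalyticSignal) else np.asarray(meg)
    r = ref.values if isinstance(ref, AnalyticSignal) else np.asarray(ref)
    if a.shape[-2:] != r.shape[-2:]:
        raise ValueError("meg and ref must share the trial/sample axes")
    if trial_subset is not None:
        idx = np.asarray(trial_subset)
        a = a[..., idx, :]
        r = r[idx, :]
    n_trials = a.shape[-2]
    if n_trials < 2:
        raise ValueError("coherence needs at least two trials")
    cross = a * np.conj(r)
    num = np.abs(cross.mean(axis=-2))
    den = np.abs(a).mean(axis=-2) * np.abs(r).mean(axis=-2)
    if np.any(den == 0):
        raise ZeroDivisionError(
            "zero mean amplitude in the coherence denominator; use a "
            "noise-augmented reference")
    return num / den


def coherence_tfr(rec: TaggedRecording, freqs=None, ref_freq: float | None = None,
                  ref_noise_amplitude: float = 0.05,
                  halfwidth: float = DEFAULT_HALFWIDTH,
                  trial_subset=None, seed: int | None = 0) -> CoherenceSeries:
    """Coherence time-frequency map against a noise-augmented reference.

    For each centre frequency on ``freqs`` (default 50-75 Hz in 1 Hz
    steps) both the sensor data and one noisy copy of the reference
    sinusoid are narrow-band filtered and the trial-averaged coherence
    time course is computed, giving (sensors, freqs, samples).
    """
    if freqs is None:
        freqs = np.arange(50.0, 76.0, 1.0)
    freqs = np.asarray(freqs, dtype=float)
    ref_freq = rec.ref_freqs[0] if ref_freq is None else ref_freq
    ri = rec.ref_index(ref_freq)
    rng = np.random.default_rng(seed)
    ref = rec.ref[ri] + ref_noise_amplitude * rng.standard_normal(rec.ref[ri].shape)
    data = rec.data
    if trial_subset is not None:
        idx = np.asarray(trial_subset)
        data, ref = data[:, idx, :], ref[idx, :]
    out = np.empty((rec.n_sensors, freqs.size, rec.n_samples))
    for i, f in enumerate(freqs):
        a = bandpass_analytic(data, rec.fs, f, halfwidth)
        r = bandpass_analytic(ref, rec.fs, f, halfwidth)
        out[:, i, :] = coherence_timecourse(a, r)
    return CoherenceSeries(values=out, time=rec.time, n_trials=data.shape[1],
                           freqs=freqs, role="tfr")


def condition_coherence(rec: TaggedRecording, trials: pd.DataFrame, role: str,
                        condition: str | None = None, set_size: int | None = None,
                        halfwidth: float = DEFAULT_HALFWIDTH,
                        min_trials: int = 2) -> CoherenceSeries:
    """Counterbalance-averaged coherence time course for one stimulus role.

    ``role`` is ``"target"`` (the trial's target colour), ``"distractor"``
    or ``"unguided"``.  For target/distractor the selected trials are
    split by which tag frequency carries the role's colour, the coherence
    time course is computed per split against the matching reference, and
    the two series are averaged, cancelling any frequency-specific
    response asymmetry.  For ``"unguided"`` the unguided trials are
    pooled and the series at both tag frequencies are averaged.
    """
    mask = np.ones(len(trials), dtype=bool)
    if condition is not None:
        mask &= (trials["condition"] == condition).to_numpy()
    if set_size is not None:
        mask &= (trials["set_size"] == set_size).to_numpy()

    if role == "unguided":
        if condition is None:
            mask &= (trials["condition"] == "unguided").to_numpy()
        rows = np.flatnonzero(mask)
        if rows.size < min_trials:
            raise ValueError("not enough trials for the unguided series")
        series = []
        for fi, f in enumerate(rec.ref_freqs):
            series.append(_series_at(rec, rows, fi, halfwidth))
        values = np.mean(series, axis=0)
        n = rows.size
    elif role in ("target", "distractor"):
        freq_of_role = target_freq(trials) if role == "target" else \
            distractor_freq(trials)
        series = []
        n = 0
        for fi, f in enumerate(rec.ref_freqs):
            rows = np.flatnonzero(mask & (freq_of_role == f))
            if rows.size < min_trials:
                raise ValueError(
                    f"split with <{min_trials} trials for role={role} at "
                    f"{f} Hz; both colour-frequency assignments must be "
                    "represented")
            series.append(_series_at(rec, rows, fi, halfwidth))
            n += rows.size
        values = np.mean(series, axis=0)
    else:
        raise ValueError("role must be 'target', 'distractor' or 'unguided'")
    return CoherenceSeries(values=values, time=rec.time, n_trials=int(n),
                           freqs=np.asarray(rec.ref_freqs), role=role)


def _series_at(rec: TaggedRecording, rows: np.ndarray, ref_idx: int,
               halfwidth: float) -> np.ndarray:
    f = rec.ref_freqs[ref_idx]
    a = bandpass_analytic(rec.data[:, rows, :], rec.fs, f, halfwidth)
    r = bandpass_analytic(rec.ref[ref_idx, rows, :], rec.fs, f, halfwidth)
    return coherence_timecourse(a, r)


def coherence_spectrum(rec: TaggedRecording, freqs=None,
                       window: tuple[float, float] = (0.1, 0.5),
                       **kwargs) -> tuple[np.ndarray, np.ndarray]:
    """Coherence spectrum: TFR averaged over a time window.

    Returns ``(freqs, values)`` with values (sensors, freqs).
    """
    tfr = coherence_tfr(rec, freqs=freqs, **kwargs)
    sl = rec.time_slice(window)
    return np.asarray(tfr.freqs), tfr.values[:, :, sl].mean(axis=-1)
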