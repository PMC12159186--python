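"""Permutation-based selection of sensors with a reliable tagging response.

For each sensor the coherence with the first tagging reference is
estimated separately in a pre-search baseline window and a search window,
and the difference is z-transformed with the Fisher-variance bias term:

    Z = [ (atanh|coh_search| - bias) - (atanh|coh_bsl| - bias) ] / sqrt(2 bias)

with bias = 1 / (2n - 2) for n trials.  The bias terms cancel in the
numerator, so Z = (atanh coh_search - atanh coh_bsl) * sqrt(n - 1); both
forms are exposed and asserted equal in the tests.

Significance is assessed with a Monte-Carlo permutation null: under the
null hypothesis the baseline and search segments of a trial are
exchangeable, so each permutation randomly swaps the two segments within
every trial and recomputes Z.  A sensor is selected when its empirical Z
is strictly larger than the (1 - alpha) fraction of its null draws
(alpha = 0.01: "larger than 99% of the null distribution").

Two coherence estimators are offered for the windows:

- ``method="fourier"`` (default): one Hanning-tapered Fourier coefficient
  per cut segment at the reference frequency; coherence over trials from
  the averaged cross- and auto-spectra.  The two segments are processed
  in complete isolation, so the segment-swap null is exact under
  exchangeability.
- ``method="hilbert"``: the narrow-band analytic-signal coherence
  computed per sample on the continuous epoch and averaged within each
  window (per-sample mean, or a single pooled window-wide estimate via
  ``average="pooled"``).  Because the narrow FIR kernel is long, the two
  windows share filtered noise under this route, which slightly
  under-disperses the swap null; it is retained for comparability with
  the response-magnitude time courses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coherence import DEFAULT_HALFWIDTH, bandpass_analytic
from .containers import TaggedRecording


@dataclass
class SelectionResult:
    """Outcome of the permutation sensor-selection test."""

    sensor_labels: list[str]
    empirical_z: np.ndarray
    null_quantile: np.ndarray  # fraction of null draws below the empirical z
    selected: np.ndarray
    n_permutations: int
    alpha: float
    n_trials: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sensor": self.sensor_labels,
            "empirical_z": self.empirical_z,
            "null_quantile": self.null_quantile,
            "selected": self.selected,
        })


def coherence_bias(n: int) -> float:
    """Variance bias term 1 / (2n - 2) of the Fisher-transformed coherence."""
    if n < 2:
        raise ValueError("bias undefined for fewer than two trials")
    return 1.0 / (2 * n - 2)


def z_coherence_diff(coh_search, coh_bsl, n: int):
    """Bias-corrected z-transformed coherence difference.

    Evaluates the printed expression
    ``((atanh|cs| - bias) - (atanh|cb| - bias)) / sqrt(2 bias)`` with
    ``bias = 1/(2n-2)``; algebraically equal to
    ``(atanh cs - atanh cb) * sqrt(n - 1)``.
    """
    coh_search = np.asarray(coh_search, dtype=float)
    coh_bsl = np.asarray(coh_bsl, dtype=float)
    if np.any(np.abs(coh_search) >= 1) or np.any(np.abs(coh_bsl) >= 1):
        raise ValueError("coherence magnitudes must be < 1 for atanh")
    bias = coherence_bias(n)
    num = (np.arctanh(np.abs(coh_search)) - bias) - (np.arctanh(np.abs(coh_bsl)) - bias)
    return num / np.sqrt(2 * bias)


# ---------------------------------------------------------------------------
# fourier route: one tapered coefficient per segment


def _segment_coefficients(rec: TaggedRecording, ref_idx: int, window):
    """Hanning-tapered Fourier coefficients of one window at the ref frequency.

    Returns ``(fx, fr)``: (n_sensors, n_trials) and (n_trials,) complex.
    """
    f = rec.ref_freqs[ref_idx]
    sl = rec.time_slice(window)
    x = rec.data[..., sl]
    r = rec.ref[ref_idx][..., sl]
    n = x.shape[-1]
    basis = np.hanning(n) * np.exp(-2j * np.pi * f * np.arange(n) / rec.fs)
    return x @ basis, r @ basis


def _coef_products(fx, fr):
    """Per-trial cross-spectra and powers from segment coefficients."""
    cross = fx * np.conj(fr)[None, :]          # (n_sensors, n_trials)
    pxx = np.abs(fx) ** 2
    pyy = np.abs(fr) ** 2
    return cross, pxx, pyy


def _coef_coherence(cross_sum, pxx_sum, pyy_sum):
    """Magnitude coherence |Sxy| / sqrt(Sxx Syy) from summed products."""
    return np.abs(cross_sum) / np.sqrt(pxx_sum * pyy_sum)


# ---------------------------------------------------------------------------
# hilbert route: per-sample Eq.-3 coherence averaged within the window


def _window_products(rec: TaggedRecording, ref_idx: int, window,
                     halfwidth: float):
    f = rec.ref_freqs[ref_idx]
    sl = rec.time_slice(window)
    a = bandpass_analytic(rec.data, rec.fs, f, halfwidth).values[..., sl]
    r = bandpass_analytic(rec.ref[ref_idx], rec.fs, f, halfwidth).values[..., sl]
    return a * np.conj(r)[None], np.abs(a), np.abs(r)


def _hilbert_coh_from_sums(cross_sum, amp_meg_sum, amp_ref_sum, n, average):
    num = np.abs(cross_sum / n)
    den = (amp_meg_sum / n) * (amp_ref_sum / n)
    coh = num / den
    if average == "samples":
        return coh.mean(axis=-1)
    if average == "pooled":
        return np.abs(cross_sum.mean(axis=-1)) / (
            amp_meg_sum.mean(axis=-1) * amp_ref_sum.mean(axis=-1) / n)
    raise ValueError("average must be 'samples' or 'pooled'")


def select_sensors(rec: TaggedRecording, trials=None,
                   search_window: tuple[float, float] = (0.0, 0.5),
                   baseline_window: tuple[float, float] = (-0.7, -0.2),
                   ref_freq: float | None = None,
                   n_perm: int = 10000, alpha: float = 0.01,
                   seed: int | None = None,
                   method: str = "fourier",
                   halfwidth: float = DEFAULT_HALFWIDTH,
                   average: str = "samples",
                   perm_chunk: int = 250) -> SelectionResult:
    """Monte-Carlo permutation test for a tagging response per sensor.

    Coherence with the ``ref_freq`` reference (default: the first tag
    frequency) is estimated within the baseline and search windows; the
    empirical z is the bias-corrected z-transformed difference.  The null
    is built by randomly swapping the two segments within each trial
    ``n_perm`` times (one shared trial-wise draw per permutation across
    sensors, as the segments of one trial are swapped for the whole
    array).  A sensor is selected when its empirical z strictly exceeds
    the (1 - alpha) fraction of its own null draws.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if method not in ("fourier", "hilbert"):
        raise ValueError("method must be 'fourier' or 'hilbert'")
    ref_idx = 0 if ref_freq is None else rec.ref_index(ref_freq)
    f = rec.ref_freqs[ref_idx]
    for win in (search_window, baseline_window):
        if (win[1] - win[0]) < 1.0 / f:
            raise ValueError(f"window {win} shorter than one cycle of {f} Hz")
    n = rec.n_trials
    if n < 2:
        raise ValueError("need at least two trials")
    rng = np.random.default_rng(seed)

    if method == "fourier":
        fx_s, fr_s = _segment_coefficients(rec, ref_idx, search_window)
        fx_b, fr_b = _segment_coefficients(rec, ref_idx, baseline_window)
        prod_s = _coef_products(fx_s, fr_s)
        prod_b = _coef_products(fx_b, fr_b)

        def z_of(search_sums, bsl_sums):
            coh_s = _coef_coherence(*search_sums)
            coh_b = _coef_coherence(*bsl_sums)
            return z_coherence_diff(np.clip(coh_s, 0, 1 - 1e-12),
                                    np.clip(coh_b, 0, 1 - 1e-12), n)

        def sums(prods, weights=None):
            if weights is None:
                return tuple(p.sum(axis=-1) for p in prods)
            # weights: (m, n_trials); products have trials on the last axis
            return tuple(p @ weights.T for p in prods)
    else:
        prod_s = _window_products(rec, ref_idx, search_window, halfwidth)
        prod_b = _window_products(rec, ref_idx, baseline_window, halfwidth)
        n_win = min(prod_s[0].shape[-1], prod_b[0].shape[-1])
        prod_s = tuple(p[..., :n_win] for p in prod_s)
        prod_b = tuple(p[..., :n_win] for p in prod_b)

        def z_of(search_sums, bsl_sums):
            coh_s = _hilbert_coh_from_sums(*search_sums, n, average)
            coh_b = _hilbert_coh_from_sums(*bsl_sums, n, average)
            return z_coherence_diff(np.clip(coh_s, 0, 1 - 1e-12),
                                    np.clip(coh_b, 0, 1 - 1e-12), n)

        def sums(prods, weights=None):
            if weights is None:
                return tuple(p.sum(axis=-2) for p in prods)
            # weights: (m, n_trials); products are (..., n_trials, n_win)
            return tuple(np.matmul(weights, p) for p in prods)

    empirical_z = np.atleast_1d(z_of(sums(prod_s), sums(prod_b)))

    count_ge = np.zeros(rec.n_sensors, dtype=int)
    done = 0
    while done < n_perm:
        m = min(perm_chunk, n_perm - done)
        swap = (rng.random((m, n)) < 0.5).astype(float)
        keep = 1.0 - swap
        null_search = tuple(ks + bs for ks, bs in
                            zip(sums(prod_s, keep), sums(prod_b, swap)))
        null_bsl = tuple(bs + ss for bs, ss in
                         zip(sums(prod_b, keep), sums(prod_s, swap)))
        z_null = z_of(null_search, null_bsl)  # (n_sensors, m)
        count_ge += (z_null >= empirical_z[..., None]).sum(axis=-1)
        done += m

    null_quantile = 1.0 - count_ge / n_perm
    selected = null_quantile > 1.0 - alpha
    return SelectionResult(
        sensor_labels=list(rec.sensor_labels),
        empirical_z=empirical_z,
        null_quantile=null_quantile,
        selected=selected,
        n_permutations=n_perm,
        alpha=alpha,
        n_trials=n,
    )
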