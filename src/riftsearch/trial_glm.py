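"""Single-trial Welch coherence and the stimulus-role GLM.

The single-trial tagging response is the magnitude-squared coherence
between a sensor and the reference, estimated with Welch's method: the
30-80 Hz band-passed epoch is segmented into 0.1 s Hanning-tapered
windows stepped by 0.025 s (75% overlap) across the 0.2-0.5 s interval,
each window is zero-padded to 512 samples, and the coherence is formed
from the averaged cross- and auto-spectra at the tag-frequency bin.

The responses to the target and distractor colours of all trials are
concatenated into one response vector and modelled with a four-column
design matrix: indicator columns for guided-target (T), unguided (U) and
guided-distractor (D) observations, plus a time-on-task regressor (tot)
scaled to [0, 1] by trial index.  The fit uses the Moore-Penrose
pseudoinverse, and contrasts C_target = [1, -1, 0, 0] and
C_distractor = [0, -1, 1, 0] yield cope, varcope and t per sensor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .containers import TaggedRecording
from .simdata import distractor_freq, target_freq

C_TARGET = np.array([1.0, -1.0, 0.0, 0.0])
C_DISTRACTOR = np.array([0.0, -1.0, 1.0, 0.0])


@dataclass
class WelchParams:
    """Windowing parameters of the single-trial coherence estimator."""

    interval: tuple[float, float] = (0.2, 0.5)
    window: float = 0.1
    step: float = 0.025
    nfft: int = 512
    filter_band: tuple[float, float] = (30.0, 80.0)
    filter_order: int = 4

    def n_windows(self, fs: float) -> int:
        span = self.interval[1] - self.interval[0]
        return int(np.floor((span - self.window) / self.step + 1e-9)) + 1

    def freq_bin(self, freq: float, fs: float) -> int:
        """Nearest FFT bin to ``freq`` on the zero-padded grid."""
        return int(round(freq * self.nfft / fs))


@dataclass
class DesignMatrix:
    """GLM design with observation provenance.

    ``X`` is (n_obs, 4) with columns (T, U, D, tot); ``row_map`` records
    each observation's source trial and stimulus role.
    """

    X: np.ndarray
    row_map: pd.DataFrame
    columns: tuple[str, ...] = ("T", "U", "D", "tot")


@dataclass
class GLMResult:
    """Pseudoinverse GLM fit with contrast statistics."""

    betas: np.ndarray          # (n_cols,) or (n_cols, n_series)
    sigma2: np.ndarray         # residual variance per series
    cope: np.ndarray           # (n_contrasts, ...) contrast estimates
    varcope: np.ndarray
    t: np.ndarray              # nan where varcope == 0 (flagged undefined)
    dof: int
    contrasts: np.ndarray


def bandpass_trials(x: np.ndarray, fs: float, params: WelchParams) -> np.ndarray:
    """Two-pass Butterworth 30-80 Hz bandpass along the last axis.

    Applied to the full (generously padded) epoch so that filter edge
    effects fall outside the analysis interval.
    """
    sos = signal.butter(params.filter_order, params.filter_band,
                        btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def _segment_starts(time: np.ndarray, fs: float, params: WelchParams):
    wlen = int(round(params.window * fs))
    step = int(round(params.step * fs))
    i0 = int(np.searchsorted(time, params.interval[0] - 1e-9))
    i1 = int(np.searchsorted(time, params.interval[1] - 1e-9))
    starts = np.arange(i0, i1 - wlen + 1, step)
    if len(starts) < 2:
        raise ValueError("interval too short: need at least two Welch windows")
    return starts, wlen


def single_trial_coherence(x: np.ndarray, ref: np.ndarray, time: np.ndarray,
                           fs: float, freq: float,
                           params: WelchParams | None = None,
                           prefilter: bool = True) -> np.ndarray:
    """Welch magnitude-squared coherence at the tag bin, per trial.

    ``x`` is (..., n_trials, n_samples), ``ref`` is (n_trials, n_samples);
    returns coherence in [0, 1] with shape ``x.shape[:-1]``.
    """
    params = params or WelchParams()
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if prefilter:
        x = bandpass_trials(x, fs, params)
        ref = bandpass_trials(ref, fs, params)
    starts, wlen = _segment_starts(time, fs, params)
    taper = signal.get_window("hann", wlen)
    k = params.freq_bin(freq, fs)

    segs_x = np.stack([x[..., s:s + wlen] for s in starts], axis=-2)
    segs_r = np.stack([ref[..., s:s + wlen] for s in starts], axis=-2)
    fx = np.fft.rfft(segs_x * taper, n=params.nfft, axis=-1)[..., k]
    fr = np.fft.rfft(segs_r * taper, n=params.nfft, axis=-1)[..., k]

    sxy = (fx * np.conj(fr)).mean(axis=-1)
    sxx = (np.abs(fx) ** 2).mean(axis=-1)
    syy = (np.abs(fr) ** 2).mean(axis=-1)
    return np.abs(sxy) ** 2 / (sxx * syy)


def rift_per_role(rec: TaggedRecording, trials: pd.DataFrame,
                  params: WelchParams | None = None):
    """Single-trial coherence at the target- and distractor-colour frequencies.

    Returns ``(rift_target, rift_distractor)``, each
    (n_sensors, n_trials): for every trial the Welch coherence between
    each sensor and the reference at the frequency tagging the role's
    colour.  In unguided trials the "target colour" is the design's
    randomised label, so the two arrays together cover both frequencies.
    """
    params = params or WelchParams()
    tfreq = target_freq(trials)
    dfreq = distractor_freq(trials)
    out_t = np.empty((rec.n_sensors, len(trials)))
    out_d = np.empty((rec.n_sensors, len(trials)))
    filt_data = bandpass_trials(rec.data, rec.fs, params)
    filt_ref = bandpass_trials(rec.ref, rec.fs, params)
    trial_pos = trials["trial_index"].to_numpy()
    for fi, f in enumerate(rec.ref_freqs):
        for out, freqs in ((out_t, tfreq), (out_d, dfreq)):
            sel = np.flatnonzero(freqs == f)
            if sel.size == 0:
                continue
            ks = trial_pos[sel]
            coh = single_trial_coherence(
                filt_data[:, ks, :], filt_ref[fi, ks, :], rec.time, rec.fs,
                f, params, prefilter=False)
            out[:, sel] = coh
    return out_t, out_d


def build_design(trials: pd.DataFrame, tot_denominator: float | None = None
                 ) -> DesignMatrix:
    """Four-column design from the concatenated role responses.

    The response vector is the target-colour coherence of every trial
    followed by the distractor-colour coherence of every trial (the same
    concatenation implemented by :func:`assemble_response`).  Guided
    trials contribute a (T) row and a (D) row; unguided trials contribute
    two (U) rows.  ``tot`` repeats the trial's time-on-task value on both
    of its rows.
    """
    n = len(trials)
    if n == 0:
        raise ValueError("empty trial table")
    guided = (trials["condition"] == "guided").to_numpy()
    if tot_denominator is None:
        tot = trials["tot"].to_numpy(dtype=float)
    else:
        tot = trials["trial_index"].to_numpy() / tot_denominator
    X = np.zeros((2 * n, 4))
    # first block: target-colour observations
    X[:n, 0] = guided
    X[:n, 1] = ~guided
    X[:n, 3] = tot
    # second block: distractor-colour observations
    X[n:, 2] = guided
    X[n:, 1] = ~guided
    X[n:, 3] = tot
    row_map = pd.DataFrame({
        "trial_index": np.concatenate([trials["trial_index"]] * 2),
        "role": ["target"] * n + ["distractor"] * n,
    })
    dm = DesignMatrix(X=X, row_map=row_map)
    if guided.any() and (~guided).any():
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix rank-deficient for this trial subset")
    return dm


def assemble_response(rift_target: np.ndarray, rift_distractor: np.ndarray
                      ) -> np.ndarray:
    """Concatenate role responses to match :func:`build_design` row order.

    Inputs are (n_sensors, n_trials); output is (2 * n_trials, n_sensors).
    """
    return np.concatenate([rift_target, rift_distractor], axis=-1).T


def fit_glm(y: np.ndarray, X: np.ndarray | DesignMatrix,
            contrasts: np.ndarray | None = None) -> GLMResult:
    """Pseudoinverse GLM fit with cope / varcope / t per contrast.

    ``y`` is (n_obs,) or (n_obs, n_series) — one series per sensor.
    ``varcope = diag(C (X'X)^+ C') * sigma2`` with ``sigma2`` the residual
    variance on ``n_obs - rank(X)`` degrees of freedom.  Where varcope is
    zero (perfect fit) the t value is flagged undefined (NaN) rather than
    returned as infinity.
    """
    if isinstance(X, DesignMatrix):
        X = X.X
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    if y.shape[0] != X.shape[0]:
        raise ValueError("response rows must align with design rows")
    if contrasts is None:
        contrasts = np.stack([C_TARGET, C_DISTRACTOR])
    contrasts = np.atleast_2d(np.asarray(contrasts, dtype=float))

    pinv = np.linalg.pinv(X)
    betas = pinv @ y                          # (n_cols, n_series)
    resid = y - X @ betas
    rank = np.linalg.matrix_rank(X)
    dof = y.shape[0] - rank
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = (resid ** 2).sum(axis=0) / dof

    xtx_inv = np.linalg.pinv(X.T @ X)
    cope = contrasts @ betas                  # (n_contrasts, n_series)
    cvar = np.einsum("ij,jk,ik->i", contrasts, xtx_inv, contrasts)
    varcope = cvar[:, None] * sigma2[None, :]
    # a residual variance at round-off level means a perfect fit: the t
    # statistic is undefined there, not astronomically large
    tol = (y ** 2).mean(axis=0) * (100 * np.finfo(float).eps) ** 2
    defined = varcope > cvar[:, None] * tol[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(defined, cope / np.sqrt(varcope), np.nan)
    if squeeze:
        betas, sigma2 = betas[:, 0], sigma2[0]
        cope, varcope, t = cope[:, 0], varcope[:, 0], t[:, 0]
    return GLMResult(betas=betas, sigma2=sigma2, cope=cope, varcope=varcope,
                     t=t, dof=dof, contrasts=contrasts)


def behaviour_glm(y: np.ndarray, trials: pd.DataFrame) -> GLMResult:
    """GLM of one role's guided-trial responses on constant, tot and RT.

    ``y`` is (n_trials,) or (n_trials, n_series) aligned with ``trials``
    (guided trials with finite reaction times).  The returned contrasts
    are the identity rows for (constant, tot, rt); the rt-row t value
    tests reaction-time dependence of the tagging response.
    """
    if not (trials["condition"] == "guided").all():
        raise ValueError("behaviour GLM is defined for guided trials only")
    rt = trials["rt"].to_numpy(dtype=float)
    if not np.all(np.isfinite(rt)):
        raise ValueError("all trials must have a reaction time")
    X = np.column_stack([np.ones(len(trials)), trials["tot"].to_numpy(), rt])
    return fit_glm(y, X, contrasts=np.eye(3))
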