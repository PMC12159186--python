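"""DICS beamforming: source-level coherence with the tagging reference.

The sensor-plus-reference cross-spectral density (CSD) matrix is
estimated at one frequency from Hanning-tapered Fourier coefficients of
short data segments.  The sensor block is inverted with a truncated-SVD
pseudoinverse (robust to rank deficiency), unit-noise-gain minimum-
variance spatial filters are formed per grid point from the lead field,
and the magnitude-squared coherence between each source and the
reference channel is mapped over the grid.  A percentile mask extracts
the most strongly activated grid points (top 1% by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class LeadField:
    """Scalar (fixed-orientation) gain matrix, sensors x grid points."""

    L: np.ndarray
    positions: np.ndarray  # (n_grid, n_dim) grid coordinates

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.L.ndim != 2:
            raise ValueError("lead field must be 2-D (sensors x grid)")
        if self.positions.shape[0] != self.L.shape[1]:
            raise ValueError("one position per grid point required")
        if not np.all(np.isfinite(self.L)):
            raise ValueError("lead field entries must be finite")
        if np.any(np.linalg.norm(self.L, axis=0) == 0):
            raise ValueError("lead field has an all-zero column")

    @property
    def n_sensors(self) -> int:
        return self.L.shape[0]

    @property
    def n_grid(self) -> int:
        return self.L.shape[1]


@dataclass
class CSDMatrix:
    """Complex Hermitian CSD at one frequency; last row/col = reference."""

    C: np.ndarray
    freq: float
    n_segments: int

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=complex)
        n = self.C.shape[0]
        if self.C.shape != (n, n):
            raise ValueError("CSD must be square")
        if not np.allclose(self.C, self.C.conj().T):
            raise ValueError("CSD must be Hermitian")

    @property
    def n_sensors(self) -> int:
        return self.C.shape[0] - 1

    @property
    def sensor_block(self) -> np.ndarray:
        return self.C[:-1, :-1]

    @property
    def ref_cross(self) -> np.ndarray:
        """Cross-spectrum between each sensor and the reference."""
        return self.C[:-1, -1]

    @property
    def ref_power(self) -> float:
        return float(self.C[-1, -1].real)


@dataclass
class SourceMap:
    """Per-grid-point coherence with the reference, plus the filters."""

    coherence: np.ndarray
    filters: np.ndarray  # (n_grid, n_sensors), unit-norm rows
    positions: np.ndarray
    freq: float
    mask: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        cols = {f"pos_{ax}": self.positions[:, i]
                for i, ax in enumerate("xyz"[: self.positions.shape[1]])}
        cols["coherence"] = self.coherence
        if self.mask is not None:
            cols["mask"] = self.mask
        out = pd.DataFrame(cols)
        out.insert(0, "grid_index", np.arange(len(out)))
        return out


def segment_fourier(x: np.ndarray, fs: float, freq: float,
                    taper: str = "hann") -> np.ndarray:
    """Tapered Fourier coefficient of each segment at exactly ``freq`` Hz.

    ``x`` is (..., n_segments, n_samples); the exact-frequency DFT is used
    so the tag frequency need not sit on an FFT grid.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    t = np.arange(n) / fs
    if taper == "hann":
        w = np.hanning(n)
    elif taper in (None, "boxcar"):
        w = np.ones(n)
    else:
        raise ValueError(f"unknown taper {taper!r}")
    basis = w * np.exp(-2j * np.pi * freq * t)
    return x @ basis


def estimate_csd(data_segments: np.ndarray, ref_segments: np.ndarray,
                 fs: float, freq: float, taper: str = "hann") -> CSDMatrix:
    """Sensor-plus-reference CSD from tapered segment Fourier coefficients.

    ``data_segments`` is (n_sensors, n_segments, n_samples) — e.g. the
    0-0.5 s search segment of every trial — and ``ref_segments`` is
    (n_segments, n_samples).  The CSD is the average over segments of the
    outer product of the stacked coefficient vector with itself.
    """
    data_segments = np.asarray(data_segments, dtype=float)
    ref_segments = np.asarray(ref_segments, dtype=float)
    if data_segments.ndim != 3 or ref_segments.ndim != 2:
        raise ValueError("expected (sensors, segments, samples) data and "
                         "(segments, samples) reference")
    n_seg = data_segments.shape[1]
    if n_seg < 2:
        raise ValueError("CSD from a single segment is rank 1; need >= 2")
    fx = segment_fourier(data_segments, fs, freq, taper)  # (nsens, nseg)
    fr = segment_fourier(ref_segments, fs, freq, taper)   # (nseg,)
    v = np.vstack([fx, fr[None, :]])                      # (nsens+1, nseg)
    C = (v @ v.conj().T) / n_seg
    C = 0.5 * (C + C.conj().T)  # exact Hermitian symmetry
    return CSDMatrix(C=C, freq=freq, n_segments=n_seg)


def truncated_svd_pinv(C: np.ndarray, rank: int | None = None,
                       rank_tol: float | None = None) -> np.ndarray:
    """Pseudoinverse of a Hermitian matrix on its numerically retained subspace.

    Singular values below ``rank_tol * s_max`` (default:
    ``dim * machine-epsilon``) are discarded; alternatively an explicit
    ``rank`` keeps exactly that many components.
    """
    C = np.asarray(C)
    if not np.allclose(C, C.conj().T):
        raise ValueError("input must be Hermitian")
    u, s, vh = np.linalg.svd(C)
    if rank is None:
        tol = (rank_tol if rank_tol is not None
               else C.shape[0] * np.finfo(float).eps)
        keep = s > tol * s[0] if s[0] > 0 else np.zeros_like(s, dtype=bool)
        rank = int(keep.sum())
    if rank == 0:
        raise ValueError("all singular values below tolerance")
    return (vh[:rank].conj().T / s[:rank]) @ u[:, :rank].conj().T


def dics_map(leadfield: LeadField, csd: CSDMatrix,
             rank: int | None = None, rank_tol: float | None = None,
             measure: str = "magnitude_squared") -> SourceMap:
    """Unit-noise-gain DICS source coherence map.

    For each grid point the minimum-variance filter
    ``w ∝ C_ss^+ l`` is normalised to unit Euclidean norm (unit noise
    gain), and the coherence with the reference is
    ``|w^H c_ref|^2 / ((w^H C_ss w) * P_ref)`` — in [0, 1] for a valid
    averaged CSD.  ``measure="magnitude"`` reports the square root.
    """
    if leadfield.n_sensors != csd.n_sensors:
        raise ValueError("lead field and CSD sensor dimensions differ")
    if measure not in ("magnitude_squared", "magnitude"):
        raise ValueError("measure must be 'magnitude_squared' or 'magnitude'")
    c_ss = csd.sensor_block
    c_inv = truncated_svd_pinv(c_ss, rank=rank, rank_tol=rank_tol)
    W = c_inv @ leadfield.L                      # (n_sensors, n_grid)
    norms = np.linalg.norm(W, axis=0)
    bad = norms == 0
    norms[bad] = 1.0
    W = W / norms[None, :]
    cross = W.conj().T @ csd.ref_cross           # (n_grid,)
    auto = np.einsum("sg,st,tg->g", W.conj(), c_ss, W).real
    denom = auto * csd.ref_power
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.where(denom > 0, np.abs(cross) ** 2 / denom, 0.0)
    coh = np.clip(coh, 0.0, 1.0)
    coh[bad] = np.nan  # zero lead-field column: grid point flagged
    if measure == "magnitude":
        coh = np.sqrt(coh)
    return SourceMap(coherence=coh, filters=W.T, positions=leadfield.positions,
                     freq=csd.freq)


def top_percent_mask(source_map: SourceMap | np.ndarray,
                     percent: float = 1.0) -> np.ndarray:
    """Boolean mask of the ceil(percent% * n_grid) highest-coherence points.

    Ties are broken by stable grid order (lower index wins).
    """
    values = (source_map.coherence if isinstance(source_map, SourceMap)
              else np.asarray(source_map, dtype=float))
    n = values.size
    if n == 0:
        raise ValueError("empty map")
    k = int(np.ceil(percent / 100.0 * n))
    order = np.argsort(-np.nan_to_num(values, nan=-np.inf), kind="stable")
    mask = np.zeros(n, dtype=bool)
    mask[order[:k]] = True
    if isinstance(source_map, SourceMap):
        source_map.mask = mask
    return mask


def make_synthetic_leadfield(n_sensors: int = 30, grid_shape=(8, 8),
                             extent: float = 6.0, sensor_radius: float = 9.0,
                             seed: int | None = 0) -> LeadField:
    """Synthetic smooth lead field: planar source grid, sensor ring above.

    Gains fall off with squared sensor-source distance, with mild random
    per-sensor gain variation; a stand-in for anatomy-based forward
    models, adequate for localisation tests at desk scale.
    """
    rng = np.random.default_rng(seed)
    gx, gy = grid_shape
    xs = np.linspace(-extent, extent, gx)
    ys = np.linspace(-extent, extent, gy)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    positions = np.column_stack([xx.ravel(), yy.ravel(),
                                 np.zeros(gx * gy)])
    ang = np.linspace(0, 2 * np.pi, n_sensors, endpoint=False)
    sensors = np.column_stack([sensor_radius * np.cos(ang),
                               sensor_radius * np.sin(ang),
                               np.full(n_sensors, 4.0)])
    d2 = ((sensors[:, None, :] - positions[None, :, :]) ** 2).sum(axis=-1)
    gains = 1.0 + 0.1 * rng.standard_normal(n_sensors)
    L = gains[:, None] / (1.0 + d2 / 20.0)
    return LeadField(L=L, positions=positions)
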