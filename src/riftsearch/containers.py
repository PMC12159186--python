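"""In-memory containers shared across analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TaggedRecording:
    """Multichannel sensor epochs plus per-frequency reference signals.

    Attributes
    ----------
    data
        Sensor time series, shape ``(n_sensors, n_trials, n_samples)``,
        arbitrary units.
    ref
        Reference ("photodiode") signals, one channel per tagging
        frequency, shape ``(n_refs, n_trials, n_samples)``.  By default
        these are noiseless sinusoids with the phase of the physical
        flicker, extending through the baseline.
    time
        Sample axis in seconds; 0 marks search-display onset.
    fs
        Sampling rate in Hz.
    ref_freqs
        Tagging frequency of each reference channel, in Hz.
    sensor_labels
        One label per sensor row.
    candidate_sensors
        Labels of the sensors eligible for tagging-response selection
        (the analogue of the occipital candidate set).
    """

    data: np.ndarray
    ref: np.ndarray
    time: np.ndarray
    fs: float
    ref_freqs: tuple[float, ...]
    sensor_labels: list[str] = field(default_factory=list)
    candidate_sensors: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.ref = np.asarray(self.ref)
        self.time = np.asarray(self.time, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_sensors, n_trials, n_samples)")
        if self.ref.ndim != 3:
            raise ValueError("ref must be (n_refs, n_trials, n_samples)")
        if self.data.shape[2] != self.time.size or self.ref.shape[2] != self.time.size:
            raise ValueError("data/ref sample axis must match time axis")
        if self.ref.shape[0] != len(self.ref_freqs):
            raise ValueError("one ref_freq per reference channel required")
        if not self.sensor_labels:
            self.sensor_labels = [f"S{i:03d}" for i in range(self.data.shape[0])]
        if not self.candidate_sensors:
            self.candidate_sensors = list(self.sensor_labels)

    @property
    def n_sensors(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def sensor_index(self, label: str) -> int:
        return self.sensor_labels.index(label)

    def ref_index(self, freq: float) -> int:
        """Index of the reference channel tagged at ``freq`` Hz."""
        for i, f in enumerate(self.ref_freqs):
            if np.isclose(f, freq):
                return i
        raise KeyError(f"no reference channel at {freq} Hz")

    def time_slice(self, window: tuple[float, float]) -> slice:
        """Sample slice covering ``window = (t_start, t_stop)`` seconds."""
        lo, hi = window
        if lo < self.time[0] - 1e-9 or hi > self.time[-1] + 1e-9:
            raise ValueError(f"window {window} outside epoch "
                             f"[{self.time[0]}, {self.time[-1]}]")
        i0 = int(np.searchsorted(self.time, lo - 1e-9))
        i1 = int(np.searchsorted(self.time, hi - 1e-9))
        return slice(i0, i1)

    def select_trials(self, idx) -> "TaggedRecording":
        idx = np.asarray(idx)
        return TaggedRecording(
            data=self.data[:, idx, :],
            ref=self.ref[:, idx, :],
            time=self.time,
            fs=self.fs,
            ref_freqs=self.ref_freqs,
            sensor_labels=list(self.sensor_labels),
            candidate_sensors=list(self.candidate_sensors),
        )


@dataclass
class StimulusLayout:
    """Search-display layout in screen-centred degrees visual angle.

    ``positions`` has shape ``(set_size, 2)`` with +x rightward and +y
    upward; all items lie inside the 10 deg x 10 deg search grid.  Colour
    counts are balanced and at most one item is the target.
    """

    positions: np.ndarray
    colours: np.ndarray
    is_target: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.colours = np.asarray(self.colours)
        self.is_target = np.asarray(self.is_target, dtype=bool)
        n = self.positions.shape[0]
        if n == 0:
            raise ValueError("layout must contain at least one stimulus")
        if self.positions.shape != (n, 2):
            raise ValueError("positions must be (n, 2)")
        if self.colours.shape != (n,) or self.is_target.shape != (n,):
            raise ValueError("colours/is_target must have one entry per stimulus")
        if self.is_target.sum() > 1:
            raise ValueError("at most one target per layout")
        if np.any(np.abs(self.positions) > 5.0 + 1e-9):
            raise ValueError("positions must lie within the 10x10 deg grid")

    @property
    def set_size(self) -> int:
        return self.positions.shape[0]


@dataclass
class GazeTrace:
    """Gaze samples for one trial, from search onset, in degrees.

    ``saccade_events`` / ``blink_events`` are lists of ``(onset, offset)``
    pairs in seconds relative to search onset.  Samples inside a blink are
    flagged invalid; elsewhere x and y are finite.
    """

    x: np.ndarray
    y: np.ndarray
    fs: float
    saccade_events: list[tuple[float, float]] = field(default_factory=list)
    blink_events: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")

    @property
    def n_samples(self) -> int:
        return self.x.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def valid_mask(self) -> np.ndarray:
        """True for samples outside every blink event."""
        t = np.arange(self.n_samples) / self.fs
        valid = np.isfinite(self.x) & np.isfinite(self.y)
        for onset, offset in self.blink_events:
            valid &= ~((t >= onset) & (t < offset))
        return valid
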