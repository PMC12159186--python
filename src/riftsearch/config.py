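"""Simulation configuration.

:class:`SimConfig` collects every knob of the synthetic experiment in one
validated, JSON-serialisable record.  The defaults reproduce the design of
the emulated study: 24 blocks of 40 trials (960 trials), guided/unguided
search crossed with set sizes 16 and 32, colour luminance tagged at 60 and
67 Hz, 1000 Hz sampling, a 1.5 s pre-search baseline.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

SCHEMA_VERSION = 1


class ConfigurationError(ValueError):
    """Raised when a :class:`SimConfig` violates its invariants."""


@dataclass
class SimConfig:
    """Parameters of a synthetic frequency-tagging search experiment.

    Parameters
    ----------
    sampling_rate
        Sensor and gaze sampling rate in Hz.
    tag_freqs
        The two tagging frequencies in Hz, one per stimulus colour.  Must
        be distinct and below the Nyquist frequency.
    n_blocks, trials_per_block
        Blocked design; ``trials_per_block`` must be even so each block
        holds equal numbers of target-present and target-absent trials.
    set_sizes
        Number of search items per display; constant within a block.
    baseline_duration, search_duration
        Epoch extent in seconds around search-display onset (t = 0).
    boost_gain, suppress_gain, unguided_gain
        Dimensionless amplitude multipliers of the tag carrier for the
        guided-target colour, guided-distractor colour and unguided
        stimuli.  ``boost_gain >= unguided_gain >= suppress_gain`` plants
        the boosting/suppression effect; equal gains give a null
        simulation.
    evoked_amplitude
        Amplitude (a.u.) of the broadband evoked transient at display
        onset.
    noise_exponent
        Spectral slope alpha of the 1/f^alpha background noise.
    snr
        Amplitude of the unit-gain tag carrier relative to the background
        noise standard deviation.
    n_sensors, signal_sensors
        Total synthetic sensors and the index subset that carries the tag
        response (the "occipital" sensors of the emulated array).
    rt_shift, rt_meanlog, rt_sigmalog, rt_setsize_slope, rt_guided_slope
        Shifted-lognormal reaction-time model: ``rt = rt_shift +
        LogNormal(mu, rt_sigmalog)`` with ``mu = rt_meanlog +
        rt_setsize_slope * [set size 32] + rt_guided_slope * [guided]``.
        The slope signs follow the behavioural effect directions (larger
        set size slower, guidance faster).
    accuracy_guided, accuracy_unguided, accuracy_setsize_drop
        Per-trial probability of a correct present/absent response.
    rt_timeout
        Trials whose drawn reaction time exceeds this limit are recorded
        as no-response trials.
    seed
        Seed for all randomness in the generator.
    """

    sampling_rate: float = 1000.0
    tag_freqs: tuple[float, float] = (60.0, 67.0)
    n_blocks: int = 24
    trials_per_block: int = 40
    set_sizes: tuple[int, int] = (16, 32)
    baseline_duration: float = 1.5
    search_duration: float = 1.0
    boost_gain: float = 1.3
    suppress_gain: float = 0.7
    unguided_gain: float = 1.0
    evoked_amplitude: float = 1.0
    noise_exponent: float = 1.0
    snr: float = 0.3
    n_sensors: int = 20
    signal_sensors: tuple[int, ...] = (0, 1, 2, 3, 4)
    rt_shift: float = 0.2
    rt_meanlog: float = -0.55
    rt_sigmalog: float = 0.35
    rt_setsize_slope: float = 0.18
    rt_guided_slope: float = -0.138
    accuracy_guided: float = 0.97
    accuracy_unguided: float = 0.93
    accuracy_setsize_drop: float = 0.02
    rt_timeout: float = 4.0
    colours: tuple[str, str] = ("yellow", "cyan")
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        nyquist = self.sampling_rate / 2.0
        if len(set(self.tag_freqs)) != 2:
            raise ConfigurationError("tag_freqs must be two distinct frequencies")
        if any(not (0.0 < f < nyquist) for f in self.tag_freqs):
            raise ConfigurationError(
                f"tag_freqs {self.tag_freqs} must lie in (0, {nyquist}) Hz"
            )
        if self.trials_per_block % 2:
            raise ConfigurationError(
                "trials_per_block must be even (half target present, half absent)"
            )
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ConfigurationError("need at least one block of one trial")
        if min(self.boost_gain, self.suppress_gain, self.unguided_gain) <= 0:
            raise ConfigurationError("condition gains must be positive")
        if self.snr < 0:
            raise ConfigurationError("snr must be non-negative")
        if not isinstance(self.seed, (int,)) or isinstance(self.seed, bool):
            raise ConfigurationError("seed must be an integer")
        if len(set(self.colours)) != 2:
            raise ConfigurationError("colours must be two distinct labels")
        if any(s < 0 or s >= self.n_sensors for s in self.signal_sensors):
            raise ConfigurationError("signal_sensors out of range")
        if self.baseline_duration <= 0 or self.search_duration <= 0:
            raise ConfigurationError("epoch durations must be positive")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schema_version"] = SCHEMA_VERSION
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        version = d.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ConfigurationError(f"unsupported config schema version {version}")
        field_names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - field_names
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        for name in ("tag_freqs", "set_sizes", "signal_sensors", "colours"):
            if name in d and isinstance(d[name], list):
                d[name] = tuple(d[name])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)
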