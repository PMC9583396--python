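"""Shared containers for continuous signals, movements and recording sessions.

Conventions used throughout the package:

* EMG is sampled at ``fs_emg`` (1000 Hz by default) in volts (post-amplifier),
  the elbow angle at ``fs_kin`` (125 Hz) in degrees; both clocks share a
  common time origin ``t0`` so events detected on the kinematic clock can be
  mapped onto the EMG clock by nearest-sample conversion.
* Muscle channels are keyed ``"TB"`` (triceps brachii, extensor/agonist),
  ``"BB"`` (biceps brachii) and ``"BR"`` (brachioradialis), the two elbow
  flexors acting as antagonists during extension.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

EMG_CHANNELS = ("TB", "BB", "BR")
FLEXORS = ("BB", "BR")


@dataclass
class TimeSeries:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    samples:
        1-D array of finite values (volts for EMG, degrees for angle,
        deg/s for angular velocity).
    fs:
        Sampling rate in Hz, strictly positive.
    label:
        Channel name, e.g. ``"TB"`` or ``"elbow_angle"``.
    t0:
        Time of the first sample in seconds on the session clock.
    """

    samples: np.ndarray
    fs: float
    label: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("TimeSeries samples must be 1-D")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"non-finite samples in channel {self.label!r}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n / self.fs

    @property
    def t_end(self) -> float:
        """Time of the last sample."""
        return self.t0 + (self.n - 1) / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def index_of(self, t: float) -> int:
        """Nearest sample index for session time ``t``."""
        i = int(round((t - self.t0) * self.fs))
        return min(max(i, 0), self.n - 1)

    def slice(self, t_start: float, t_end: float) -> "TimeSeries":
        """Sub-series covering ``[t_start, t_end]`` (nearest samples, inclusive)."""
        i0 = self.index_of(t_start)
        i1 = self.index_of(t_end)
        return TimeSeries(
            self.samples[i0 : i1 + 1],
            self.fs,
            label=self.label,
            t0=self.t0 + i0 / self.fs,
        )

    def with_samples(self, samples: np.ndarray) -> "TimeSeries":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass
class MovementBounds:
    """Onset, offset and peak-velocity time of one detected movement (seconds).

    ``peak_velocity`` keeps its sign: positive for extension (angle
    increasing), negative for flexion.
    """

    onset: float
    offset: float
    peak_velocity_time: float
    peak_velocity: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.onset < self.peak_velocity_time < self.offset):
            raise ValueError(
                "movement bounds must satisfy onset < peak-velocity time < offset, got "
                f"{self.onset} / {self.peak_velocity_time} / {self.offset}"
            )

    @property
    def direction(self) -> str:
        return "extension" if self.peak_velocity >= 0 else "flexion"

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class MovementTrial:
    """One segmented movement: per-muscle EMG padded by ``pad`` seconds on each
    side, together with the angle/velocity segments and the movement bounds."""

    emg: dict[str, TimeSeries]
    angle: TimeSeries
    velocity: TimeSeries
    bounds: MovementBounds
    pad: float = 3.0

    @property
    def fs_emg(self) -> float:
        return next(iter(self.emg.values())).fs

    def _emg_index(self, t: float) -> int:
        return next(iter(self.emg.values())).index_of(t)

    @property
    def onset_index(self) -> int:
        """Movement onset on the EMG clock (index into the padded segment)."""
        return self._emg_index(self.bounds.onset)

    @property
    def offset_index(self) -> int:
        return self._emg_index(self.bounds.offset)

    @property
    def peak_index(self) -> int:
        return self._emg_index(self.bounds.peak_velocity_time)

    def emg_movement(self, muscle: str) -> np.ndarray:
        """EMG samples of ``muscle`` over [onset, offset]."""
        return self.emg[muscle].samples[self.onset_index : self.offset_index + 1]


@dataclass
class Recording:
    """Synchronized multichannel EMG + elbow angle for one limb/session."""

    subject: str
    group: str
    limb: str
    emg: dict[str, TimeSeries]
    angle: TimeSeries
    age: float = float("nan")

    def __post_init__(self) -> None:
        missing = [ch for ch in EMG_CHANNELS if ch not in self.emg]
        if missing:
            raise ValueError(f"recording is missing EMG channels: {missing}")

    @property
    def fs_emg(self) -> float:
        return self.emg["TB"].fs

    @property
    def fs_kin(self) -> float:
        return self.angle.fs


@dataclass
class MVCTrial:
    """One maximal-voluntary-contraction trial: flexor EMG plus elbow torque."""

    emg: dict[str, TimeSeries]
    torque: TimeSeries
    trial_id: int = 0
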