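"""Core data containers shared across the pipeline.

These are thin, validated wrappers around numpy arrays: a wrist-speed
trace, a detected movement window, a raw multi-channel EMG trial, and the
muscles x pooled-samples phasic activation matrix that is the unit of
synergy extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class VelocityTrace:
    """Wrist-marker speed sampled at ``kin_rate`` Hz (non-negative)."""

    speed: np.ndarray
    kin_rate: float

    def __post_init__(self) -> None:
        self.speed = np.asarray(self.speed, dtype=float)
        if self.speed.ndim != 1:
            raise ValueError("speed must be a 1-D series")
        if self.kin_rate <= 0:
            raise ValueError("kin_rate must be positive")
        if np.any(self.speed < 0):
            raise ValueError("speed must be non-negative")

    @property
    def duration(self) -> float:
        return self.speed.size / self.kin_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.speed.size) / self.kin_rate


@dataclass(frozen=True)
class PhaseWindow:
    """One forward movement phase: kinematic onset/offset in seconds."""

    onset: float
    offset: float
    task_index: int

    def __post_init__(self) -> None:
        if not self.onset < self.offset:
            raise ValueError(f"onset ({self.onset}) must precede offset ({self.offset})")
        if self.task_index < 0:
            raise ValueError("task_index must be >= 0")


@dataclass
class RawTrial:
    """Raw EMG (channels x samples, ``emg_rate`` Hz) plus the wrist speed trace."""

    emg: np.ndarray
    channel_names: list[str]
    emg_rate: float
    velocity: VelocityTrace
    subject_id: int = 0
    repetition_id: int = 0

    def __post_init__(self) -> None:
        self.emg = np.asarray(self.emg, dtype=float)
        if self.emg.ndim != 2:
            raise ValueError("emg must be channels x samples")
        if len(self.channel_names) != self.emg.shape[0]:
            raise ValueError("channel_names length must match EMG channel count")
        if self.emg_rate <= 0:
            raise ValueError("emg_rate must be positive")
        # EMG and kinematics must cover the same span (within one kinematic sample)
        if abs(self.emg.shape[1] / self.emg_rate - self.velocity.duration) > 1.0 / self.velocity.kin_rate + 1e-9:
            raise ValueError("EMG and velocity traces cover different time spans")

    @property
    def n_channels(self) -> int:
        return self.emg.shape[0]


@dataclass
class PhasicMatrix:
    """Non-negative phasic activation matrix M (muscles x pooled samples).

    Column count is samples-per-phase x number of tasks (16 x 900 with the
    default design); values are max-normalized per channel across all
    repetitions of a subject, so entries live in [0, 1].
    """

    values: np.ndarray
    subject_id: int
    repetition_id: int
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be muscles x samples")
        if np.any(self.values < 0):
            raise ValueError("phasic matrix must be non-negative")
        if self.channel_names and len(self.channel_names) != self.values.shape[0]:
            raise ValueError("channel_names length must match row count")

    @property
    def n_muscles(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]
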