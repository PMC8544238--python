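"""Cohort design parameters for the synthetic reaching-task generator.

The defaults mirror the experimental design the pipeline targets: 12
subjects, 10 repetitions of a trial of 9 point-to-point reaching tasks in
the frontal plane, 16 surface-EMG channels sampled at 1000 Hz with wrist
kinematics at 100 Hz, and each forward phase resampled to 100 points
(so a pooled phasic matrix is 16 x 900).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

#: The 16 recorded muscles (trunk, shoulder girdle, upper arm, forearm).
MUSCLES_16 = [
    "ES", "TeresMa", "Inf", "TrapL", "TrapM", "TrapU", "DeltA", "DeltM",
    "DeltP", "Pect", "TriLong", "TriLat", "BicLong", "BicShort", "Bra", "ProT",
]

#: Upper edge of the surface-EMG carrier band used by the raw synthesizer (Hz).
CARRIER_BAND = (20.0, 450.0)


@dataclass(frozen=True)
class CohortConfig:
    """Everything that defines a synthetic cohort, apart from the seed-derived draws.

    Parameters
    ----------
    n_subjects, n_repetitions, n_tasks, n_muscles
        Cohort design counts. ``n_tasks`` reaching directions are spread
        evenly on the circle.
    n_true_synergies
        Number of planted synergy vectors (the ground-truth model order).
    samples_per_point
        Samples per resampled forward phase (100 -> 900 pooled columns).
    emg_rate, kin_rate
        Sampling rates in Hz for EMG and kinematics.
    phase_duration, pause_duration
        Seconds per forward phase and per between-phase pause.
    sigma_intra
        SD of the multiplicative repetition-to-repetition jitter applied to
        each subject's synergy weights (unitless).
    sigma_inter
        SD of the additive subject-level perturbation of the template
        synergies (unitless). Must exceed ``sigma_intra`` for the cohort to
        embody the within-subject < between-subject structure.
    sigma_noise
        Envelope noise SD, relative to the RMS of the clean envelope.
    tonic_level
        Tonic (antigravity) baseline as a fraction of the mean phasic
        amplitude per channel.
    similarity_cap
        Maximum allowed pairwise cosine similarity between template
        synergies, so that matching is identifiable.
    seed
        Root seed; all subject/repetition streams are derived from it.
    """

    n_subjects: int = 12
    n_repetitions: int = 10
    n_tasks: int = 9
    n_muscles: int = 16
    n_true_synergies: int = 4
    samples_per_point: int = 100
    emg_rate: float = 1000.0
    kin_rate: float = 100.0
    phase_duration: float = 1.0
    pause_duration: float = 1.0
    sigma_intra: float = 0.05
    sigma_inter: float = 0.3
    sigma_noise: float = 0.05
    tonic_level: float = 0.2
    similarity_cap: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_repetitions", "n_tasks", "n_muscles",
                     "n_true_synergies", "samples_per_point"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("sigma_intra", "sigma_inter", "sigma_noise", "tonic_level"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("emg_rate", "kin_rate", "phase_duration", "pause_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_true_synergies > self.n_muscles:
            raise ValueError("n_true_synergies cannot exceed n_muscles")
        if not 0 < self.similarity_cap <= 1:
            raise ValueError("similarity_cap must be in (0, 1]")

    @property
    def channel_names(self) -> list[str]:
        if self.n_muscles == len(MUSCLES_16):
            return list(MUSCLES_16)
        return [f"M{i + 1:02d}" for i in range(self.n_muscles)]

    @property
    def pooled_samples(self) -> int:
        return self.samples_per_point * self.n_tasks

    def with_(self, **kwargs: Any) -> "CohortConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


# Fixed stream identifiers for the counter-based seed expansion: every
# random draw in the generator uses SeedSequence([seed, STREAM, subject,
# repetition, ...]) so regenerating any single trial is reproducible.
STREAM_TEMPLATE = 0
STREAM_SUBJECT = 1
STREAM_REPETITION = 2
STREAM_ENVELOPE_NOISE = 3
STREAM_CARRIER = 4


def child_rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic child generator for a (stream, subject, repetition, ...) key."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def child_seed(seed: int, *key: int) -> int:
    """A derived integer seed (< 2**31) for APIs that take a plain seed."""
    return int(np.random.SeedSequence([int(seed), *map(int, key)]).generate_state(1)[0] % (2 ** 31))
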