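"""Synthetic multi-subject reaching cohorts with known planted synergies.

The generator emulates the study design the pipeline analyzes: each
subject's phasic muscle activity is a non-negative linear combination
``M = W C`` of a small set of time-invariant synergy vectors (columns of
``W``) with direction-tuned, bell-shaped activation time courses (rows of
``C``), plus envelope noise. Subject-level synergies perturb a shared
template (inter-subject variability) and repetition-level synergies jitter
the subject's (intra-subject variability), so the planted structure has
within-subject similarity above between-subject similarity by construction.

Two levels of realism are offered:

* envelope level — directly the pooled muscles x samples phasic matrices
  (what preprocessing would output), via :func:`synthesize_envelopes`;
* raw level — amplitude-modulated broadband EMG plus a tonic baseline and
  a wrist-speed trace, via :func:`synthesize_raw_trial`, for exercising
  the full filtering/segmentation front end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .config import (
    CARRIER_BAND,
    STREAM_CARRIER,
    STREAM_ENVELOPE_NOISE,
    STREAM_REPETITION,
    STREAM_SUBJECT,
    STREAM_TEMPLATE,
    CohortConfig,
    child_rng,
)
from .containers import PhasicMatrix, PhaseWindow, RawTrial, VelocityTrace

__all__ = [
    "ActivationParams",
    "GroundTruthModel",
    "EnvelopeSet",
    "make_ground_truth",
    "make_activation_profiles",
    "synthesize_envelopes",
    "synthesize_velocity",
    "synthesize_raw_trial",
]


@dataclass(frozen=True)
class ActivationParams:
    """Per-synergy tuning: preferred direction, bump center/width (phase fraction), gain."""

    theta: np.ndarray
    center: np.ndarray
    width: np.ndarray
    gain: np.ndarray


@dataclass
class GroundTruthModel:
    """Planted synergies at every level of the perturbation chain.

    ``template_W`` (muscles x N) is the cohort template; ``subject_W[s]``
    is the template plus an additive Normal(0, sigma_inter) perturbation,
    rectified and re-normalized; ``repetition_W[s, r]`` is the subject
    matrix with multiplicative Normal(0, sigma_intra) jitter, rectified
    and re-normalized. All synergy columns are non-negative unit vectors.
    """

    template_W: np.ndarray
    subject_W: np.ndarray
    repetition_W: np.ndarray
    activation_params: ActivationParams
    seed: int

    def __post_init__(self) -> None:
        for arr in (self.template_W, self.subject_W, self.repetition_W):
            if np.any(arr < 0):
                raise ValueError("synergy matrices must be non-negative")
        norms = np.linalg.norm(self.repetition_W, axis=-2)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("synergy columns must have unit Euclidean norm")

    @property
    def n_true_synergies(self) -> int:
        return self.template_W.shape[1]


def _unit_columns(W: np.ndarray, fallback: np.ndarray | None = None) -> np.ndarray:
    norms = np.linalg.norm(W, axis=0)
    out = W.copy()
    for j, nj in enumerate(norms):
        if nj > 0:
            out[:, j] /= nj
        elif fallback is not None:
            out[:, j] = fallback[:, j]
        else:
            raise ValueError("degenerate all-zero synergy column")
    return out


def _draw_template(rng: np.random.Generator, m: int, n: int) -> np.ndarray:
    """One candidate template: sparse non-negative unit columns.

    Muscles are dealt round-robin across synergies so every recorded
    channel participates in at least one synergy (no dead channels), each
    synergy keeps one private anchor muscle no other synergy recruits, and
    the remaining slots are topped up with shared muscles — most muscles
    therefore contribute to more than one synergy, as real upper-limb
    muscles do. Anchors plus compact activation bursts make the planted
    factorization identifiable.
    """
    n_active = max(3, m // 2)  # ~8 of 16 muscles carry each synergy
    perm = rng.permutation(m)
    supports = [list(perm[j::n]) for j in range(n)]
    anchors = {supports[j][0] for j in range(n)}
    W = np.zeros((m, n))
    for j in range(n):
        shareable = [i for i in perm if i not in supports[j] and i not in anchors]
        extra = max(0, n_active - len(supports[j]))
        sup = supports[j] + shareable[:extra]
        W[sup, j] = rng.uniform(0.2, 1.0, size=len(sup))
    return _unit_columns(W)


def make_ground_truth(config: CohortConfig, max_redraws: int = 200) -> GroundTruthModel:
    """Draw the planted synergy chain (template -> subjects -> repetitions).

    Template columns are redrawn until every pairwise cosine similarity is
    below ``config.similarity_cap`` so that downstream matching is
    identifiable; a cap that cannot be met within ``max_redraws`` raises.
    """
    m, n = config.n_muscles, config.n_true_synergies
    rng = child_rng(config.seed, STREAM_TEMPLATE)

    template = None
    for _ in range(max_redraws):
        cand = _draw_template(rng, m, n)
        gram = cand.T @ cand
        off = gram[~np.eye(n, dtype=bool)]
        if off.size == 0 or np.max(off) < config.similarity_cap:
            template = cand
            break
    if template is None:
        raise ValueError(
            f"could not draw {n} synergies with pairwise cosine similarity "
            f"below the cap {config.similarity_cap} in {max_redraws} attempts"
        )

    # Subject perturbation is additive Gaussian on the template's active
    # muscles only (rectified, re-normalized): subjects share which muscles a
    # synergy recruits but differ in the weighting. Perturbing the silent
    # muscles too would make every synergy dense in all channels, which
    # destroys the identifiability of the planted factorization. Recruited
    # weights are floored at 40% of the muscle's template weight: a subject
    # modulates a muscle's participation but does not abolish it, so no
    # recorded channel ends up with a near-zero maximum that would amplify
    # envelope noise unboundedly under per-channel max normalization. (The
    # relative floor leaves the zero-perturbation limit an exact identity.)
    support = template > 0
    floor = 0.4 * template
    subject_W = np.empty((config.n_subjects, m, n))
    for s in range(config.n_subjects):
        delta = child_rng(config.seed, STREAM_SUBJECT, s).normal(0.0, config.sigma_inter, (m, n))
        perturbed = np.maximum(np.abs(template + delta * support), floor)
        subject_W[s] = _unit_columns(perturbed * support, fallback=template)

    repetition_W = np.empty((config.n_subjects, config.n_repetitions, m, n))
    for s in range(config.n_subjects):
        for r in range(config.n_repetitions):
            eps = child_rng(config.seed, STREAM_REPETITION, s, r).normal(0.0, config.sigma_intra, (m, n))
            jittered = np.clip(subject_W[s] * (1.0 + eps), 0.0, None)
            repetition_W[s, r] = _unit_columns(jittered, fallback=subject_W[s])

    # Preferred directions spread evenly on the circle; burst centers
    # staggered through the phase with widths small enough that the
    # truncated bursts have disjoint time supports (see
    # make_activation_profiles), so each synergy owns a stretch of every
    # task it is recruited in and the planted factorization is identifiable.
    theta = 2.0 * np.pi * np.arange(n) / n
    if n > 1:
        center = np.linspace(0.15, 0.85, n)
        width = min(0.05, 0.2 * (0.85 - 0.15) / (n - 1))
    else:
        center = np.array([0.5])
        width = 0.05
    params = ActivationParams(
        theta=theta,
        center=np.asarray(center, dtype=float),
        width=np.full(n, width),
        gain=np.ones(n),
    )
    return GroundTruthModel(
        template_W=template,
        subject_W=subject_W,
        repetition_W=repetition_W,
        activation_params=params,
        seed=config.seed,
    )


def task_directions(config: CohortConfig) -> np.ndarray:
    """Reaching directions (rad), spread evenly on the circle."""
    return 2.0 * np.pi * np.arange(config.n_tasks) / config.n_tasks


def make_activation_profiles(truth: GroundTruthModel, config: CohortConfig) -> np.ndarray:
    """Direction-tuned activation time courses, shape (n_tasks, N, samples_per_point).

    For task direction ``theta_d`` and synergy ``k`` the coefficient is a
    rectified-cosine tuning gain times a Gaussian burst in normalized phase
    time: ``c_k(t) = gain_k * max(0, cos(theta_d - theta_k)) *
    exp(-(t - center_k)^2 / (2 width_k^2))``, truncated to zero beyond 2.4
    widths from the center so bursts of different synergies have disjoint
    time supports. If a direction leaves every synergy silent (possible for
    very small N), the best-aligned synergy is activated at 10% gain so
    that each task recruits at least one synergy.
    """
    p = truth.activation_params
    n = truth.n_true_synergies
    t = (np.arange(config.samples_per_point) + 0.5) / config.samples_per_point
    dist = np.abs(t[None, :] - p.center[:, None])
    bumps = np.exp(-(dist ** 2) / (2.0 * p.width[:, None] ** 2))
    bumps[dist > 2.4 * p.width[:, None]] = 0.0

    profiles = np.zeros((config.n_tasks, n, config.samples_per_point))
    for d, theta_d in enumerate(task_directions(config)):
        tuning = np.maximum(0.0, np.cos(theta_d - p.theta)) * p.gain
        if np.all(tuning <= 0):
            k = int(np.argmax(np.cos(theta_d - p.theta)))
            tuning = np.zeros(n)
            tuning[k] = 0.1 * p.gain[k]
        profiles[d] = tuning[:, None] * bumps
    return profiles


def pooled_activations(truth: GroundTruthModel, config: CohortConfig) -> np.ndarray:
    """Activation profiles concatenated across tasks: (N, samples_per_point * n_tasks)."""
    profiles = make_activation_profiles(truth, config)
    return np.concatenate([profiles[d] for d in range(config.n_tasks)], axis=1)


@dataclass
class EnvelopeSet:
    """Envelope-level cohort: noisy and clean pooled matrices plus labels."""

    config: CohortConfig
    truth: GroundTruthModel
    envelopes: np.ndarray  # (S, R, m, samples_per_point * n_tasks)
    clean: np.ndarray      # same shape, noise-free W C
    activations: np.ndarray  # (N, samples_per_point * n_tasks), shared C

    def channel_scale(self, subject: int) -> np.ndarray:
        """Per-channel max over all the subject's repetitions (the normalizer)."""
        denom = self.envelopes[subject].max(axis=(0, 2))
        return np.where(denom > 0, denom, 1.0)

    def planted_W(self, subject: int, repetition: int, normalized: bool = True) -> np.ndarray:
        """Planted synergies in the coordinates of :meth:`phasic_matrices`.

        Per-channel max normalization rescales the rows of M, so the
        synergies that generate the *normalized* matrix are the planted
        ones divided by the channel scale (columns re-normalized to unit
        length). Recovered synergies should be compared against these.
        """
        W = self.truth.repetition_W[subject, repetition]
        if not normalized:
            return W
        Wn = W / self.channel_scale(subject)[:, None]
        return Wn / np.linalg.norm(Wn, axis=0)

    def phasic_matrices(self, normalize: bool = True) -> dict[tuple[int, int], PhasicMatrix]:
        """Per-(subject, repetition) matrices, max-normalized per channel per subject."""
        names = self.config.channel_names
        out: dict[tuple[int, int], PhasicMatrix] = {}
        for s in range(self.config.n_subjects):
            block = self.envelopes[s]
            if normalize:
                denom = block.max(axis=(0, 2))
                denom = np.where(denom > 0, denom, 1.0)
                block = block / denom[None, :, None]
            for r in range(self.config.n_repetitions):
                out[(s, r)] = PhasicMatrix(block[r], subject_id=s, repetition_id=r,
                                           channel_names=names)
        return out


def _repetition_envelope(truth: GroundTruthModel, config: CohortConfig,
                         C: np.ndarray, s: int, r: int) -> tuple[np.ndarray, np.ndarray]:
    """(noisy, clean) pooled envelope for one subject/repetition."""
    clean = truth.repetition_W[s, r] @ C
    if config.sigma_noise > 0:
        rms = np.sqrt(np.mean(clean ** 2))
        noise = np.abs(child_rng(config.seed, STREAM_ENVELOPE_NOISE, s, r)
                       .normal(0.0, config.sigma_noise * rms, clean.shape))
    else:
        noise = 0.0
    return np.clip(clean + noise, 0.0, None), clean


def synthesize_envelopes(truth: GroundTruthModel, config: CohortConfig) -> EnvelopeSet:
    """Generate the full envelope-level cohort.

    Each repetition is ``M = W_rep C + noise`` with half-Normal envelope
    noise scaled by ``sigma_noise`` times the clean-signal RMS, clipped at
    zero, pooled across tasks to muscles x (samples_per_point * n_tasks).
    """
    C = pooled_activations(truth, config)
    S, R = config.n_subjects, config.n_repetitions
    m, T = config.n_muscles, config.pooled_samples
    env = np.empty((S, R, m, T))
    clean = np.empty((S, R, m, T))
    for s in range(S):
        for r in range(R):
            env[s, r], clean[s, r] = _repetition_envelope(truth, config, C, s, r)
    return EnvelopeSet(config=config, truth=truth, envelopes=env, clean=clean, activations=C)


def _min_jerk_speed(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk speed profile on tau in [0, 1], normalized to unit peak."""
    return 30.0 * tau ** 2 * (1.0 - tau) ** 2 / 1.875


def trial_timeline(config: CohortConfig) -> tuple[float, list[PhaseWindow]]:
    """Total trial duration and the true forward-phase windows.

    The trial is a leading pause, then ``n_tasks`` repetitions of
    (forward phase, pause).
    """
    windows = []
    t = config.pause_duration
    for d in range(config.n_tasks):
        windows.append(PhaseWindow(onset=t, offset=t + config.phase_duration, task_index=d))
        t += config.phase_duration + config.pause_duration
    return t, windows


def synthesize_velocity(config: CohortConfig) -> tuple[VelocityTrace, list[PhaseWindow]]:
    """Wrist-speed trace: one minimum-jerk bell per forward phase, zero in pauses.

    Returns the trace and the ground-truth phase windows.
    """
    total, windows = trial_timeline(config)
    n = int(round(total * config.kin_rate))
    t = np.arange(n) / config.kin_rate
    speed = np.zeros(n)
    for w in windows:
        mask = (t >= w.onset) & (t < w.offset)
        tau = (t[mask] - w.onset) / (w.offset - w.onset)
        speed[mask] = _min_jerk_speed(tau)
    return VelocityTrace(speed=speed, kin_rate=config.kin_rate), windows


def _carrier(rng: np.random.Generator, shape: tuple[int, int], fs: float) -> np.ndarray:
    """Zero-mean band-limited Gaussian carrier (20-450 Hz), unit RMS per channel."""
    lo, hi = CARRIER_BAND
    white = rng.standard_normal(shape)
    sos = signal.butter(4, [lo, min(hi, 0.49 * fs)], btype="bandpass", fs=fs, output="sos")
    band = signal.sosfiltfilt(sos, white, axis=-1)
    rms = np.sqrt(np.mean(band ** 2, axis=-1, keepdims=True))
    return band / np.where(rms > 0, rms, 1.0)


def synthesize_raw_trial(truth: GroundTruthModel, config: CohortConfig,
                         subject: int, repetition: int,
                         return_envelope: bool = False):
    """Raw-EMG trial for one subject/repetition, consistent with the envelope level.

    The repetition's phasic envelope (including its envelope noise stream,
    so the raw and envelope levels describe the same data) is placed on the
    trial timeline, a constant tonic baseline of ``tonic_level`` times the
    mean phasic amplitude per channel is added, and the sum modulates a
    zero-mean broadband carrier spanning the surface-EMG band.
    """
    if config.emg_rate < 2.0 * CARRIER_BAND[1]:
        raise ValueError(
            f"emg_rate {config.emg_rate} Hz cannot carry the {CARRIER_BAND[1]} Hz EMG band"
        )
    C = pooled_activations(truth, config)
    env_pooled, _ = _repetition_envelope(truth, config, C, subject, repetition)

    total, windows = trial_timeline(config)
    n_emg = int(round(total * config.emg_rate))
    t = np.arange(n_emg) / config.emg_rate
    m, P = config.n_muscles, config.samples_per_point

    env_trial = np.zeros((m, n_emg))
    for w in windows:
        mask = (t >= w.onset) & (t < w.offset)
        tau = (t[mask] - w.onset) / (w.offset - w.onset)
        src = env_pooled[:, w.task_index * P:(w.task_index + 1) * P]
        grid = (np.arange(P) + 0.5) / P
        for ch in range(m):
            env_trial[ch, mask] = np.interp(tau, grid, src[ch])

    tonic = config.tonic_level * env_pooled.mean(axis=1)
    carrier = _carrier(child_rng(config.seed, STREAM_CARRIER, subject, repetition),
                       (m, n_emg), config.emg_rate)
    raw = (env_trial + tonic[:, None]) * carrier

    velocity, _ = synthesize_velocity(config)
    trial = RawTrial(emg=raw, channel_names=config.channel_names, emg_rate=config.emg_rate,
                     velocity=velocity, subject_id=subject, repetition_id=repetition)
    if return_envelope:
        return trial, env_trial + tonic[:, None]
    return trial
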