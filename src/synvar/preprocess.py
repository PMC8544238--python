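"""Raw EMG + wrist velocity -> per-repetition phasic activation matrices.

The front end of the pipeline: smooth the wrist-speed trace and segment
the forward movement phases from it, band-filter and rectify the EMG to an
envelope, strip the tonic (antigravity) component inside each phase
window, resample every phase to a fixed number of points, max-normalize
per channel across all of a subject's repetitions, and pool tasks into
the muscles x (points x tasks) phasic matrix that synergy extraction
consumes.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .containers import PhasicMatrix, PhaseWindow, RawTrial, VelocityTrace

__all__ = [
    "smooth_velocity",
    "segment_phases",
    "filter_envelope",
    "remove_tonic",
    "resample_phase",
    "normalize_and_pool",
    "preprocess_trial",
    "preprocess_cohort",
]

log = logging.getLogger(__name__)

HP_CUTOFF_HZ = 50.0   # artifact removal
LP_CUTOFF_HZ = 10.0   # envelope extraction
FILTER_ORDER = 7      # Butterworth order of each stage (applied zero-phase)


def smooth_velocity(v: VelocityTrace, window_s: float = 0.2) -> VelocityTrace:
    """Centered moving-average smoothing with edge truncation.

    The window shrinks near the boundaries (the average is taken over the
    available samples), so the output has the input's length. A 0.2 s
    window at 100 Hz spans 21 samples (the window is forced odd so it can
    be centered).
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    w = int(round(window_s * v.kin_rate))
    if w % 2 == 0:
        w += 1
    if w > v.speed.size:
        raise ValueError(f"smoothing window ({w} samples) longer than trace ({v.speed.size})")
    kernel = np.ones(w)
    summed = np.convolve(v.speed, kernel, mode="same")
    counts = np.convolve(np.ones_like(v.speed), kernel, mode="same")
    return VelocityTrace(speed=summed / counts, kin_rate=v.kin_rate)


def segment_phases(v: VelocityTrace, n_tasks: int, threshold_frac: float = 0.05,
                   min_separation_s: float = 0.5) -> list[PhaseWindow]:
    """Detect the onsets/offsets of the ``n_tasks`` forward phases.

    The ``n_tasks`` largest speed peaks separated by at least
    ``min_separation_s`` are located; each phase onset (offset) is the
    last (first) crossing below ``threshold_frac`` of that peak's height
    before (after) the peak.
    """
    if n_tasks < 1:
        raise ValueError("n_tasks must be >= 1")
    speed = v.speed
    distance = max(1, int(round(min_separation_s * v.kin_rate)))
    peaks, props = signal.find_peaks(speed, distance=distance, height=np.max(speed) * 1e-6 if np.max(speed) > 0 else 1e-12)
    if len(peaks) < n_tasks:
        raise ValueError(f"{len(peaks)} peaks found in the velocity trace, need {n_tasks}")
    order = np.argsort(props["peak_heights"])[::-1][:n_tasks]
    chosen = np.sort(peaks[order])

    windows: list[PhaseWindow] = []
    for task, pk in enumerate(chosen):
        thr = threshold_frac * speed[pk]
        below_before = np.flatnonzero(speed[:pk] < thr)
        onset_idx = below_before[-1] if below_before.size else 0
        after = np.flatnonzero(speed[pk:] < thr)
        offset_idx = pk + after[0] if after.size else speed.size - 1
        windows.append(PhaseWindow(onset=onset_idx / v.kin_rate,
                                   offset=offset_idx / v.kin_rate,
                                   task_index=task))
    for a, b in zip(windows, windows[1:]):
        if a.offset > b.onset:
            raise ValueError("detected phase windows overlap; check the velocity trace")
    return windows


def filter_envelope(trial: RawTrial) -> np.ndarray:
    """EMG envelope: 50 Hz high-pass, full-wave rectification, 10 Hz low-pass.

    Both Butterworth stages are 7th order and applied forward-backward
    (zero phase), so the envelope is not delayed relative to the
    kinematics; the effective attenuation is that of a squared 7th-order
    response. Small negative excursions from the low-pass stage are left
    in place — clipping happens after tonic removal.
    """
    if trial.emg_rate <= 2 * HP_CUTOFF_HZ:
        raise ValueError(f"emg_rate {trial.emg_rate} Hz too low for a {HP_CUTOFF_HZ} Hz high-pass")
    sos_hp = signal.butter(FILTER_ORDER, HP_CUTOFF_HZ, btype="highpass", fs=trial.emg_rate, output="sos")
    sos_lp = signal.butter(FILTER_ORDER, LP_CUTOFF_HZ, btype="lowpass", fs=trial.emg_rate, output="sos")
    hp = signal.sosfiltfilt(sos_hp, trial.emg, axis=-1)
    return signal.sosfiltfilt(sos_lp, np.abs(hp), axis=-1)


def remove_tonic(envelope: np.ndarray, window: PhaseWindow, emg_rate: float,
                 emd_pad_s: float = 0.2) -> np.ndarray:
    """Phasic segment of one phase: envelope minus a linear tonic ramp, clipped at 0.

    The segment spans (onset - pad, offset + pad) — the padding absorbs the
    electromechanical delay between EMG and movement onset. The tonic
    estimate per channel is a linear ramp between the mean envelope in the
    pad before the onset and the mean in the pad after the offset; negative
    residuals are set to zero.
    """
    n = envelope.shape[-1]
    i0 = int(round((window.onset - emd_pad_s) * emg_rate))
    i1 = int(round((window.offset + emd_pad_s) * emg_rate))
    on = int(round(window.onset * emg_rate))
    off = int(round(window.offset * emg_rate))
    if i0 < 0 or i1 > n:
        raise ValueError("EMD padding extends beyond the recording")
    pre = envelope[:, i0:on].mean(axis=-1)
    post = envelope[:, off:i1].mean(axis=-1)
    seg = envelope[:, i0:i1]
    ramp = np.linspace(0.0, 1.0, seg.shape[-1])
    tonic = pre[:, None] + (post - pre)[:, None] * ramp[None, :]
    return np.clip(seg - tonic, 0.0, None)


def resample_phase(segment: np.ndarray, n_points: int = 100) -> np.ndarray:
    """Linear resampling of a phase segment onto ``n_points`` per channel.

    Endpoints are preserved exactly (the new grid spans the full segment).
    """
    seg = np.atleast_2d(np.asarray(segment, dtype=float))
    if seg.shape[-1] < 2:
        raise ValueError("segment must have at least 2 samples")
    src = np.linspace(0.0, 1.0, seg.shape[-1])
    dst = np.linspace(0.0, 1.0, n_points)
    return np.stack([np.interp(dst, src, seg[ch]) for ch in range(seg.shape[0])])


def normalize_and_pool(per_rep_task_matrices: Sequence[Sequence[np.ndarray]],
                       subject_id: int = 0,
                       channel_names: Sequence[str] | None = None) -> list[PhasicMatrix]:
    """Max-normalize per channel across a subject's repetitions, pool tasks.

    ``per_rep_task_matrices[r][d]`` is the resampled phasic matrix of
    repetition ``r``, task ``d`` (channels x points). The divisor per
    channel is the maximum over all tasks and repetitions of the subject
    (this is what makes subjects comparable); all-zero channels are left
    at zero with a warning. Each repetition's tasks are then concatenated
    column-wise in task order.
    """
    if not per_rep_task_matrices:
        raise ValueError("no repetitions given")
    m = per_rep_task_matrices[0][0].shape[0]
    for rep in per_rep_task_matrices:
        for mat in rep:
            if mat.shape[0] != m:
                raise ValueError("inconsistent channel counts across matrices")
    denom = np.zeros(m)
    for rep in per_rep_task_matrices:
        for mat in rep:
            denom = np.maximum(denom, mat.max(axis=-1))
    dead = denom == 0
    if np.any(dead):
        log.warning("channel(s) %s are all-zero for subject %s; left at zero",
                    np.flatnonzero(dead).tolist(), subject_id)
    safe = np.where(dead, 1.0, denom)

    names = list(channel_names) if channel_names is not None else []
    out = []
    for r, rep in enumerate(per_rep_task_matrices):
        pooled = np.concatenate([mat / safe[:, None] for mat in rep], axis=-1)
        out.append(PhasicMatrix(pooled, subject_id=subject_id, repetition_id=r,
                                channel_names=names))
    return out


def preprocess_trial(trial: RawTrial, n_tasks: int, n_points: int = 100,
                     smooth_window_s: float = 0.2, threshold_frac: float = 0.05,
                     emd_pad_s: float = 0.2,
                     min_separation_s: float = 0.5) -> list[np.ndarray]:
    """One trial -> per-task resampled phasic matrices (not yet normalized).

    Runs the full chain: velocity smoothing, phase segmentation, envelope
    filtering, tonic removal per phase, and resampling. Only the forward
    phases found in the velocity trace are processed.
    """
    smoothed = smooth_velocity(trial.velocity, window_s=smooth_window_s)
    windows = segment_phases(smoothed, n_tasks, threshold_frac=threshold_frac,
                             min_separation_s=min_separation_s)
    envelope = filter_envelope(trial)
    out = []
    for w in windows:
        phasic = remove_tonic(envelope, w, trial.emg_rate, emd_pad_s=emd_pad_s)
        out.append(resample_phase(phasic, n_points=n_points))
    return out


def preprocess_cohort(trials: Mapping[tuple[int, int], RawTrial], n_tasks: int,
                      n_points: int = 100, **kwargs) -> dict[tuple[int, int], PhasicMatrix]:
    """Preprocess all trials of a cohort, normalizing within each subject.

    ``trials`` maps (subject, repetition) to a :class:`RawTrial`; the
    result maps the same keys to pooled, normalized phasic matrices.
    """
    by_subject: dict[int, list[tuple[int, RawTrial]]] = {}
    for (s, r), trial in sorted(trials.items()):
        by_subject.setdefault(s, []).append((r, trial))
    out: dict[tuple[int, int], PhasicMatrix] = {}
    for s, reps in by_subject.items():
        task_mats = [preprocess_trial(trial, n_tasks, n_points=n_points, **kwargs)
                     for _, trial in reps]
        names = reps[0][1].channel_names
        pooled = normalize_and_pool(task_mats, subject_id=s, channel_names=names)
        for (r, _), pm in zip(reps, pooled):
            pm.repetition_id = r
            out[(s, r)] = pm
    return out
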