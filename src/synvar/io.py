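"""Plain-text persistence for simulated cohorts and analysis outputs.

Layout written by :func:`save_raw_cohort` (one directory per subject and
repetition, CSV matrices with named muscle rows):

    <out>/ground_truth.json
    <out>/S01/R01/emg.csv         # rows = muscles, columns = samples
    <out>/S01/R01/velocity.csv
    ...
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .config import CohortConfig
from .containers import PhasicMatrix, RawTrial, VelocityTrace
from .simulate import GroundTruthModel, make_ground_truth, synthesize_raw_trial

__all__ = ["save_raw_cohort", "load_raw_trial", "load_raw_cohort",
           "save_phasic_matrices", "load_phasic_matrices"]


def _truth_to_json(truth: GroundTruthModel) -> dict:
    p = truth.activation_params
    return {
        "seed": truth.seed,
        "template_W": truth.template_W.tolist(),
        "subject_W": truth.subject_W.tolist(),
        "repetition_W": truth.repetition_W.tolist(),
        "activation_params": {
            "theta": p.theta.tolist(), "center": p.center.tolist(),
            "width": p.width.tolist(), "gain": p.gain.tolist(),
        },
    }


def save_raw_cohort(out_dir: str | Path, config: CohortConfig,
                    truth: GroundTruthModel | None = None) -> Path:
    """Simulate and write a raw-signal cohort in the CSV layout above."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if truth is None:
        truth = make_ground_truth(config)
    (out / "ground_truth.json").write_text(json.dumps(_truth_to_json(truth)))
    (out / "config.json").write_text(json.dumps(config.__dict__))
    for s in range(config.n_subjects):
        for r in range(config.n_repetitions):
            trial = synthesize_raw_trial(truth, config, s, r)
            d = out / f"S{s + 1:02d}" / f"R{r + 1:02d}"
            d.mkdir(parents=True, exist_ok=True)
            pd.DataFrame(trial.emg, index=trial.channel_names).to_csv(d / "emg.csv",
                                                                      header=False)
            pd.DataFrame({"speed": trial.velocity.speed}).to_csv(d / "velocity.csv",
                                                                 index=False)
    return out


def load_raw_trial(trial_dir: str | Path, emg_rate: float, kin_rate: float,
                   subject_id: int = 0, repetition_id: int = 0) -> RawTrial:
    """Read one ``S*/R*`` directory back into a :class:`RawTrial`."""
    d = Path(trial_dir)
    emg_df = pd.read_csv(d / "emg.csv", header=None, index_col=0)
    speed = pd.read_csv(d / "velocity.csv")["speed"].to_numpy()
    return RawTrial(emg=emg_df.to_numpy(), channel_names=list(emg_df.index.astype(str)),
                    emg_rate=emg_rate, velocity=VelocityTrace(speed=speed, kin_rate=kin_rate),
                    subject_id=subject_id, repetition_id=repetition_id)


def load_raw_cohort(in_dir: str | Path) -> tuple[CohortConfig, dict[tuple[int, int], RawTrial]]:
    """Read a directory written by :func:`save_raw_cohort`."""
    root = Path(in_dir)
    config = CohortConfig(**json.loads((root / "config.json").read_text()))
    trials: dict[tuple[int, int], RawTrial] = {}
    for sdir in sorted(root.glob("S*")):
        s = int(sdir.name[1:]) - 1
        for rdir in sorted(sdir.glob("R*")):
            r = int(rdir.name[1:]) - 1
            trials[(s, r)] = load_raw_trial(rdir, config.emg_rate, config.kin_rate,
                                            subject_id=s, repetition_id=r)
    return config, trials


def save_phasic_matrices(out_dir: str | Path,
                         matrices: Mapping[tuple[int, int], PhasicMatrix]) -> Path:
    """Write pooled phasic matrices as ``S*/R*/phasic.csv`` (muscle-named rows)."""
    out = Path(out_dir)
    for (s, r), pm in sorted(matrices.items()):
        d = out / f"S{s + 1:02d}" / f"R{r + 1:02d}"
        d.mkdir(parents=True, exist_ok=True)
        idx = pm.channel_names or range(pm.n_muscles)
        pd.DataFrame(pm.values, index=idx).to_csv(d / "phasic.csv", header=False)
    return out


def load_phasic_matrices(in_dir: str | Path) -> dict[tuple[int, int], PhasicMatrix]:
    root = Path(in_dir)
    out: dict[tuple[int, int], PhasicMatrix] = {}
    for f in sorted(root.glob("S*/R*/phasic.csv")):
        s = int(f.parent.parent.name[1:]) - 1
        r = int(f.parent.name[1:]) - 1
        df = pd.read_csv(f, header=None, index_col=0)
        out[(s, r)] = PhasicMatrix(df.to_numpy(), subject_id=s, repetition_id=r,
                                   channel_names=list(df.index.astype(str)))
    return out
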