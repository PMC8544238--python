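"""Cross-subject reconstruction: fixed synergies, NNLS coefficients, rVAF.

How well do one subject's synergies explain another subject's muscle
activations? The source synergy matrix is held fixed, the activation
coefficients are refit to the target matrix by non-negative least squares
(each time sample independently), and the reconstruction VAF
``rVAF = 1 - ||M - W C||_F^2 / ||M||_F^2`` measures the transfer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _scipy_nnls

from .containers import PhasicMatrix
from .decompose import SynergyDecomposition

__all__ = ["RvafTable", "nnls_fit", "rvaf", "cross_reconstruction"]


def _as_array(M: PhasicMatrix | np.ndarray) -> np.ndarray:
    return M.values if isinstance(M, PhasicMatrix) else np.asarray(M, dtype=float)


def nnls_fit(M: PhasicMatrix | np.ndarray, W_fixed: np.ndarray) -> np.ndarray:
    """Non-negative coefficients C minimizing ``||M - W C||_F`` with W fixed.

    Each time-sample column of M is solved exactly by active-set NNLS;
    columns are independent. A rank-deficient W is allowed but warned
    about (the fit is then non-unique).
    """
    V = _as_array(M)
    W = np.asarray(W_fixed, dtype=float)
    if np.any(W < 0):
        raise ValueError("W_fixed must be non-negative")
    if V.shape[0] != W.shape[0]:
        raise ValueError(f"shape mismatch: M has {V.shape[0]} muscles, W has {W.shape[0]}")
    if np.linalg.matrix_rank(W) < W.shape[1]:
        warnings.warn("W_fixed is rank deficient; NNLS coefficients are not unique",
                      stacklevel=2)
    C = np.empty((W.shape[1], V.shape[1]))
    for t in range(V.shape[1]):
        C[:, t], _ = _scipy_nnls(W, V[:, t])
    return C


def rvaf(M: PhasicMatrix | np.ndarray, W_fixed: np.ndarray) -> float:
    """Reconstruction VAF of M under the fixed synergy matrix.

    ``1 - ||M - W C||_F^2 / ||M||_F^2`` with C from :func:`nnls_fit`.
    Can be negative for a hopeless transfer; returned unclipped because a
    negative value is informative about generalization failure.
    """
    V = _as_array(M)
    sst = float(np.sum(V ** 2))
    if sst == 0:
        raise ValueError("rVAF is undefined for an all-zero matrix")
    C = nnls_fit(V, W_fixed)
    sse = float(np.sum((V - np.asarray(W_fixed) @ C) ** 2))
    return 1.0 - sse / sst


@dataclass
class RvafTable:
    """rVAF for every (source subject, target subject/repetition) pair.

    ``values[i, j]``: reconstruction of target ``target_ids[j]`` by the
    mean synergies of source subject ``source_ids[i]``. ``diagonal``
    marks self-reconstructions (source == target subject).
    ``intra_vaf[j]`` is the target's own extraction VAF for comparison.
    """

    values: np.ndarray
    source_ids: list[int]
    target_ids: list[tuple[int, int]]
    diagonal: np.ndarray
    intra_vaf: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.values > 1 + 1e-12):
            raise ValueError("rVAF cannot exceed 1")

    def self_rvaf(self, subject: int) -> float:
        """Mean rVAF of a subject's own repetitions under its own mean synergies."""
        i = self.source_ids.index(subject)
        cols = [j for j, (s, _) in enumerate(self.target_ids) if s == subject]
        return float(np.mean(self.values[i, cols]))

    def cross_rvaf(self, subject: int) -> float:
        """Mean rVAF of a subject's repetitions under every other subject's synergies."""
        rows = [i for i, s in enumerate(self.source_ids) if s != subject]
        cols = [j for j, (s, _) in enumerate(self.target_ids) if s == subject]
        return float(np.mean(self.values[np.ix_(rows, cols)]))

    def to_dataframe(self) -> pd.DataFrame:
        cols = pd.MultiIndex.from_tuples(self.target_ids, names=["subject", "repetition"])
        return pd.DataFrame(self.values,
                            index=pd.Index(self.source_ids, name="source_subject"),
                            columns=cols)


def cross_reconstruction(mean_W: Mapping[int, np.ndarray],
                         matrices: Mapping[tuple[int, int], PhasicMatrix | np.ndarray],
                         decompositions: Mapping[tuple[int, int], SynergyDecomposition] | None = None,
                         ) -> RvafTable:
    """Full rVAF grid: every subject's mean synergies against every repetition.

    ``mean_W`` maps subject -> repetition-averaged synergy matrix (from the
    intra-subject analysis); ``matrices`` maps (subject, repetition) to the
    phasic matrices being reconstructed. When ``decompositions`` is given,
    each target's own extraction VAF is carried along for the
    intra-vs-transfer comparison.
    """
    sources = sorted(mean_W)
    targets = sorted(matrices)
    values = np.empty((len(sources), len(targets)))
    for i, s in enumerate(sources):
        for j, key in enumerate(targets):
            values[i, j] = rvaf(matrices[key], mean_W[s])
    diagonal = np.array([[s == t for (t, _) in targets] for s in sources])
    intra = None
    if decompositions is not None:
        intra = np.array([decompositions[key].vaf for key in targets])
    return RvafTable(values=values, source_ids=sources, target_ids=targets,
                     diagonal=diagonal, intra_vaf=intra)
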