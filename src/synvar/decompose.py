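"""Non-negative matrix factorization of phasic matrices and model-order selection.

The phasic matrix ``M`` (muscles x pooled samples) is modeled as a linear
combination of ``N`` time-invariant synergy vectors with non-negative
activation coefficients, ``M = W C + e``. Factors are fit by the classical
multiplicative-update rule for the squared Frobenius loss, restarted from
several random initializations to escape local minima; goodness of fit is
the variance accounted for, ``VAF = 1 - SSE/SST`` with the uncentered SST.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .config import child_seed
from .containers import PhasicMatrix

__all__ = [
    "SynergyDecomposition",
    "VafCurve",
    "CohortExtraction",
    "nmf_decompose",
    "compute_vaf",
    "vaf_curve",
    "select_model_order",
    "extract_cohort",
]

log = logging.getLogger(__name__)

_MU_EPS = 1e-12  # guards the multiplicative-update denominators


def _as_array(M: PhasicMatrix | np.ndarray) -> np.ndarray:
    if isinstance(M, PhasicMatrix):
        return M.values
    return np.asarray(M, dtype=float)


@dataclass
class SynergyDecomposition:
    """One NMF fit: synergy vectors W (unit-norm columns), coefficients C, order, VAF."""

    W: np.ndarray
    C: np.ndarray
    order: int
    vaf: float
    sse: float
    n_restarts: int
    seed: int
    subject_id: int | None = None
    repetition_id: int | None = None

    def __post_init__(self) -> None:
        if np.any(self.W < 0) or np.any(self.C < 0):
            raise ValueError("W and C must be non-negative")
        if self.W.shape[1] != self.order or self.C.shape[0] != self.order:
            raise ValueError("W/C shapes inconsistent with order")

    def reconstruction(self) -> np.ndarray:
        return self.W @ self.C


@dataclass
class VafCurve:
    """Best-of-restarts VAF per model order (contiguous from 1) and the selected order."""

    vaf_by_order: dict[int, float]
    selected_order: int

    def __post_init__(self) -> None:
        orders = sorted(self.vaf_by_order)
        if orders != list(range(1, len(orders) + 1)):
            raise ValueError("orders must be contiguous from 1")
        if any(v > 1.0 + 1e-12 for v in self.vaf_by_order.values()):
            raise ValueError("VAF cannot exceed 1")


def compute_vaf(M: PhasicMatrix | np.ndarray, W: np.ndarray, C: np.ndarray) -> float:
    """Variance accounted for: ``1 - ||M - W C||_F^2 / ||M||_F^2`` (uncentered SST)."""
    V = _as_array(M)
    sst = float(np.sum(V ** 2))
    if sst == 0:
        raise ValueError("VAF is undefined for an all-zero matrix")
    sse = float(np.sum((V - W @ C) ** 2))
    return 1.0 - sse / sst


def _mu_fit(V: np.ndarray, order: int, rng: np.random.Generator,
            tol: float, max_iter: int) -> tuple[np.ndarray, np.ndarray, float]:
    """One multiplicative-update run from a uniform(eps, 1) initialization."""
    m, T = V.shape
    W = rng.uniform(1e-6, 1.0, (m, order))
    C = rng.uniform(1e-6, 1.0, (order, T))
    sst = float(np.sum(V ** 2))
    sse_prev = None
    sse = sst
    for _ in range(max_iter):
        WtV = W.T @ V
        C *= WtV / (W.T @ W @ C + _MU_EPS)
        VCt = V @ C.T
        CCt = C @ C.T
        W *= VCt / (W @ CCt + _MU_EPS)
        # SSE via the Gram identity (no m x T reconstruction needed)
        cross = float(np.sum((W.T @ V) * C))
        sse = sst - 2.0 * cross + float(np.sum((W.T @ W) * (C @ C.T)))
        if sse_prev is not None and sse_prev - sse <= tol * max(sse_prev, _MU_EPS):
            break
        sse_prev = sse
    return W, C, max(sse, 0.0)


def nmf_decompose(M: PhasicMatrix | np.ndarray, order: int, n_restarts: int = 50,
                  seed: int = 0, tol: float = 1e-6, max_iter: int = 1000) -> SynergyDecomposition:
    """Best-of-restarts multiplicative-update NMF at a fixed order.

    Each restart initializes W and C uniform on (1e-6, 1) from a child seed,
    iterates the multiplicative updates until the relative SSE change drops
    below ``tol`` (or ``max_iter``), and the restart with the lowest SSE
    wins. Synergy columns are rescaled to unit Euclidean norm with the
    compensating scale pushed into the coefficient rows.
    """
    V = _as_array(M)
    if np.any(V < 0):
        raise ValueError("NMF input must be non-negative")
    m = V.shape[0]
    if not 1 <= order <= m:
        raise ValueError(f"order must be in [1, {m}], got {order}")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for restart in range(n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), restart]))
        W, C, sse = _mu_fit(V, order, rng, tol, max_iter)
        if best is None or sse < best[0]:
            best = (sse, W, C)
    sse, W, C = best

    norms = np.linalg.norm(W, axis=0)
    keep = norms > 0
    W = W.copy()
    C = C.copy()
    W[:, keep] /= norms[keep]
    C[keep, :] *= norms[keep, None]

    sst = float(np.sum(V ** 2))
    vaf = 1.0 - sse / sst if sst > 0 else np.nan
    dec = SynergyDecomposition(W=W, C=C, order=order, vaf=vaf, sse=sse,
                               n_restarts=n_restarts, seed=seed)
    if isinstance(M, PhasicMatrix):
        dec.subject_id = M.subject_id
        dec.repetition_id = M.repetition_id
    return dec


def select_model_order(vaf_by_order: Mapping[int, float], vaf_min: float = 0.8,
                       increment: float = 0.05, strict_increment: bool = False) -> int:
    """Pick the number of synergies from a VAF-vs-order curve.

    Default (stopping) rule: the smallest order N with ``VAF(N) >= vaf_min``
    whose next synergy adds less than ``increment`` of variance
    (``VAF(N+1) - VAF(N) < increment``). If no order satisfies both, the
    smallest order reaching ``vaf_min`` is returned; if the curve never
    reaches it, the largest computed order is returned with a warning.

    With ``strict_increment=True`` the alternative reading is used: every
    synergy retained up to N must itself add at least ``increment``
    (taking VAF(0) = 0), in addition to ``VAF(N) >= vaf_min``.
    """
    if not vaf_by_order:
        raise ValueError("empty VAF curve")
    orders = sorted(vaf_by_order)
    if strict_increment:
        prev = 0.0
        last_ok = None
        for n in orders:
            if vaf_by_order[n] - prev < increment:
                break
            last_ok = n
            prev = vaf_by_order[n]
        if last_ok is not None and vaf_by_order[last_ok] >= vaf_min:
            return last_ok
    else:
        for n in orders[:-1]:
            if vaf_by_order[n] >= vaf_min and vaf_by_order[n + 1] - vaf_by_order[n] < increment:
                return n
    for n in orders:
        if vaf_by_order[n] >= vaf_min:
            return n
    warnings.warn(
        f"no order reached VAF {vaf_min}; returning the largest computed order {orders[-1]}",
        stacklevel=2,
    )
    return orders[-1]


def vaf_curve(M: PhasicMatrix | np.ndarray, max_order: int | None = None,
              n_restarts: int = 50, seed: int = 0, vaf_min: float = 0.8,
              increment: float = 0.05, early_stop: bool = True,
              tol: float = 1e-6, max_iter: int = 1000,
              return_decompositions: bool = False):
    """VAF for orders 1..max_order and the selected order.

    With ``early_stop`` the curve stops as soon as the selection rule is
    decidable (an order meets the VAF floor and the next adds < 5%), which
    is how the curve is used in cohort extraction; set it False to force
    the full curve up to ``max_order``. ``return_decompositions`` also
    yields the per-order fits (to avoid refitting the selected order).
    """
    V = _as_array(M)
    m = V.shape[0]
    cap = m if max_order is None else min(max_order, m)
    vafs: dict[int, float] = {}
    decs: dict[int, SynergyDecomposition] = {}
    for order in range(1, cap + 1):
        dec = nmf_decompose(V, order, n_restarts=n_restarts,
                            seed=child_seed(seed, order), tol=tol, max_iter=max_iter)
        vafs[order] = dec.vaf
        decs[order] = dec
        if early_stop and order >= 2:
            prev = order - 1
            if vafs[prev] >= vaf_min and vafs[order] - vafs[prev] < increment:
                break
    selected = select_model_order(vafs, vaf_min=vaf_min, increment=increment)
    curve = VafCurve(vaf_by_order=vafs, selected_order=selected)
    if return_decompositions:
        return curve, decs
    return curve


@dataclass
class CohortExtraction:
    """Per-(subject, repetition) decompositions; VAF curves where order was free."""

    decompositions: dict[tuple[int, int], SynergyDecomposition]
    vaf_curves: dict[tuple[int, int], VafCurve] = field(default_factory=dict)

    @property
    def orders(self) -> dict[tuple[int, int], int]:
        return {k: d.order for k, d in self.decompositions.items()}

    @property
    def n_runs(self) -> int:
        return len(self.decompositions)


def extract_cohort(matrices: Mapping[tuple[int, int], PhasicMatrix | np.ndarray],
                   fixed_order: int | None = None, n_restarts: int = 50, seed: int = 0,
                   max_order: int | None = None, tol: float = 1e-6,
                   max_iter: int = 1000) -> CohortExtraction:
    """Decompose every repetition of a cohort: one extraction run per matrix.

    With ``fixed_order`` (the usual choice is 4 for cross-subject
    comparisons) every matrix is decomposed at that order; otherwise the
    order is chosen per repetition from its VAF curve. Every run's seed is
    derived from ``seed`` and the (subject, repetition) key.
    """
    decs: dict[tuple[int, int], SynergyDecomposition] = {}
    curves: dict[tuple[int, int], VafCurve] = {}
    for (s, r), M in sorted(matrices.items()):
        run_seed = child_seed(seed, 5, s, r)
        if fixed_order is not None:
            dec = nmf_decompose(M, fixed_order, n_restarts=n_restarts, seed=run_seed,
                                tol=tol, max_iter=max_iter)
        else:
            curve, by_order = vaf_curve(M, max_order=max_order, n_restarts=n_restarts,
                                        seed=run_seed, tol=tol, max_iter=max_iter,
                                        return_decompositions=True)
            curves[(s, r)] = curve
            dec = by_order[curve.selected_order]
        dec.subject_id, dec.repetition_id = s, r
        decs[(s, r)] = dec
    return CohortExtraction(decompositions=decs, vaf_curves=curves)
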