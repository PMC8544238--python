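"""Synergy matching and similarity: SSV, SSM, random-pairing null, activation similarity.

Synergy vectors recovered by NMF come in arbitrary order, so any
comparison first matches the two sets by maximizing the total cosine
similarity over all pairings (optimal assignment). Similarity is then
summarized per matched pair (SSV), per matrix (SSM: the mean over matched
pairs, or the literal mean over all N^2 pairs), and judged against the
random-pairing level of the pooled synergy population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
from scipy.optimize import linear_sum_assignment

from .decompose import SynergyDecomposition

__all__ = [
    "MatchResult",
    "SimilarityReport",
    "IntraSubjectResult",
    "ssv",
    "match_synergies",
    "ssm",
    "random_similarity",
    "ac_similarity",
    "intra_subject_similarity",
    "inter_subject_similarity",
    "group_similarity",
]


def ssv(w1: np.ndarray, w2: np.ndarray) -> float:
    """Cosine similarity of two non-negative synergy vectors (in [0, 1])."""
    w1 = np.asarray(w1, dtype=float).ravel()
    w2 = np.asarray(w2, dtype=float).ravel()
    n1, n2 = np.linalg.norm(w1), np.linalg.norm(w2)
    if n1 == 0 or n2 == 0:
        raise ValueError("SSV is undefined for a zero vector")
    return float(min(1.0, np.dot(w1, w2) / (n1 * n2)))


def _ssv_matrix(WA: np.ndarray, WB: np.ndarray) -> np.ndarray:
    """Pairwise SSV between columns of two synergy matrices."""
    na = np.linalg.norm(WA, axis=0)
    nb = np.linalg.norm(WB, axis=0)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("SSV is undefined for a zero vector")
    return np.clip((WA / na).T @ (WB / nb), 0.0, 1.0)


def _W(x) -> np.ndarray:
    return x.W if isinstance(x, SynergyDecomposition) else np.asarray(x, dtype=float)


@dataclass
class MatchResult:
    """Optimal pairing between two synergy sets.

    ``permutation[i] = j`` pairs synergy ``i`` of A with synergy ``j`` of
    B; ``pair_ssv[i]`` is that pair's cosine similarity.
    """

    permutation: np.ndarray
    pair_ssv: np.ndarray

    def __post_init__(self) -> None:
        perm = np.asarray(self.permutation)
        if sorted(perm.tolist()) != list(range(perm.size)):
            raise ValueError("permutation must be a bijection")
        if np.any(self.pair_ssv < 0) or np.any(self.pair_ssv > 1):
            raise ValueError("pair SSV values must lie in [0, 1]")

    @property
    def total(self) -> float:
        return float(np.sum(self.pair_ssv))


def match_synergies(A: SynergyDecomposition | np.ndarray,
                    B: SynergyDecomposition | np.ndarray) -> MatchResult:
    """Match synergies of A to synergies of B by optimal assignment on SSV.

    The bijection maximizes the summed cosine similarity over all N!
    pairings (Hungarian algorithm); ties resolve to the lowest indices.
    """
    WA, WB = _W(A), _W(B)
    if WA.shape[1] != WB.shape[1]:
        raise ValueError(f"orders differ: {WA.shape[1]} vs {WB.shape[1]}")
    S = _ssv_matrix(WA, WB)
    rows, cols = linear_sum_assignment(-S)
    perm = np.empty_like(cols)
    perm[rows] = cols
    return MatchResult(permutation=perm, pair_ssv=S[rows, perm[rows]])


def ssm(A: SynergyDecomposition | np.ndarray, B: SynergyDecomposition | np.ndarray,
        mode: Literal["matched", "allpairs"] = "matched") -> float:
    """Synergy-matrix similarity.

    ``matched`` (default): mean cosine similarity over the optimally
    matched pairs. ``allpairs``: the literal mean over all N^2 ordered
    pairs of synergy vectors from the two matrices (which is bounded well
    below 1 for distinct synergies; both are offered because reported
    values in the field are consistent with the matched reading).
    """
    WA, WB = _W(A), _W(B)
    if mode == "matched":
        return float(np.mean(match_synergies(WA, WB).pair_ssv))
    if mode == "allpairs":
        return float(np.mean(_ssv_matrix(WA, WB)))
    raise ValueError(f"unknown SSM mode: {mode!r}")


def random_similarity(pool: np.ndarray) -> float:
    """Mean SSV over all unordered pairs of a pooled synergy population.

    ``pool`` is muscles x K with one column per synergy (all subjects,
    all repetitions). Exact enumeration over the K(K-1)/2 pairs.
    """
    pool = np.asarray(pool, dtype=float)
    if pool.ndim != 2 or pool.shape[1] < 2:
        raise ValueError("pool must be muscles x K with K >= 2")
    S = _ssv_matrix(pool, pool)
    iu = np.triu_indices(pool.shape[1], k=1)
    return float(np.mean(S[iu]))


def ac_similarity(c1: np.ndarray, c2: np.ndarray) -> float:
    """Cosine similarity of two non-negative activation time courses."""
    c1 = np.asarray(c1, dtype=float).ravel()
    c2 = np.asarray(c2, dtype=float).ravel()
    if c1.size != c2.size:
        raise ValueError("activation courses must have equal length")
    return ssv(c1, c2)


@dataclass
class SimilarityReport:
    """Aggregated similarity at one level (intra-subject, inter-subject, or random).

    ``per_synergy_ssv`` holds the mean and SD over all compared pairs for
    each matched synergy; ``group_values`` holds one value per sampling
    unit (subject) for use in the downstream hypothesis tests.
    """

    level: str
    per_synergy_ssv_mean: np.ndarray
    per_synergy_ssv_sd: np.ndarray
    ssm_matched: float
    ssm_allpairs: float
    ac_similarity: np.ndarray | None = None
    group_values: np.ndarray | None = None
    random_level: float | None = None

    def __post_init__(self) -> None:
        vals = np.concatenate([np.atleast_1d(self.per_synergy_ssv_mean),
                               [self.ssm_matched, self.ssm_allpairs]])
        if np.any(vals < 0) or np.any(vals > 1 + 1e-12):
            raise ValueError("similarity values must lie in [0, 1]")


@dataclass
class IntraSubjectResult:
    """Within-subject similarity plus the aligned repetition-averaged synergies."""

    reports: dict[int, SimilarityReport]
    mean_W: dict[int, np.ndarray]
    mean_C: dict[int, np.ndarray]
    pooled: SimilarityReport


def _align_to_reference(Ws: list[np.ndarray], Cs: list[np.ndarray],
                        ref: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Reorder every (W, C) so column j matches reference synergy j."""
    aw, ac = [], []
    for W, C in zip(Ws, Cs):
        perm = match_synergies(ref, W).permutation  # ref i -> column perm[i]
        aw.append(W[:, perm])
        ac.append(C[perm, :])
    return aw, ac


def _refined_alignment(Ws: list[np.ndarray], Cs: list[np.ndarray]
                       ) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
    """Align repetitions to an iteratively refined mean synergy matrix.

    All repetitions are first matched to repetition 0, the matched vectors
    averaged into a provisional mean, and everything re-matched to that
    mean once — removing the arbitrary dependence on repetition 0.
    Returns the aligned Ws/Cs and the final unit-normalized mean W.
    """
    aw, ac = _align_to_reference(Ws, Cs, Ws[0])
    mean = np.mean(aw, axis=0)
    mean /= np.linalg.norm(mean, axis=0)
    aw, ac = _align_to_reference(Ws, Cs, mean)
    mean = np.mean(aw, axis=0)
    mean /= np.linalg.norm(mean, axis=0)
    return aw, ac, mean


def _pairwise_report(level: str, aligned_W: list[np.ndarray],
                     aligned_C: list[np.ndarray] | None) -> SimilarityReport:
    """Per-synergy pairwise SSV statistics over a list of aligned synergy sets."""
    n_sets = len(aligned_W)
    N = aligned_W[0].shape[1]
    per_pair = []   # (pair, synergy) matched SSVs
    allpairs = []
    for i in range(n_sets):
        for j in range(i + 1, n_sets):
            S = _ssv_matrix(aligned_W[i], aligned_W[j])
            per_pair.append(np.diag(S))
            allpairs.append(float(np.mean(S)))
    per_pair = np.asarray(per_pair)
    ac_sim = None
    if aligned_C is not None:
        ac_vals = []
        for i in range(n_sets):
            for j in range(i + 1, n_sets):
                ac_vals.append([ac_similarity(aligned_C[i][k], aligned_C[j][k])
                                for k in range(N)])
        ac_sim = np.mean(np.asarray(ac_vals), axis=0)
    return SimilarityReport(
        level=level,
        per_synergy_ssv_mean=per_pair.mean(axis=0),
        per_synergy_ssv_sd=per_pair.std(axis=0, ddof=1) if per_pair.shape[0] > 1 else np.zeros(N),
        ssm_matched=float(per_pair.mean()),
        ssm_allpairs=float(np.mean(allpairs)),
        ac_similarity=ac_sim,
    )


def _by_subject(decomps: Mapping[tuple[int, int], SynergyDecomposition]
                ) -> dict[int, list[SynergyDecomposition]]:
    out: dict[int, list[SynergyDecomposition]] = {}
    for (s, r), d in sorted(decomps.items()):
        out.setdefault(s, []).append(d)
    return out


def _common_order(decomps: Mapping[tuple[int, int], SynergyDecomposition]) -> int:
    orders = {d.order for d in decomps.values()}
    if len(orders) != 1:
        raise ValueError(f"similarity analysis needs a common order, got {sorted(orders)}")
    return orders.pop()


def intra_subject_similarity(decomps: Mapping[tuple[int, int], SynergyDecomposition]
                             ) -> IntraSubjectResult:
    """Within-subject similarity across repetitions, per subject.

    For each subject the repetitions are aligned to the refined mean
    synergy set; per-synergy SSV statistics are computed over all
    repetition pairs, along with the matched/all-pairs SSM and activation
    -coefficient similarity. ``group_values`` of the pooled report holds
    each subject's mean matched SSV — the sampling unit for the
    intra-vs-inter test.
    """
    _common_order(decomps)
    groups = _by_subject(decomps)
    reports: dict[int, SimilarityReport] = {}
    mean_W: dict[int, np.ndarray] = {}
    mean_C: dict[int, np.ndarray] = {}
    for s, ds in groups.items():
        Ws = [d.W for d in ds]
        Cs = [d.C for d in ds]
        if len(ds) < 2:
            raise ValueError(f"subject {s} has fewer than 2 repetitions")
        aw, ac_, mean = _refined_alignment(Ws, Cs)
        reports[s] = _pairwise_report("intra", aw, ac_)
        mean_W[s] = mean
        mean_C[s] = np.mean(ac_, axis=0)
    subj_means = np.array([reports[s].ssm_matched for s in sorted(reports)])
    N = next(iter(mean_W.values())).shape[1]
    pooled = SimilarityReport(
        level="intra",
        per_synergy_ssv_mean=np.mean([reports[s].per_synergy_ssv_mean for s in sorted(reports)], axis=0),
        per_synergy_ssv_sd=np.std([reports[s].per_synergy_ssv_mean for s in sorted(reports)], axis=0, ddof=1)
        if len(reports) > 1 else np.zeros(N),
        ssm_matched=float(subj_means.mean()),
        ssm_allpairs=float(np.mean([reports[s].ssm_allpairs for s in sorted(reports)])),
        ac_similarity=np.mean([reports[s].ac_similarity for s in sorted(reports)], axis=0),
        group_values=subj_means,
    )
    return IntraSubjectResult(reports=reports, mean_W=mean_W, mean_C=mean_C, pooled=pooled)


def inter_subject_similarity(decomps: Mapping[tuple[int, int], SynergyDecomposition],
                             intra: IntraSubjectResult | None = None) -> SimilarityReport:
    """Across-subject similarity of the repetition-averaged synergies.

    Each subject's matched synergies are averaged across repetitions
    (re-unit-normalized) and the subject means are aligned to a reference
    subject — the one with the highest within-subject SSM, a stable
    template. ``group_values`` holds, for each subject, the mean matched
    SSV of its synergies against the other subjects' means.
    """
    if intra is None:
        intra = intra_subject_similarity(decomps)
    subjects = sorted(intra.mean_W)
    if len(subjects) < 2:
        raise ValueError("inter-subject similarity needs at least 2 subjects")
    ref_subject = max(subjects, key=lambda s: intra.reports[s].ssm_matched)
    ref = intra.mean_W[ref_subject]
    Ws = [intra.mean_W[s] for s in subjects]
    Cs = [intra.mean_C[s] for s in subjects]
    aw, ac_ = _align_to_reference(Ws, Cs, ref)
    report = _pairwise_report("inter", aw, ac_)

    # per-subject value: mean matched SSV of this subject against the others
    n = len(subjects)
    vals = np.zeros(n)
    counts = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            pair = float(np.mean(np.diag(_ssv_matrix(aw[i], aw[j]))))
            vals[i] += pair
            vals[j] += pair
            counts[i] += 1
            counts[j] += 1
    report.group_values = vals / counts
    return report


def pooled_synergies(decomps: Mapping[tuple[int, int], SynergyDecomposition]) -> np.ndarray:
    """All synergy vectors of a cohort as one muscles x (sum N_i r) matrix."""
    return np.concatenate([d.W for _, d in sorted(decomps.items())], axis=1)


def random_group_values(decomps: Mapping[tuple[int, int], SynergyDecomposition]) -> np.ndarray:
    """Per-subject random-pairing similarity level.

    For each subject: the mean SSV between that subject's synergy vectors
    (all repetitions) and every synergy of every *other* subject —
    i.e. the similarity obtained with no matching at all. Exact
    enumeration; serves as the per-subject sample of the random level.
    """
    groups = _by_subject(decomps)
    subjects = sorted(groups)
    if len(subjects) < 2:
        raise ValueError("random level needs at least 2 subjects")
    mats = {s: np.concatenate([d.W for d in groups[s]], axis=1) for s in subjects}
    vals = []
    for s in subjects:
        others = np.concatenate([mats[t] for t in subjects if t != s], axis=1)
        vals.append(float(np.mean(_ssv_matrix(mats[s], others))))
    return np.asarray(vals)


def group_similarity(decomps: Mapping[tuple[int, int], SynergyDecomposition],
                     design: Literal["intra", "inter"]) -> SimilarityReport:
    """Similarity report for one design, with the random level attached."""
    rand = random_similarity(pooled_synergies(decomps))
    if design == "intra":
        report = intra_subject_similarity(decomps).pooled
    elif design == "inter":
        report = inter_subject_similarity(decomps)
    else:
        raise ValueError(f"unknown design: {design!r}")
    report.random_level = rand
    return report
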