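"""Variability statistics and the consolidated cohort report.

Quantifies intra- vs inter-subject variability of the synergy analysis:
coefficients of variation of the number of synergies and of the VAF,
a Kruskal-Wallis test on synergy counts across subjects with pairwise
post-hoc comparisons, and a one-way ANOVA comparing intra-subject,
inter-subject and random similarity levels with Tukey HSD post-hocs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "CvReport",
    "StatsResult",
    "coefficient_of_variation",
    "compare_counts",
    "compare_similarities",
    "build_report",
]


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample CV: SD (n-1 denominator) / mean. NaN (with a warning) if the mean is 0."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = x.mean()
    if mean == 0:
        warnings.warn("CV undefined for zero-mean data", stacklevel=2)
        return float("nan")
    return float(x.std(ddof=1) / mean)


@dataclass
class CvReport:
    """Coefficients of variation of synergy counts and VAF.

    Per-subject CVs are computed across that subject's repetitions; the
    pooled ``all`` CV is computed over every repetition of every subject
    jointly, so it folds inter-subject variability on top of intra.
    """

    count_cv: dict[int, float]
    count_cv_all: float
    vaf_cv: dict[int, dict[int, float]]       # order -> subject -> CV
    vaf_cv_all: dict[int, float]              # order -> pooled CV

    def n_subjects_above_all(self, metric: str = "count", order: int | None = None) -> int:
        """How many subjects have a higher CV than the pooled 'All' level."""
        if metric == "count":
            per, ref = self.count_cv, self.count_cv_all
        else:
            per, ref = self.vaf_cv[order], self.vaf_cv_all[order]
        return int(sum(v > ref for v in per.values()))


def cv_report(counts_by_subject: Mapping[int, Sequence[int]],
              vaf_by_subject: Mapping[int, Mapping[int, Sequence[float]]]) -> CvReport:
    """Assemble the CV report.

    ``counts_by_subject[s]`` is the per-repetition selected synergy count;
    ``vaf_by_subject[order][s]`` the per-repetition VAF at that fixed order
    (typically 3 and 4).
    """
    count_cv = {s: coefficient_of_variation(v) for s, v in counts_by_subject.items()}
    pooled_counts = np.concatenate([np.asarray(v, dtype=float) for v in counts_by_subject.values()])
    vaf_cv = {}
    vaf_all = {}
    for order, groups in vaf_by_subject.items():
        vaf_cv[order] = {s: coefficient_of_variation(v) for s, v in groups.items()}
        vaf_all[order] = coefficient_of_variation(
            np.concatenate([np.asarray(v, dtype=float) for v in groups.values()]))
    return CvReport(count_cv=count_cv,
                    count_cv_all=coefficient_of_variation(pooled_counts),
                    vaf_cv=vaf_cv, vaf_cv_all=vaf_all)


@dataclass
class StatsResult:
    """One hypothesis test: statistic, p-value, pairwise post-hoc p-values."""

    test: str
    statistic: float
    pvalue: float
    posthoc: dict[tuple, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.pvalue <= 1 or np.isnan(self.pvalue)):
            raise ValueError("p-value must lie in [0, 1]")


def _dunn_posthoc(groups: Mapping, alpha_adjust: str = "bonferroni") -> dict[tuple, float]:
    """Dunn's rank-based pairwise comparisons with Bonferroni correction."""
    keys = sorted(groups)
    data = [np.asarray(groups[k], dtype=float) for k in keys]
    pooled = np.concatenate(data)
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (12.0 * (n_total - 1)) if n_total > 1 else 0.0
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    mean_ranks = {}
    start = 0
    for k, d in zip(keys, data):
        mean_ranks[k] = ranks[start:start + d.size].mean()
        start += d.size
    m = len(keys) * (len(keys) - 1) // 2
    out = {}
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            na, nb = len(groups[a]), len(groups[b])
            se = np.sqrt(var_base * (1.0 / na + 1.0 / nb))
            if se == 0:
                p = 1.0
            else:
                z = (mean_ranks[a] - mean_ranks[b]) / se
                p = 2.0 * sps.norm.sf(abs(z))
                if alpha_adjust == "bonferroni":
                    p = min(1.0, p * m)
            out[(a, b)] = float(p)
    return out


def compare_counts(counts_by_subject: Mapping[int, Sequence[int]],
                   posthoc: str = "dunn") -> StatsResult:
    """Kruskal-Wallis test of the selected synergy counts across subjects.

    All-identical data yields H = 0, p = 1 (no variability to explain,
    not an error). Post-hoc pairwise comparisons are Dunn tests with
    Bonferroni correction by default; ``posthoc='tukey'`` switches to the
    parametric Tukey HSD variant.
    """
    keys = sorted(counts_by_subject)
    if len(keys) < 2:
        raise ValueError("need at least 2 subjects")
    data = [np.asarray(counts_by_subject[k], dtype=float) for k in keys]
    pooled = np.concatenate(data)
    if np.all(pooled == pooled[0]):
        return StatsResult(test="kruskal-wallis", statistic=0.0, pvalue=1.0,
                           posthoc={(a, b): 1.0 for i, a in enumerate(keys) for b in keys[i + 1:]})
    H, p = sps.kruskal(*data)
    if posthoc == "dunn":
        ph = _dunn_posthoc(counts_by_subject)
    elif posthoc == "tukey":
        ph = _tukey_pairs({k: counts_by_subject[k] for k in keys})
    else:
        raise ValueError(f"unknown posthoc: {posthoc!r}")
    return StatsResult(test="kruskal-wallis", statistic=float(H), pvalue=float(p), posthoc=ph)


def _tukey_pairs(groups: Mapping) -> dict[tuple, float]:
    keys = sorted(groups)
    values = np.concatenate([np.asarray(groups[k], dtype=float) for k in keys])
    labels = np.concatenate([[str(k)] * len(groups[k]) for k in keys])
    res = pairwise_tukeyhsd(values, labels)
    out = {}
    for row in res.summary().data[1:]:
        a, b, padj = row[0], row[1], float(row[3])
        ka = type(keys[0])(a) if not isinstance(keys[0], str) else a
        kb = type(keys[0])(b) if not isinstance(keys[0], str) else b
        out[(ka, kb)] = padj
    return out


def compare_similarities(intra: Sequence[float], inter: Sequence[float],
                         random: Sequence[float]) -> StatsResult:
    """One-way ANOVA of intra vs inter vs random similarity, Tukey HSD post-hoc."""
    groups = {"intra": np.asarray(intra, float), "inter": np.asarray(inter, float),
              "random": np.asarray(random, float)}
    for name, g in groups.items():
        if g.size < 2:
            raise ValueError(f"group {name!r} needs at least 2 values")
    if all(np.ptp(g) == 0 for g in groups.values()) and len({g[0] for g in groups.values()}) == 1:
        return StatsResult(test="anova", statistic=0.0, pvalue=1.0,
                           posthoc={("intra", "inter"): 1.0, ("intra", "random"): 1.0,
                                    ("inter", "random"): 1.0})
    F, p = sps.f_oneway(*groups.values())
    values = np.concatenate(list(groups.values()))
    labels = np.concatenate([[k] * g.size for k, g in groups.items()])
    res = pairwise_tukeyhsd(values, labels)
    ph = {}
    for row in res.summary().data[1:]:
        ph[(str(row[0]), str(row[1]))] = float(row[3])
    return StatsResult(test="anova", statistic=float(F), pvalue=float(p), posthoc=ph)


def build_report(orders: Mapping[tuple[int, int], int] | None = None,
                 cv: CvReport | None = None,
                 similarity: Mapping[str, object] | None = None,
                 rvaf_table=None,
                 stats: Mapping[str, StatsResult] | None = None) -> dict:
    """Consolidate every analysis stage into one machine-readable report.

    Missing stages are marked explicitly so a partial pipeline still
    produces a valid report. The same inputs always produce the same
    report.
    """
    report: dict = {}
    if orders is not None:
        vals = np.asarray(sorted(orders.values()))
        uniq, counts = np.unique(vals, return_counts=True)
        report["order_distribution"] = {
            "n_extractions": int(vals.size),
            "counts": {int(k): int(c) for k, c in zip(uniq, counts)},
            "fractions": {int(k): float(c / vals.size) for k, c in zip(uniq, counts)},
        }
    else:
        report["order_distribution"] = "missing"
    report["cv"] = cv if cv is not None else "missing"
    report["similarity"] = dict(similarity) if similarity is not None else "missing"
    if rvaf_table is not None:
        subjects = rvaf_table.source_ids
        report["rvaf"] = {
            "self_mean": float(np.mean([rvaf_table.self_rvaf(s) for s in subjects])),
            "cross_mean": float(np.mean([rvaf_table.cross_rvaf(s) for s in subjects])),
            "n_subjects_self_ge_cross": int(sum(
                rvaf_table.self_rvaf(s) >= rvaf_table.cross_rvaf(s) for s in subjects)),
        }
    else:
        report["rvaf"] = "missing"
    report["stats"] = dict(stats) if stats is not None else "missing"
    return report
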