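"""End-to-end cohort analysis: extraction, similarity, reconstruction, statistics.

Glue around the stage modules so a whole cohort — synthetic or
preprocessed from raw recordings — can be analyzed with one call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .config import CohortConfig, child_seed
from .containers import PhasicMatrix
from .decompose import CohortExtraction, extract_cohort
from .reconstruct import RvafTable, cross_reconstruction
from .similarity import (
    IntraSubjectResult,
    SimilarityReport,
    inter_subject_similarity,
    intra_subject_similarity,
    pooled_synergies,
    random_group_values,
    random_similarity,
)
from .simulate import EnvelopeSet, make_ground_truth, synthesize_envelopes
from .variability import CvReport, StatsResult, build_report, compare_counts, compare_similarities, cv_report

__all__ = ["CohortAnalysis", "simulate_envelope_cohort", "analyze_cohort"]


def simulate_envelope_cohort(config: CohortConfig) -> EnvelopeSet:
    """Ground truth + envelope-level cohort in one step."""
    return synthesize_envelopes(make_ground_truth(config), config)


@dataclass
class CohortAnalysis:
    """Everything the variability analysis produces for one cohort."""

    free_extraction: CohortExtraction
    fixed_extraction: CohortExtraction
    intra: IntraSubjectResult
    inter: SimilarityReport
    random_level: float
    rvaf_table: RvafTable
    cv: CvReport
    stats: dict[str, StatsResult]
    report: dict


def analyze_cohort(matrices: Mapping[tuple[int, int], PhasicMatrix],
                   seed: int = 0, n_restarts: int = 50, fixed_order: int = 4,
                   cv_orders: tuple[int, ...] = (3, 4), max_order: int | None = None,
                   tol: float = 1e-6, max_iter: int = 1000) -> CohortAnalysis:
    """Run the full variability analysis on a cohort of phasic matrices.

    Two extraction passes are run: free order (one VAF-curve-guided run
    per repetition, for the synergy-count variability analysis) and fixed
    order (default 4, for all cross-repetition / cross-subject
    comparisons). Similarity is summarized at the intra-subject,
    inter-subject and random-pairing levels, every repetition is
    cross-reconstructed from every subject's mean synergies, and the
    Kruskal-Wallis / ANOVA tests are applied.
    """
    kw = dict(n_restarts=n_restarts, tol=tol, max_iter=max_iter)
    free = extract_cohort(matrices, fixed_order=None, seed=child_seed(seed, 10),
                          max_order=max_order, **kw)
    fixed = extract_cohort(matrices, fixed_order=fixed_order, seed=child_seed(seed, 11), **kw)

    subjects = sorted({s for (s, _) in matrices})
    counts_by_subject = {
        s: [d.order for (ss, _), d in sorted(free.decompositions.items()) if ss == s]
        for s in subjects
    }
    vaf_by_order: dict[int, dict[int, list[float]]] = {}
    for order in cv_orders:
        if order == fixed_order:
            ext = fixed
        else:
            ext = extract_cohort(matrices, fixed_order=order,
                                 seed=child_seed(seed, 12, order), **kw)
        vaf_by_order[order] = {
            s: [d.vaf for (ss, _), d in sorted(ext.decompositions.items()) if ss == s]
            for s in subjects
        }
    cv = cv_report(counts_by_subject, vaf_by_order)

    intra = intra_subject_similarity(fixed.decompositions)
    inter = inter_subject_similarity(fixed.decompositions, intra)
    rand_level = random_similarity(pooled_synergies(fixed.decompositions))
    intra.pooled.random_level = rand_level
    inter.random_level = rand_level

    table = cross_reconstruction(intra.mean_W, matrices, fixed.decompositions)

    stats = {
        "counts": compare_counts(counts_by_subject),
        "similarity": compare_similarities(intra.pooled.group_values,
                                           inter.group_values,
                                           random_group_values(fixed.decompositions)),
    }
    report = build_report(
        orders=free.orders, cv=cv,
        similarity={"intra": intra.pooled, "inter": inter, "random_level": rand_level},
        rvaf_table=table, stats=stats,
    )
    return CohortAnalysis(free_extraction=free, fixed_extraction=fixed, intra=intra,
                          inter=inter, random_level=rand_level, rvaf_table=table,
                          cv=cv, stats=stats, report=report)
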