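"""Validation of predicted target rankings against confirmed interactions.

The ground truth (a union of experimentally validated interaction databases)
is incomplete, so methods are compared *relatively*: count confirmed targets
in each method's top-N list, convert counts to per-miRNA ranking scores in
1..M (M = number of methods, M for the method with most confirmed targets,
ties averaged), and sum the scores over miRNAs and datasets. An enrichment
z-score checks that a method's confirmed-target rate beats the ground
truth's base rate, and a Wilcoxon signed-rank test compares two methods'
per-miRNA scores.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from dataclasses import dataclass

from .io_data import InteractionSet
from .single_methods import RankedTargets

__all__ = [
    "EnrichmentResult",
    "confirmed_in_topN",
    "eligible_mirnas",
    "method_ranking_scores",
    "dataset_score_sum",
    "enrichment_zscore",
    "wilcoxon_compare",
    "novel_interactions",
    "score_table",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Enrichment of confirmed interactions among n evaluated predictions.

    ``x`` observed confirmed fraction, ``mu`` ground-truth confirmed
    fraction, ``sigma = sqrt(mu*(1-mu))`` (Bernoulli), and
    ``z = (x - mu) / (sigma / sqrt(n))``.
    """

    x: float
    mu: float
    sigma: float
    n: int
    z: float


def confirmed_in_topN(ranking: RankedTargets, truth: InteractionSet, N: int) -> int:
    """Number of confirmed targets among the ranking's top min(N, G) genes."""
    if N < 1:
        raise ValueError("N must be >= 1")
    m = ranking.mirna_id
    return sum((m, g) in truth for g in ranking.top(N))


def eligible_mirnas(rankings_by_method: dict, truth: InteractionSet, N: int) -> list:
    """miRNAs for which *every* method's top-N contains >= 1 confirmed target.

    ``rankings_by_method`` maps method name -> {mirna -> RankedTargets}; all
    methods must cover the same miRNAs.
    """
    methods = list(rankings_by_method)
    if not methods:
        raise ValueError("at least one method required")
    coverage = {m: set(rankings_by_method[m]) for m in methods}
    first = coverage[methods[0]]
    for m in methods[1:]:
        if coverage[m] != first:
            raise ValueError(
                f"method miRNA coverage differs: {sorted(first ^ coverage[m])}"
            )
    out = []
    for mirna in sorted(first):
        if all(
            confirmed_in_topN(rankings_by_method[m][mirna], truth, N) >= 1
            for m in methods
        ):
            out.append(mirna)
    return out


def method_ranking_scores(counts: dict) -> dict:
    """Per-miRNA ranking scores in 1..M from confirmed-target counts.

    The method with the most confirmed targets scores M, the worst scores 1;
    tied counts share the average of the scores they span, so the scores of
    all M methods always sum to M(M+1)/2.
    """
    methods = list(counts)
    vals = np.array([counts[m] for m in methods], dtype=float)
    scores = stats.rankdata(vals, method="average")
    return dict(zip(methods, scores.tolist()))


def dataset_score_sum(per_mirna_scores: dict) -> dict:
    """Sum each method's ranking scores over all miRNAs of a dataset.

    ``per_mirna_scores`` maps mirna -> {method -> score}. Summing the
    returned per-dataset sums across datasets gives the overall score.
    """
    if not per_mirna_scores:
        raise ValueError("no miRNAs to sum over")
    totals: dict = {}
    for scores in per_mirna_scores.values():
        for method, s in scores.items():
            totals[method] = totals.get(method, 0.0) + s
    return totals


def enrichment_zscore(
    confirmed_found: int, n_pairs: int, truth_confirmed: int, truth_possible: int
) -> EnrichmentResult:
    """Bernoulli enrichment z-score of a method's confirmed-interaction rate.

    ``x = confirmed_found / n_pairs`` is the observed rate over the evaluated
    miRNA-mRNA pairs; ``mu = truth_confirmed / truth_possible`` the base rate
    in the ground truth (possible pairs = unique miRNAs x unique genes);
    ``z = (x - mu) / (sqrt(mu*(1-mu)) / sqrt(n_pairs))``.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if not 0 < truth_confirmed < truth_possible:
        raise ValueError("need 0 < truth_confirmed < truth_possible (else sigma = 0)")
    x = confirmed_found / n_pairs
    mu = truth_confirmed / truth_possible
    sigma = float(np.sqrt(mu * (1 - mu)))
    z = (x - mu) / (sigma / np.sqrt(n_pairs))
    return EnrichmentResult(x=x, mu=mu, sigma=sigma, n=n_pairs, z=float(z))


def wilcoxon_compare(scores_a, scores_b) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired per-miRNA scores.

    Zero-difference pairs are dropped (standard practice); if every pair is
    tied the test is undefined and an error is raised.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired score vectors of equal length required")
    if a.size < 6:
        raise ValueError("at least 6 pairs required for a meaningful test")
    if np.all(a == b):
        raise ValueError("all paired differences are zero; test undefined")
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return float(res.pvalue)


def novel_interactions(
    predicted_topk: InteractionSet,
    truth: InteractionSet,
    sequence_predicted: InteractionSet,
) -> InteractionSet:
    """Highly-confident novel pairs: predicted, sequence-supported, unconfirmed.

    The intersection of the expression-based predictions with an independent
    sequence-based prediction set, minus everything already confirmed.
    """
    return InteractionSet((predicted_topk.pairs & sequence_predicted.pairs) - truth.pairs)


def score_table(rankings_by_method: dict, truth: InteractionSet, topns: list) -> pd.DataFrame:
    """Long-format validation table over methods, miRNAs and top-N cutoffs.

    For each N: restrict to the miRNAs eligible at that cutoff, count
    confirmed targets per method, and convert counts to 1..M ranking scores.
    Columns: topn, mirna, method, confirmed, ranking_score.
    """
    rows = []
    for N in topns:
        for mirna in eligible_mirnas(rankings_by_method, truth, N):
            counts = {
                m: confirmed_in_topN(rankings_by_method[m][mirna], truth, N)
                for m in rankings_by_method
            }
            scores = method_ranking_scores(counts)
            for m in rankings_by_method:
                rows.append(
                    {
                        "topn": N,
                        "mirna": mirna,
                        "method": m,
                        "confirmed": counts[m],
                        "ranking_score": scores[m],
                    }
                )
    return pd.DataFrame(rows, columns=["topn", "mirna", "method", "confirmed", "ranking_score"])
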