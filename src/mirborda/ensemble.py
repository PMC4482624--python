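"""Borda-count rank aggregation of per-miRNA target rankings.

The Borda count elects candidates by best average rank across voters (here,
prediction methods). ``borda_topk_rank`` is the top-k variant: genes outside
a method's top k are imputed the maximal rank G before averaging, so only
agreement within the heads of the lists matters; with k = G it coincides
exactly with the original Borda count.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .single_methods import RankedTargets

__all__ = ["EnsembleSpec", "borda_rank", "borda_topk_rank", "enumerate_ensembles"]


@dataclass(frozen=True)
class EnsembleSpec:
    """A combination of method names and a top-k cutoff ("all" = original Borda)."""

    method_names: tuple
    k: object = "all"  # int or "all"

    def __post_init__(self) -> None:
        if len(self.method_names) < 2:
            raise ValueError("an ensemble needs at least 2 methods")
        if len(set(self.method_names)) != len(self.method_names):
            raise ValueError("method names must be distinct")
        if self.k != "all" and (not isinstance(self.k, int) or self.k < 1):
            raise ValueError("k must be a positive integer or 'all'")

    @property
    def name(self) -> str:
        return "+".join(self.method_names)


def _check_universe(rankings: list) -> tuple:
    if not rankings:
        raise ValueError("at least one ranking required")
    mirna = rankings[0].mirna_id
    universe = set(rankings[0].gene_ids)
    for r in rankings[1:]:
        if r.mirna_id != mirna:
            raise ValueError(f"rankings mix miRNAs: {mirna!r} vs {r.mirna_id!r}")
        other = set(r.gene_ids)
        if other != universe:
            diff = sorted(universe ^ other)
            raise ValueError(f"gene universes differ; symmetric difference: {diff}")
    return mirna, universe


def borda_rank(rankings: list) -> RankedTargets:
    """Aggregate rankings of one miRNA by mean rank (original Borda count).

    Each gene's aggregate score is the arithmetic mean of its ranks across
    methods; the output is ordered by ascending mean rank, ties broken
    lexicographically by gene id, with ranks reassigned 1..G.
    """
    return borda_topk_rank(rankings, k=None)


def borda_topk_rank(rankings: list, k: int | None) -> RankedTargets:
    """Borda aggregation using only each method's top-k targets.

    Genes outside a method's top k receive the maximal rank (the number of
    genes G) for that method. ``k=None`` (or ``k=G``) is the original Borda
    count.
    """
    mirna, universe = _check_universe(rankings)
    G = len(universe)
    if k is None:
        k = G
    if not 1 <= k <= G:
        raise ValueError(f"k must lie in 1..{G}, got {k}")
    totals = dict.fromkeys(universe, 0.0)
    for r in rankings:
        for gene, _, rank in r.entries:
            totals[gene] += rank if rank <= k else G
    m = len(rankings)
    order = sorted(universe, key=lambda g: (totals[g], g))
    entries = [(g, totals[g] / m, rank) for rank, g in enumerate(order, start=1)]
    return RankedTargets(mirna_id=mirna, entries=entries)


def enumerate_ensembles(methods: list, levels: list) -> list:
    """All method subsets of each requested size, in canonical input order."""
    methods = list(methods)
    if len(set(methods)) != len(methods):
        raise ValueError("method names must be distinct")
    specs = []
    for level in levels:
        if not 2 <= level <= len(methods):
            raise ValueError(
                f"level {level} outside 2..{len(methods)} available methods"
            )
        specs.extend(EnsembleSpec(tuple(c)) for c in combinations(methods, level))
    return specs
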