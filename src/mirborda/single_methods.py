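"""The six individual miRNA-target scoring methods and ranking conversion.

Each method fills a miRNAs x genes score matrix from matched expression data:

- ``pearson``: product-moment correlation of each miRNA/mRNA pair;
- ``mic``: maximal information coefficient (captures non-linear regulation);
- ``lasso`` / ``elastic``: per-mRNA penalised regression on all miRNAs, the
  miRNA's coefficient is the association strength;
- ``zscore``: knockout-emulation z-score — the sample where a miRNA is
  lowest stands in for a knockout of that miRNA, and each mRNA's standardised
  deviation in that sample is its score;
- ``ida``: IDA causal-effect estimation on the PC-derived CPDAG of the joint
  miRNA+mRNA data.

Because miRNAs predominantly *down*-regulate their targets, rankings put
negative scores first (by absolute value); MIC, which carries no sign, ranks
by magnitude alone. Non-estimable entries are stored as NaN — the explicit
"undefined" marker — and always rank last.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, ElasticNetCV, Lasso, LassoCV
from sklearn.model_selection import KFold

from .causal import CPDAG, ida_all_effects, ida_effects, pc_cpdag
from .io_data import MatchedExpressionPair
from .mic import mic

__all__ = [
    "ScoreMatrix",
    "RankedTargets",
    "CPDAG",
    "pearson_scores",
    "mic_scores",
    "lasso_scores",
    "elastic_scores",
    "zscore_knockout_scores",
    "ida_scores",
    "pc_cpdag",
    "ida_effects",
    "scores_to_ranking",
    "write_rankings_tsv",
    "read_rankings_tsv",
    "METHOD_NAMES",
]

METHOD_NAMES = ("pearson", "mic", "lasso", "elastic", "zscore", "ida")


@dataclass
class ScoreMatrix:
    """miRNAs x genes association scores for one method.

    ``sign_informative`` is True when the score's sign distinguishes
    down-regulation (Pearson, Lasso, Elastic-net, Z-score, IDA) and False for
    magnitude-only measures (MIC). NaN marks a non-estimable entry.
    """

    mirna_ids: list[str]
    gene_ids: list[str]
    scores: np.ndarray
    method_name: str
    sign_informative: bool = True

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.mirna_ids), len(self.gene_ids)):
            raise ValueError("score matrix shape does not match id lists")

    def row(self, mirna: str) -> np.ndarray:
        try:
            return self.scores[self.mirna_ids.index(mirna)]
        except ValueError:
            raise KeyError(f"unknown miRNA {mirna!r}") from None


@dataclass
class RankedTargets:
    """One miRNA's genes ordered best-first; ranks are the permutation 1..G."""

    mirna_id: str
    entries: list[tuple]  # (gene_id, score, rank)

    def __post_init__(self) -> None:
        ranks = [r for _, _, r in self.entries]
        if sorted(ranks) != list(range(1, len(self.entries) + 1)):
            raise ValueError("ranks must be exactly the permutation 1..G")

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _, _ in self.entries]

    @property
    def n_genes(self) -> int:
        return len(self.entries)

    def rank_of(self) -> dict:
        return {g: r for g, _, r in self.entries}

    def top(self, n: int) -> list[str]:
        return [g for g, _, _ in self.entries[:n]]


def _standardise(values: np.ndarray) -> np.ndarray:
    """Rows to mean 0, sd 1 (population sd); zero-variance rows become 0."""
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (values - mu) / sd


def pearson_scores(pair: MatchedExpressionPair) -> ScoreMatrix:
    """Pearson correlation of every miRNA with every mRNA across samples.

    Zero-variance features give an undefined (NaN) score.
    """
    if pair.n_samples < 3:
        raise ValueError("Pearson correlation needs at least 3 samples")
    X, Y = pair.mirnas.values, pair.mrnas.values
    n = pair.n_samples
    r = (_standardise(X) @ _standardise(Y).T) / n
    r = np.clip(r, -1.0, 1.0)
    r[X.std(axis=1) == 0, :] = np.nan
    r[:, Y.std(axis=1) == 0] = np.nan
    return ScoreMatrix(
        list(pair.mirnas.feature_ids), list(pair.mrnas.feature_ids), r, "pearson", True
    )


def mic_scores(pair: MatchedExpressionPair, alpha: float = 0.6, c: int = 15) -> ScoreMatrix:
    """Maximal information coefficient for every miRNA/mRNA pair (in [0, 1])."""
    if pair.n_samples < 10:
        raise ValueError("MIC is degenerate below 10 samples")
    X, Y = pair.mirnas.values, pair.mrnas.values
    out = np.empty((X.shape[0], Y.shape[0]))
    for i in range(X.shape[0]):
        for j in range(Y.shape[0]):
            out[i, j] = mic(X[i], Y[j], alpha=alpha, c=c)
    return ScoreMatrix(
        list(pair.mirnas.feature_ids), list(pair.mrnas.feature_ids), out, "mic", False
    )


def _penalised_scores(
    pair: MatchedExpressionPair,
    l1_ratio: float,
    lam,
    cv: int,
    seed: int,
    method_name: str,
) -> ScoreMatrix:
    X = _standardise(pair.mirnas.values).T  # samples x miRNAs
    Yall = pair.mrnas.values
    n, p = X.shape
    scores = np.zeros((p, Yall.shape[0]))
    folds = KFold(n_splits=cv, shuffle=True, random_state=seed) if lam == "cv" else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for j in range(Yall.shape[0]):
            sd = Yall[j].std()
            if sd == 0:
                warnings.warn(
                    f"zero-variance response {pair.mrnas.feature_ids[j]!r}; "
                    "coefficients set to 0",
                    stacklevel=3,
                )
                continue
            y = (Yall[j] - Yall[j].mean()) / sd
            if lam == "cv":
                if l1_ratio == 1.0:
                    model = LassoCV(cv=folds, fit_intercept=False, random_state=seed)
                else:
                    model = ElasticNetCV(
                        l1_ratio=l1_ratio, cv=folds, fit_intercept=False, random_state=seed
                    )
            elif l1_ratio == 1.0:
                model = Lasso(alpha=float(lam), fit_intercept=False)
            else:
                model = ElasticNet(alpha=float(lam), l1_ratio=l1_ratio, fit_intercept=False)
            model.fit(X, y)
            scores[:, j] = model.coef_
    return ScoreMatrix(
        list(pair.mirnas.feature_ids), list(pair.mrnas.feature_ids), scores, method_name, True
    )


def lasso_scores(
    pair: MatchedExpressionPair, lam="cv", cv: int = 10, seed: int = 0
) -> ScoreMatrix:
    """L1-penalised regression of each (standardised) mRNA on all miRNAs.

    ``lam`` is either the literal penalty weight or ``"cv"`` (default) for
    10-fold cross-validation minimising mean squared error, folds drawn from
    ``seed``. Features are standardised so coefficients are comparable across
    miRNAs. The penalised objective is ``(1/2n)||y - Xb||^2 + lam*||b||_1``.
    """
    if pair.n_samples < 10:
        raise ValueError("penalised regression needs at least 10 samples")
    return _penalised_scores(pair, 1.0, lam, cv, seed, "lasso")


def elastic_scores(
    pair: MatchedExpressionPair,
    alpha_mix: float = 0.5,
    lam="cv",
    cv: int = 10,
    seed: int = 0,
) -> ScoreMatrix:
    """Elastic-net variant of :func:`lasso_scores`.

    ``alpha_mix`` in (0, 1] is the L1 share of the penalty; ``alpha_mix=1``
    reduces exactly to the lasso.
    """
    if not 0 < alpha_mix <= 1:
        raise ValueError("alpha_mix must lie in (0, 1]")
    if pair.n_samples < 10:
        raise ValueError("penalised regression needs at least 10 samples")
    return _penalised_scores(pair, float(alpha_mix), lam, cv, seed, "elastic")


def zscore_knockout_scores(pair: MatchedExpressionPair) -> ScoreMatrix:
    """Knockout-emulation z-score.

    For each miRNA the sample with its minimum expression (ties: first
    sample) emulates a knockout; each mRNA's score is its standardised
    deviation in that sample, ``(x_j(s*) - mean(x_j)) / sd(x_j)`` with the
    n-1 sd. A zero-variance mRNA scores 0 by convention.
    """
    if pair.n_samples < 3:
        raise ValueError("knockout z-score needs at least 3 samples")
    X, Y = pair.mirnas.values, pair.mrnas.values
    s_star = np.argmin(X, axis=1)  # first minimum per miRNA
    mu = Y.mean(axis=1)
    sd = Y.std(axis=1, ddof=1)
    z = np.zeros((X.shape[0], Y.shape[0]))
    ok = sd > 0
    for i, s in enumerate(s_star):
        z[i, ok] = (Y[ok, s] - mu[ok]) / sd[ok]
    return ScoreMatrix(
        list(pair.mirnas.feature_ids), list(pair.mrnas.feature_ids), z, "zscore", True
    )


def ida_scores(
    pair: MatchedExpressionPair,
    alpha: float = 0.05,
    max_cond_size: int = 3,
    orient_mirna_to_mrna: bool = True,
) -> ScoreMatrix:
    """IDA causal effects of each miRNA on each mRNA.

    Runs the PC algorithm once on the joint (miRNA + mRNA) data and fills
    each entry with the aggregated local-IDA effect. Deterministic for a
    fixed input: variable order is miRNAs then mRNAs, as given.

    By default, undirected miRNA-mRNA edges in the CPDAG are oriented
    miRNA -> mRNA as biological background knowledge before effects are
    computed (an mRNA does not transcriptionally regulate a miRNA); without
    this, every target attached by an unoriented edge contributes a
    reversed-edge zero to the effect multiset and the minimum-absolute-value
    summary degenerates to 0. Set ``orient_mirna_to_mrna=False`` for the
    purely data-driven CPDAG.
    """
    from .causal import orient_background

    mir_ids = list(pair.mirnas.feature_ids)
    gene_ids = list(pair.mrnas.feature_ids)
    names = mir_ids + gene_ids
    data = np.vstack([_standardise(pair.mirnas.values), _standardise(pair.mrnas.values)]).T
    cpdag = pc_cpdag(data, alpha=alpha, max_cond_size=max_cond_size, var_names=names)
    if orient_mirna_to_mrna:
        cpdag = orient_background(cpdag, mir_ids, gene_ids)
    eff = ida_all_effects(cpdag, data, names, mir_ids, gene_ids)
    return ScoreMatrix(mir_ids, gene_ids, eff, "ida", True)


def scores_to_ranking(
    scores: ScoreMatrix, mirna: str, magnitude_only: bool = False
) -> RankedTargets:
    """Order one miRNA's genes by the down-regulation-first ranking rule.

    Sign-informative methods: negative scores by descending magnitude, then
    positive scores by descending magnitude, then zeros, then undefined.
    MIC: descending score with undefined last. Ties break lexicographically
    by gene id; ranks are assigned 1..G.

    ``magnitude_only=True`` ranks by descending ``|score|`` regardless of
    sign — useful for the knockout z-score, whose direction is ambiguous
    (knocking out a repressor *raises* its targets).
    """
    row = scores.row(mirna)
    genes = scores.gene_ids

    def key(idx: int):
        s = row[idx]
        g = genes[idx]
        if np.isnan(s):
            return (3, 0.0, g)
        if magnitude_only or not scores.sign_informative:
            return (0, -abs(s), g)
        if s < 0:
            return (0, -abs(s), g)
        if s > 0:
            return (1, -abs(s), g)
        return (2, 0.0, g)

    order = sorted(range(len(genes)), key=key)
    entries = [(genes[i], float(row[i]), rank) for rank, i in enumerate(order, start=1)]
    return RankedTargets(mirna_id=mirna, entries=entries)


def write_rankings_tsv(rankings: dict, path, header_lines: list[str] | None = None) -> None:
    """Write rankings as long-format TSV: mirna_id, gene_id, score, rank, method.

    ``rankings`` maps method name -> {mirna -> RankedTargets}. Comment lines
    (tool version, seed, parameters) are written first, prefixed with '#'.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write("mirna_id\tgene_id\tscore\trank\tmethod\n")
        for method in rankings:
            for mirna in rankings[method]:
                for gene, score, rank in rankings[method][mirna].entries:
                    fh.write(f"{mirna}\t{gene}\t{score!r}\t{rank}\t{method}\n")


def read_rankings_tsv(path) -> dict:
    """Inverse of :func:`write_rankings_tsv` (comment lines are skipped)."""
    out: dict = {}
    with open(path, encoding="utf-8") as fh:
        header = None
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if header is None:
                header = fields
                if header != ["mirna_id", "gene_id", "score", "rank", "method"]:
                    raise ValueError(f"{path}: unexpected ranking columns {header}")
                continue
            mirna, gene, score, rank, method = fields
            out.setdefault(method, {}).setdefault(mirna, []).append(
                (gene, float(score), int(rank))
            )
    for method in out:
        for mirna, entries in out[method].items():
            entries.sort(key=lambda e: e[2])
            out[method][mirna] = RankedTargets(mirna_id=mirna, entries=entries)
    return out
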