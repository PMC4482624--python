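"""Synthetic matched expression data with planted miRNA->mRNA regulation.

The generator emulates the core signal the prediction methods exploit: if a
miRNA regulates a gene, their expression co-varies negatively. miRNA profiles
are standard normal; each planted target gene is a linear combination of its
regulator miRNAs with a negative effect size plus Gaussian noise; an optional
fraction of planted pairs uses a monotone-decreasing *nonlinear* transfer
instead (which MIC can exploit but Pearson under-rates); the remaining
"decoy" genes are independent noise. A configurable fraction of the planted
pairs is marked "confirmed", emulating an incomplete experimentally validated
ground truth.

A separate helper fabricates noisy rankers of known skill over a planted
truth, for studying when Borda aggregation beats the best individual ranker.

All outputs are pure functions of the config, including its seed: every
consumer (miRNA matrix, target choice, each gene's noise, each ranker) draws
from its own documented sub-stream, so e.g. adding rankers never perturbs
earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_data import ExpressionMatrix, InteractionSet, MatchedExpressionPair
from .single_methods import RankedTargets

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "simulate_matched_expression",
    "simulate_noisy_rankers",
    "nonlinear_transfer",
]

# sub-stream tags appended to the config seed
_STREAM_MIRNA = 1
_STREAM_TARGETS = 2
_STREAM_GENES = 3
_STREAM_CONFIRMED = 4
_STREAM_RANKER_BASE = 1000


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one simulated dataset.

    Defaults describe a desk-scale matched-expression study: 30 miRNAs, 300
    genes, 100 samples, 5 targets per miRNA with effect -1.0 and noise sd
    0.5 — strong but noisy down-regulation, all-linear by default —
    with 80% of planted pairs "confirmed" (the ground truth is incomplete).
    """

    n_mirnas: int = 30
    n_genes: int = 300
    n_samples: int = 100
    targets_per_mirna: int = 5
    effect_size: float = -1.0
    noise_sd: float = 0.5
    nonlinear_fraction: float = 0.0
    confirmed_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_mirnas, self.n_genes, self.n_samples, self.targets_per_mirna) < 1:
            raise ValueError("all counts must be positive")
        if self.targets_per_mirna > self.n_genes:
            raise ValueError("targets_per_mirna cannot exceed n_genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.nonlinear_fraction <= 1:
            raise ValueError("nonlinear_fraction must lie in [0, 1]")
        if not 0 < self.confirmed_fraction <= 1:
            raise ValueError("confirmed_fraction must lie in (0, 1]")


@dataclass
class SyntheticTruth:
    """The planted regulatory network and its 'confirmed' subset."""

    planted: set  # {(mirna_id, gene_id, effect_size)}
    confirmed_subset: InteractionSet
    mirna_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        pairs = self.planted_pairs()
        if not self.confirmed_subset.pairs <= pairs.pairs:
            raise ValueError("confirmed subset must be contained in the planted pairs")

    def planted_pairs(self) -> InteractionSet:
        return InteractionSet({(m, g) for m, g, _ in self.planted})


def nonlinear_transfer(x: np.ndarray) -> np.ndarray:
    """Monotone-decreasing bounded-slope transfer g(x) = -|x| x / (1 + |x|)."""
    ax = np.abs(x)
    return -ax * x / (1 + ax)


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, *stream])


def simulate_matched_expression(config: SyntheticConfig):
    """Generate a matched expression pair and its planted truth.

    Returns ``(MatchedExpressionPair, SyntheticTruth)``. Identical configs
    (including seed) give identical output.
    """
    c = config
    mirna_ids = [f"mir-{i:03d}" for i in range(c.n_mirnas)]
    gene_ids = [f"gene-{j:04d}" for j in range(c.n_genes)]
    sample_ids = [f"s{t:03d}" for t in range(c.n_samples)]

    M = _rng(c.seed, _STREAM_MIRNA).standard_normal((c.n_mirnas, c.n_samples))

    rng_t = _rng(c.seed, _STREAM_TARGETS)
    planted = []  # (mirna index, gene index, nonlinear?)
    for i in range(c.n_mirnas):
        genes = rng_t.choice(c.n_genes, size=c.targets_per_mirna, replace=False)
        for j in sorted(genes):
            planted.append([i, int(j), False])
    n_nl = int(round(c.nonlinear_fraction * len(planted)))
    if n_nl:
        for idx in rng_t.choice(len(planted), size=n_nl, replace=False):
            planted[idx][2] = True

    regulators: dict = {}
    for i, j, nl in planted:
        regulators.setdefault(j, []).append((i, nl))

    rng_g = _rng(c.seed, _STREAM_GENES)
    G = rng_g.standard_normal((c.n_genes, c.n_samples))  # decoy/noise baseline
    amp = abs(c.effect_size)
    for j, regs in regulators.items():
        signal = np.zeros(c.n_samples)
        for i, nl in regs:
            signal += amp * nonlinear_transfer(M[i]) if nl else c.effect_size * M[i]
        G[j] = signal + c.noise_sd * G[j]

    planted_set = {
        (mirna_ids[i], gene_ids[j], float(c.effect_size)) for i, j, _ in planted
    }
    all_pairs = sorted((mirna_ids[i], gene_ids[j]) for i, j, _ in planted)
    n_conf = int(round(c.confirmed_fraction * len(all_pairs)))
    rng_c = _rng(c.seed, _STREAM_CONFIRMED)
    conf_idx = rng_c.choice(len(all_pairs), size=n_conf, replace=False)
    confirmed = InteractionSet({all_pairs[k] for k in conf_idx})

    pair = MatchedExpressionPair(
        ExpressionMatrix(mirna_ids, sample_ids, M),
        ExpressionMatrix(gene_ids, sample_ids, G),
    )
    truth = SyntheticTruth(
        planted=planted_set,
        confirmed_subset=confirmed,
        mirna_ids=mirna_ids,
        gene_ids=gene_ids,
    )
    return pair, truth


def simulate_noisy_rankers(
    truth: SyntheticTruth,
    n_rankers: int,
    skill: float,
    seed: int,
    noise_scale: float = 1.0,
) -> dict:
    """Independent synthetic rankers of known skill over a planted truth.

    Each ranker scores every gene as ``skill * 1[planted target] +
    noise_scale * Uniform(0, 1)`` and ranks descending, so ``skill = 0`` is a
    pure-noise ranker and high skill with negligible noise recovers the truth
    exactly. Returns ``{mirna_id: [RankedTargets, ...]}`` with one entry per
    ranker; ranker r draws from sub-stream ``seed, 1000 + r`` so earlier
    rankers are unaffected by adding more.
    """
    if skill < 0:
        raise ValueError("skill must be >= 0")
    targets = {}
    for m, g in truth.planted_pairs():
        targets.setdefault(m, set()).add(g)
    genes = list(truth.gene_ids)
    out: dict = {m: [] for m in truth.mirna_ids}
    for r in range(n_rankers):
        rng = _rng(seed, _STREAM_RANKER_BASE + r)
        for m in truth.mirna_ids:
            tset = targets.get(m, set())
            noise = rng.random(len(genes)) * noise_scale
            score = np.array([skill * (g in tset) for g in genes]) + noise
            order = sorted(range(len(genes)), key=lambda i: (-score[i], genes[i]))
            entries = [
                (genes[i], float(score[i]), rank) for rank, i in enumerate(order, 1)
            ]
            out[m].append(RankedTargets(mirna_id=m, entries=entries))
    return out
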