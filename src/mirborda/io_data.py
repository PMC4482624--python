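"""Expression matrices, interaction tables and the differential-expression prefilter.

Expression data are delimited text: rows are features (miRNA or mRNA probes),
columns are samples, the first column holds feature identifiers and the header
row holds sample identifiers. Values are assumed already normalised / on log
scale; missing cells are a hard error at load time (the downstream statistics
assume complete matrices).

Interaction tables are two-column delimited text (miRNA id, gene id).
Identifiers are normalised deterministically: whitespace-trimmed, case-folded,
and an optional ``hsa-`` prefix is stripped from miRNA ids. Distinct mature
forms (``-5p``/``-3p``) are kept distinct.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "MatchedExpressionPair",
    "InteractionSet",
    "GroupLabels",
    "read_expression_matrix",
    "write_expression_matrix",
    "align_matched_pair",
    "read_interaction_table",
    "union_interactions",
    "bh_adjust",
    "de_filter",
    "normalise_mirna_id",
    "normalise_gene_id",
]


@dataclass
class ExpressionMatrix:
    """A features x samples numeric expression matrix with identifiers."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        dup = _first_duplicate(self.feature_ids)
        if dup is not None:
            raise ValueError(f"duplicate feature id: {dup!r}")
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise ValueError(f"duplicate sample id: {dup!r}")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at feature {self.feature_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r}"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def subset_features(self, keep: list[str]) -> "ExpressionMatrix":
        """Restrict to the given features, preserving this matrix's row order."""
        keep_set = set(keep)
        idx = [i for i, f in enumerate(self.feature_ids) if f in keep_set]
        return ExpressionMatrix(
            [self.feature_ids[i] for i in idx], list(self.sample_ids), self.values[idx]
        )

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        """Restrict to the given samples in the given order."""
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return ExpressionMatrix(list(self.feature_ids), list(sample_ids), self.values[:, idx])


@dataclass
class MatchedExpressionPair:
    """Matched miRNA and mRNA expression profiles over identical samples."""

    mirnas: ExpressionMatrix
    mrnas: ExpressionMatrix

    def __post_init__(self) -> None:
        if self.mirnas.sample_ids != self.mrnas.sample_ids:
            raise ValueError("miRNA and mRNA matrices must have identical sample ids in identical order")

    @property
    def n_samples(self) -> int:
        return self.mirnas.n_samples


@dataclass
class InteractionSet:
    """A deduplicated set of (miRNA id, gene id) pairs."""

    pairs: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.pairs = frozenset((str(m), str(g)) for m, g in self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair) -> bool:
        return tuple(pair) in self.pairs

    def __iter__(self):
        return iter(sorted(self.pairs))

    def mirnas(self) -> set:
        return {m for m, _ in self.pairs}

    def genes(self) -> set:
        return {g for _, g in self.pairs}


@dataclass
class GroupLabels:
    """Two-group sample assignment for the differential-expression prefilter."""

    assignment: dict

    def __post_init__(self) -> None:
        groups = set(self.assignment.values())
        if len(groups) != 2:
            raise ValueError(f"exactly two groups required, got {sorted(map(str, groups))}")

    def split(self, sample_ids: list[str]) -> tuple:
        """Column indices of each group; every sample must be assigned."""
        missing = [s for s in sample_ids if s not in self.assignment]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        g1, g2 = sorted({str(v) for v in self.assignment.values()})
        a = [i for i, s in enumerate(sample_ids) if str(self.assignment[s]) == g1]
        b = [i for i, s in enumerate(sample_ids) if str(self.assignment[s]) == g2]
        return a, b


def _first_duplicate(items):
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


def normalise_mirna_id(raw: str) -> str:
    """Trim, case-fold, and strip an optional ``hsa-`` species prefix."""
    s = str(raw).strip().casefold()
    if s.startswith("hsa-"):
        s = s[4:]
    return s


def normalise_gene_id(raw: str) -> str:
    """Trim and case-fold."""
    return str(raw).strip().casefold()


def read_expression_matrix(path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a features x samples delimited-text expression matrix.

    The first header cell (above the feature-id column) is ignored. Duplicate
    feature ids, non-numeric cells and missing cells are reported as errors
    with their location — no silent coercion or imputation.
    """
    raw = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str, keep_default_na=False)
    feature_ids = [str(i).strip() for i in raw.index]
    sample_ids = [str(c).strip() for c in raw.columns]
    dup = _first_duplicate(feature_ids)
    if dup is not None:
        raise ValueError(f"{path}: duplicate feature id: {dup!r}")
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        blank = raw[col].str.strip() == ""
        if blank.any():
            i = int(np.argmax(blank.to_numpy()))
            raise ValueError(
                f"{path}: missing value at feature {feature_ids[i]!r}, "
                f"sample {sample_ids[j]!r}"
            )
        try:
            values[:, j] = pd.to_numeric(raw[col], errors="raise").to_numpy()
        except (ValueError, TypeError):
            for i, cell in enumerate(raw[col]):
                if cell.strip() == "":
                    raise ValueError(
                        f"{path}: missing value at feature {feature_ids[i]!r}, "
                        f"sample {sample_ids[j]!r}"
                    ) from None
                try:
                    float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric value {cell!r} at feature "
                        f"{feature_ids[i]!r}, sample {sample_ids[j]!r}"
                    ) from None
            raise
    return ExpressionMatrix(feature_ids, sample_ids, values)


def write_expression_matrix(matrix: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    """Write a matrix in the same layout :func:`read_expression_matrix` reads."""
    matrix.to_frame().to_csv(path, sep=delimiter, index_label="feature_id")


def align_matched_pair(
    mirnas: ExpressionMatrix, mrnas: ExpressionMatrix
) -> MatchedExpressionPair:
    """Restrict both matrices to their shared samples, in the miRNA matrix's order.

    Samples present in only one matrix are dropped (the count is logged);
    fewer than three shared samples is an error because every downstream
    statistic is undefined there.
    """
    shared = set(mirnas.sample_ids) & set(mrnas.sample_ids)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared samples; at least 3 required")
    order = [s for s in mirnas.sample_ids if s in shared]
    dropped = (mirnas.n_samples - len(order)) + (mrnas.n_samples - len(order))
    if dropped:
        logger.info("align_matched_pair: dropped %d unmatched sample columns", dropped)
    return MatchedExpressionPair(mirnas.subset_samples(order), mrnas.subset_samples(order))


def read_interaction_table(path, delimiter: str = "\t", header: bool = False) -> InteractionSet:
    """Read a two-column (miRNA id, gene id) table into a deduplicated set.

    Identifiers are normalised (trim, case-fold, optional ``hsa-`` strip on
    the miRNA); applied to a concatenation of database dumps this yields the
    deduplicated union used as ground truth.
    """
    pairs = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno == 1 and header:
                continue
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split(delimiter)
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(f"{path}: malformed interaction row at line {lineno}: {line!r}")
            pairs.add((normalise_mirna_id(fields[0]), normalise_gene_id(fields[1])))
    return InteractionSet(pairs)


def union_interactions(sets: list) -> InteractionSet:
    """Deduplicated union of interaction sets (e.g. several validated databases)."""
    if not sets:
        raise ValueError("union_interactions requires at least one set")
    out = set()
    for s in sets:
        out |= set(s.pairs)
    return InteractionSet(out)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_filter(matrix: ExpressionMatrix, labels: GroupLabels, alpha: float) -> ExpressionMatrix:
    """Keep features differentially expressed between the two groups.

    Welch (unequal-variance) t-test per feature followed by BH adjustment;
    features with adjusted p < ``alpha`` are retained in their original row
    order. Features with zero variance in both groups are untestable and are
    dropped with a warning before testing. This is a deliberate lightweight
    stand-in for a moderated-statistics fit.
    """
    ia, ib = labels.split(matrix.sample_ids)
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("each group needs at least 2 samples for the Welch t-test")
    xa, xb = matrix.values[:, ia], matrix.values[:, ib]
    testable = ~((xa.std(axis=1) == 0) & (xb.std(axis=1) == 0))
    if not np.all(testable):
        warnings.warn(
            f"dropping {int((~testable).sum())} zero-variance feature(s) before testing",
            stacklevel=2,
        )
    if not np.any(testable):
        return ExpressionMatrix([], matrix.sample_ids, np.empty((0, matrix.n_samples)))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = stats.ttest_ind(xa[testable], xb[testable], axis=1, equal_var=False)
    padj = bh_adjust(np.nan_to_num(t.pvalue, nan=1.0))
    keep_ids = [
        f
        for f, ok in zip(np.asarray(matrix.feature_ids)[testable], padj < alpha)
        if ok
    ]
    return matrix.subset_features(keep_ids)
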