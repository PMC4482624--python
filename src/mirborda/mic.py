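"""Maximal information coefficient (MIC) estimator.

MIC measures association between two real variables on a [0, 1] scale,
capturing linear and non-linear relationships with comparable scores. For a
grid with ``nx`` columns and ``ny`` rows the normalised mutual information is
``I(X_grid; Y_grid) / log2(min(nx, ny))``; MIC is the maximum of this quantity
over all grids whose total cell count ``nx * ny`` does not exceed ``B(n) =
n**alpha``. The maximisation over one axis is exact by dynamic programming
while the other axis is equipartitioned (the ApproxMaxMI heuristic); both
orientations are evaluated, which also makes the estimate symmetric in its
two arguments.
"""

from __future__ import annotations

import numpy as np

__all__ = ["mic"]


def _equipartition_bins(v: np.ndarray, k: int) -> np.ndarray:
    """Assign each value of ``v`` to one of at most ``k`` equal-frequency bins.

    Tied values always share a bin, so the realised number of bins may be
    smaller than ``k``.
    """
    n = v.size
    order = np.argsort(v, kind="stable")
    desired = np.floor(np.arange(n) * k / n).astype(int)
    bins = np.empty(n, dtype=int)
    bins[order] = desired
    # ties must not straddle a bin boundary: give every run of equal values
    # the bin of its first element
    sv = v[order]
    run_start = np.concatenate(([0], np.nonzero(np.diff(sv))[0] + 1))
    run_id = np.cumsum(np.isin(np.arange(n), run_start)) - 1
    first_bin = desired[run_start]
    bins[order] = first_bin[run_id]
    # relabel to consecutive 0..m-1
    _, bins = np.unique(bins, return_inverse=True)
    return bins


def _clumps(x: np.ndarray, ybins: np.ndarray, max_clumps: int) -> np.ndarray:
    """Cumulative per-row counts at candidate x-partition boundaries.

    Points are sorted by x; runs of equal x, and consecutive points falling in
    the same y-row, are merged into clumps (an optimal x-partition never cuts
    inside one). If more than ``max_clumps`` clumps remain they are merged
    into superclumps of near-equal point counts. Returns an array of shape
    (k+1, rows): ``cum[t, j]`` = number of points among the first t clumps in
    row j.
    """
    n = x.size
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], ybins[order]
    # runs of equal x can never be separated; they form the atomic groups
    new_x = np.concatenate(([True], np.diff(xs) != 0))
    starts = np.nonzero(new_x)[0]
    ends = np.append(starts[1:], n)
    # label each group by its single y-row, or a unique sentinel if it spans
    # several rows (such a group is always its own clump)
    nrows = int(ybins.max()) + 1
    labels = np.empty(starts.size, dtype=int)
    sentinel = nrows
    for g, (s, e) in enumerate(zip(starts, ends)):
        seg = np.unique(ys[s:e])
        if seg.size == 1:
            labels[g] = seg[0]
        else:
            labels[g] = sentinel
            sentinel += 1
    clump_first = np.concatenate(([0], np.nonzero(np.diff(labels) != 0)[0] + 1))
    bnd = np.append(starts[clump_first], n)
    if bnd.size - 1 > max_clumps:
        # superclumps: thin the boundary set to ~max_clumps by point count
        keep = [0]
        step = n / max_clumps
        for b in bnd[1:-1]:
            if b >= step * len(keep):
                keep.append(int(b))
        keep.append(n)
        bnd = np.unique(keep)
    rowcum = np.zeros((n + 1, nrows))
    rowcum[np.arange(1, n + 1), ys] = 1.0
    rowcum = np.cumsum(rowcum, axis=0)
    return rowcum[bnd]


def _entropy_terms(counts: np.ndarray, n: int) -> np.ndarray:
    """-(c/n) log2(c/n) summed over the last axis, with 0 log 0 = 0."""
    p = counts / n
    with np.errstate(divide="ignore", invalid="ignore"):
        t = -p * np.log2(p)
    return np.nan_to_num(t).sum(axis=-1)


def _optimize_axis(x: np.ndarray, ybins: np.ndarray, max_cols: int, c: int) -> np.ndarray:
    """Best mutual information for each column count 2..max_cols.

    The y-axis rows are fixed (``ybins``); the x-axis cut points are optimised
    exactly over clump boundaries by dynamic programming. Returns an array
    ``best`` with ``best[l]`` = max I for exactly <= l columns (l >= 2).
    """
    n = x.size
    cum = _clumps(x, ybins, max_clumps=max(c * max_cols, 2))
    k = cum.shape[0] - 1  # number of clumps
    if k < 2:
        return np.zeros(max_cols + 1)
    hq = _entropy_terms(cum[-1], n)  # H(Q), fixed row entropy
    # block score for clump interval (s, t]: -(nb/n)log(nb/n) + sum_j (nbj/n)log(nbj/n)
    # DP maximises sum of block scores = H(P) - H(P,Q); I = that + H(Q)
    nb = cum[:, None, :] - cum[None, :, :]  # (t, s, rows), valid for s < t
    tot = nb.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        hp_term = -(tot / n) * np.log2(tot / n)
        hpq_term = np.nan_to_num(-(nb / n) * np.log2(nb / n)).sum(axis=-1)
    block = np.nan_to_num(hp_term) - hpq_term  # block[t, s]
    NEG = -np.inf
    dp = np.full((k + 1, max_cols + 1), NEG)
    dp[0, 0] = 0.0
    for t in range(1, k + 1):
        dp[t, 1] = block[t, 0]
    for l in range(2, max_cols + 1):
        prev = dp[:, l - 1]
        for t in range(l, k + 1):
            cand = prev[l - 1 : t] + block[t, l - 1 : t]
            dp[t, l] = cand.max() if cand.size else NEG
    best = np.full(max_cols + 1, 0.0)
    for l in range(2, max_cols + 1):
        # exactly <= l columns: trailing clumps may merge, so take the best over l' <= l
        vals = dp[k, 2 : l + 1]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            best[l] = max(0.0, vals.max() + hq)
    return best


def mic(x, y, alpha: float = 0.6, c: int = 15) -> float:
    """Maximal information coefficient of two equal-length samples.

    Parameters
    ----------
    x, y : array-like, same length n >= 10
    alpha : grid-budget exponent; grids satisfy nx*ny <= n**alpha
    c : clump factor controlling the DP search resolution

    Returns a value in [0, 1]; 0 for a constant input.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 10:
        raise ValueError(f"MIC needs at least 10 samples, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    B = max(int(n**alpha), 4)
    best = 0.0
    for a, b in ((x, y), (y, x)):
        # equipartition b into r rows, optimise columns on a
        for r in range(2, B // 2 + 1):
            max_cols = B // r
            if max_cols < 2:
                break
            ybins = _equipartition_bins(b, r)
            rows = ybins.max() + 1
            if rows < 2:
                continue
            scores = _optimize_axis(a, ybins, max_cols, c)
            for l in range(2, max_cols + 1):
                denom = np.log2(min(l, rows))
                if denom > 0:
                    best = max(best, scores[l] / denom)
    return float(min(best, 1.0))
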