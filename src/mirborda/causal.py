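"""PC algorithm and IDA causal-effect estimation.

The PC algorithm recovers the completed partially directed acyclic graph
(CPDAG) of the Markov equivalence class of the data-generating DAG, assuming
multivariate Gaussianity: conditional independence is tested with Fisher-z
partial-correlation tests. IDA ("intervention calculus when the DAG is
absent") then estimates, for an exposure/outcome pair, the multiset of
possible total causal effects — one linear-regression adjustment per locally
valid parent set of the exposure — and summarises it conservatively by the
effect of minimum absolute value (sign preserved).

The skeleton phase is the order-stable PC variant: edges removed at each
conditioning-set size are deleted only after the whole level completes, so
the output is deterministic for a fixed variable order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = [
    "CPDAG",
    "pc_cpdag",
    "dag_to_cpdag",
    "ida_effects",
    "ida_all_effects",
    "orient_background",
]


@dataclass
class CPDAG:
    """A completed partially directed acyclic graph.

    ``directed_edges`` holds (parent, child) pairs; ``undirected_edges`` holds
    frozensets {u, v}. The two sets are disjoint and the directed part is
    acyclic.
    """

    nodes: list[str]
    directed_edges: set = field(default_factory=set)
    undirected_edges: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.nodes = [str(n) for n in self.nodes]
        self.directed_edges = {(str(a), str(b)) for a, b in self.directed_edges}
        self.undirected_edges = {frozenset(map(str, e)) for e in self.undirected_edges}
        node_set = set(self.nodes)
        for a, b in self.directed_edges:
            if a == b:
                raise ValueError(f"self-loop at {a!r}")
            if a not in node_set or b not in node_set:
                raise ValueError(f"edge ({a!r}, {b!r}) references unknown node")
        for e in self.undirected_edges:
            if len(e) != 2:
                raise ValueError(f"undirected self-loop: {set(e)}")
            if not e <= node_set:
                raise ValueError(f"undirected edge {set(e)} references unknown node")
        overlap = {frozenset(e) for e in self.directed_edges} & self.undirected_edges
        if overlap:
            raise ValueError(f"edges both directed and undirected: {overlap}")
        if self._has_directed_cycle():
            raise ValueError("directed part of CPDAG contains a cycle")

    def _has_directed_cycle(self) -> bool:
        children: dict = {n: [] for n in self.nodes}
        indeg = {n: 0 for n in self.nodes}
        for a, b in self.directed_edges:
            children[a].append(b)
            indeg[b] += 1
        queue = [n for n in self.nodes if indeg[n] == 0]
        seen = 0
        while queue:
            n = queue.pop()
            seen += 1
            for m in children[n]:
                indeg[m] -= 1
                if indeg[m] == 0:
                    queue.append(m)
        return seen < len(self.nodes)

    # -- adjacency helpers -------------------------------------------------
    def parents(self, node: str) -> set:
        return {a for a, b in self.directed_edges if b == node}

    def undirected_neighbours(self, node: str) -> set:
        return {next(iter(e - {node})) for e in self.undirected_edges if node in e}

    def adjacent(self, u: str, v: str) -> bool:
        return (
            (u, v) in self.directed_edges
            or (v, u) in self.directed_edges
            or frozenset((u, v)) in self.undirected_edges
        )


def _fisher_z_pvalue(r: float, n: int, k: int) -> float:
    """Two-sided p-value that a partial correlation (given k variables) is 0."""
    dof = n - k - 3
    if dof <= 0:
        return 1.0
    r = float(np.clip(r, -0.999999, 0.999999))
    z = 0.5 * np.log1p(2 * r / (1 - r)) * np.sqrt(dof)
    return float(2 * stats.norm.sf(abs(z)))


def _partial_corr(corr: np.ndarray, i: int, j: int, cond: tuple) -> float:
    """Partial correlation of variables i, j given the set ``cond``."""
    if not cond:
        return corr[i, j]
    idx = [i, j, *cond]
    sub = corr[np.ix_(idx, idx)]
    try:
        prec = np.linalg.inv(sub)
    except np.linalg.LinAlgError:
        return 0.0
    d = prec[0, 0] * prec[1, 1]
    if d <= 0:
        return 0.0
    return float(-prec[0, 1] / np.sqrt(d))


def pc_cpdag(
    data: np.ndarray,
    alpha: float = 0.05,
    max_cond_size: int = 3,
    var_names: list[str] | None = None,
) -> CPDAG:
    """Estimate the CPDAG from an n x p data matrix with the PC algorithm.

    Variables are standardised internally; conditional independence uses
    Fisher-z tests at level ``alpha`` with conditioning sets of size up to
    ``max_cond_size``. Variable order is the input column order, fixed for
    determinism. ``max_cond_size`` bounds the search for tractability on
    matrices with thousands of variables.
    """
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    if n < 10:
        raise ValueError(f"PC needs at least 10 samples, got {n}")
    names = [str(v) for v in var_names] if var_names is not None else [f"V{i}" for i in range(p)]
    if len(names) != p:
        raise ValueError("var_names length must match number of columns")
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    corr = np.corrcoef(Z, rowvar=False)
    if not np.all(np.isfinite(corr)):
        raise ValueError("correlation matrix contains non-finite values")

    adj = [set(range(p)) - {i} for i in range(p)]
    sepset: dict = {}

    # level 0 vectorised: remove marginally independent pairs
    if n - 3 > 0:
        r0 = np.clip(corr, -0.999999, 0.999999)
        z0 = 0.5 * np.log((1 + r0) / (1 - r0)) * np.sqrt(n - 3)
        p0 = 2 * stats.norm.sf(np.abs(z0))
    else:
        p0 = np.ones((p, p))
    for i, j in zip(*np.nonzero(np.triu(p0 > alpha, k=1))):
        i, j = int(i), int(j)
        adj[i].discard(j)
        adj[j].discard(i)
        sepset[(i, j)] = ()

    for level in range(1, max_cond_size + 1):
        adj_frozen = [frozenset(a) for a in adj]  # PC-stable: fix neighbourhoods
        if all(len(a) - 1 < level for a in adj_frozen):
            break
        removals = []
        for i in range(p):
            for j in sorted(adj[i]):
                if j < i or j not in adj[i]:
                    continue
                separated = False
                for base in (adj_frozen[i] - {j}, adj_frozen[j] - {i}):
                    if len(base) < level:
                        continue
                    for cond in combinations(sorted(base), level):
                        r = _partial_corr(corr, i, j, cond)
                        if _fisher_z_pvalue(r, n, level) > alpha:
                            removals.append((i, j, cond))
                            separated = True
                            break
                    if separated:
                        break
                if separated:
                    adj[i].discard(j)
                    adj[j].discard(i)
        for i, j, cond in removals:
            sepset[(min(i, j), max(i, j))] = cond

    # v-structures: for i - k - j with i, j non-adjacent and k not in sepset(i, j)
    directed: set = set()
    undirected = {frozenset((i, j)) for i in range(p) for j in adj[i] if i < j}

    def path_exists(src, dst):
        stack, seen = [src], {src}
        while stack:
            v = stack.pop()
            if v == dst:
                return True
            for w in adj[v]:
                if (v, w) in directed and w not in seen:
                    seen.add(w)
                    stack.append(w)
        return False

    for i in range(p):
        for j in range(i + 1, p):
            if j in adj[i]:
                continue
            for k in sorted(adj[i] & adj[j]):
                if k in sepset.get((i, j), ()):
                    continue
                for a in (i, j):
                    e = frozenset((a, k))
                    # conflicting v-structures (an existing k -> a edge, or an
                    # orientation that would close a directed cycle) are left
                    # alone: first-come wins, in deterministic order
                    if e in undirected and not path_exists(k, a):
                        undirected.discard(e)
                        directed.add((a, k))

    _apply_meek_rules(range(p), adj, directed, undirected)

    return CPDAG(
        nodes=names,
        directed_edges={(names[a], names[b]) for a, b in directed},
        undirected_edges={frozenset((names[a], names[b])) for a, b in undirected},
    )


def _apply_meek_rules(nodes, adj, directed: set, undirected: set) -> None:
    """Orient undirected edges by Meek's rules R1-R3 until closure.

    With orientations seeded purely by v-structures, rules R1-R3 are
    complete. Background-knowledge edges may make the seed orientations
    inconsistent, so any orientation that would close a directed cycle is
    skipped.
    """

    def is_adj(a, b):
        return b in adj[a]

    def would_cycle(x, y):
        # directed path y ->* x already present?
        stack, seen = [y], {y}
        while stack:
            v = stack.pop()
            if v == x:
                return True
            for w in adj[v]:
                if (v, w) in directed and w not in seen:
                    seen.add(w)
                    stack.append(w)
        return False

    changed = True
    while changed:
        changed = False
        for e in sorted(undirected, key=sorted):
            if e not in undirected:
                continue
            a, b = sorted(e)
            for x, y in ((a, b), (b, a)):
                orient = False
                # R1: z -> x, z not adjacent y  =>  x -> y
                if any((z, x) in directed and not is_adj(z, y) for z in adj[x] if z != y):
                    orient = True
                # R2: x -> z -> y  =>  x -> y
                elif any((x, z) in directed and (z, y) in directed for z in adj[x] if z != y):
                    orient = True
                # R3: x - z1 -> y, x - z2 -> y, z1 not adjacent z2  =>  x -> y
                else:
                    zs = [
                        z
                        for z in adj[x]
                        if z != y
                        and frozenset((x, z)) in undirected
                        and (z, y) in directed
                    ]
                    if any(not is_adj(z1, z2) for z1, z2 in combinations(sorted(zs), 2)):
                        orient = True
                if orient and not would_cycle(x, y):
                    undirected.discard(e)
                    directed.add((x, y))
                    changed = True
                    break


def dag_to_cpdag(nodes: list[str], dag_edges: set) -> CPDAG:
    """CPDAG of the Markov equivalence class of a DAG.

    Keeps the skeleton, orients the edges participating in v-structures
    (colliders with non-adjacent parents), and closes under Meek's rules.
    """
    names = [str(n) for n in nodes]
    pos = {v: i for i, v in enumerate(names)}
    p = len(names)
    edges = {(pos[str(a)], pos[str(b)]) for a, b in dag_edges}
    adj = [set() for _ in range(p)]
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    parents = [sorted({a for a, b in edges if b == v}) for v in range(p)]
    directed: set = set()
    for v in range(p):
        for a, b in combinations(parents[v], 2):
            if (a, b) not in edges and (b, a) not in edges:
                directed.add((a, v))
                directed.add((b, v))
    undirected = {frozenset(e) for e in edges if e not in directed and (e[1], e[0]) not in directed}
    _apply_meek_rules(range(p), adj, directed, undirected)
    return CPDAG(
        nodes=names,
        directed_edges={(names[a], names[b]) for a, b in directed},
        undirected_edges={frozenset((names[a], names[b])) for a, b in undirected},
    )


def orient_background(cpdag: CPDAG, causes: list[str], effects: list[str]) -> CPDAG:
    """Orient undirected cause-effect edges by background knowledge.

    Every edge between a node in ``causes`` and a node in ``effects`` is
    oriented cause -> effect (e.g. miRNA -> mRNA: transcripts do not
    transcriptionally regulate miRNAs), then Meek's rules are applied to
    closure. Effect -> cause edges produced by spurious v-structures are
    flipped: the hard domain constraint overrides the data-driven
    orientation. Edges within either group are left as they are. Returns a
    new graph; acyclicity holds because no effect -> cause edge remains.
    """
    cause_set, effect_set = set(map(str, causes)), set(map(str, effects))
    pos = {v: i for i, v in enumerate(cpdag.nodes)}
    directed = set()
    for a, b in cpdag.directed_edges:
        if a in effect_set and b in cause_set:
            a, b = b, a
        directed.add((pos[a], pos[b]))
    undirected = set()
    for e in cpdag.undirected_edges:
        u, v = sorted(e)
        if u in cause_set and v in effect_set:
            directed.add((pos[u], pos[v]))
        elif v in cause_set and u in effect_set:
            directed.add((pos[v], pos[u]))
        else:
            undirected.add(frozenset((pos[u], pos[v])))
    p = len(cpdag.nodes)
    adj = [set() for _ in range(p)]
    for a, b in directed:
        adj[a].add(b)
        adj[b].add(a)
    for e in undirected:
        a, b = tuple(e)
        adj[a].add(b)
        adj[b].add(a)
    _apply_meek_rules(range(p), adj, directed, undirected)
    names = cpdag.nodes
    return CPDAG(
        nodes=list(names),
        directed_edges={(names[a], names[b]) for a, b in directed},
        undirected_edges={frozenset((names[a], names[b])) for a, b in undirected},
    )


def _valid_parent_sets(cpdag: CPDAG, x: str) -> list[tuple]:
    """Locally valid adjustment sets for exposure ``x``.

    Each is pa(x) plus a subset S of x's undirected neighbours such that
    orienting S into x creates no new collider: members of S must be pairwise
    adjacent and adjacent to every directed parent.
    """
    pa = sorted(cpdag.parents(x))
    sib = sorted(cpdag.undirected_neighbours(x))
    valid: list[tuple] = []

    def extend(chosen: list, start: int) -> None:
        valid.append(tuple(pa) + tuple(chosen))
        for idx in range(start, len(sib)):
            s = sib[idx]
            if all(cpdag.adjacent(s, t) for t in chosen) and all(
                cpdag.adjacent(s, q) for q in pa
            ):
                chosen.append(s)
                extend(chosen, idx + 1)
                chosen.pop()

    extend([], 0)
    return valid


def _effect_from_cov(cov: np.ndarray, pos: dict, x: str, y: str, zset: tuple) -> float:
    """Coefficient of x in the population regression of y on {x} u zset."""
    idx = [pos[x], *(pos[z] for z in zset)]
    A = cov[np.ix_(idx, idx)]
    b = cov[idx, pos[y]]
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.nan
    return float(beta[0])


def ida_effects(
    cpdag: CPDAG,
    data: np.ndarray,
    var_names: list[str],
    mirna: str,
    gene: str,
    return_multiset: bool = False,
):
    """Aggregated local-IDA causal effect of ``mirna`` on ``gene``.

    One adjusted OLS effect per locally valid parent set of the exposure; an
    effect is 0 whenever the outcome lies in the adjustment set (the outcome
    would then be a non-descendant of the exposure). The multiset is
    aggregated by minimum absolute value, preserving that element's sign —
    the conservative lower bound customary for IDA.
    """
    names = [str(v) for v in var_names]
    if mirna not in names or gene not in names:
        raise ValueError(f"{mirna!r} or {gene!r} not among the CPDAG variables")
    if mirna not in cpdag.nodes or gene not in cpdag.nodes:
        raise ValueError(f"{mirna!r} or {gene!r} not in the CPDAG")
    X = np.asarray(data, dtype=float)
    cov = np.cov(X, rowvar=False)
    pos = {v: i for i, v in enumerate(names)}
    effects = []
    for zset in _valid_parent_sets(cpdag, mirna):
        if gene in zset:
            effects.append(0.0)
            continue
        beta = _effect_from_cov(cov, pos, mirna, gene, zset)
        if not np.isfinite(beta):
            warnings.warn(
                f"singular regression for parent set {zset}; effect excluded",
                stacklevel=2,
            )
            continue
        effects.append(beta)
    if return_multiset:
        return effects
    if not effects:
        return np.nan
    return min(effects, key=abs)


def ida_all_effects(
    cpdag: CPDAG,
    data: np.ndarray,
    var_names: list[str],
    exposures: list[str],
    outcomes: list[str],
) -> np.ndarray:
    """Aggregated IDA effects for every exposure/outcome pair (vectorised).

    Valid parent sets are enumerated once per exposure and the per-set
    regression solves are shared across all outcomes.
    """
    names = [str(v) for v in var_names]
    pos = {v: i for i, v in enumerate(names)}
    X = np.asarray(data, dtype=float)
    cov = np.cov(X, rowvar=False)
    out = np.zeros((len(exposures), len(outcomes)))
    out_idx = np.array([pos[o] for o in outcomes])
    for i, x in enumerate(exposures):
        zsets = _valid_parent_sets(cpdag, x)
        per_set = np.empty((len(zsets), len(outcomes)))
        for s, zset in enumerate(zsets):
            idx = [pos[x], *(pos[z] for z in zset)]
            A = cov[np.ix_(idx, idx)]
            B = cov[np.ix_(idx, out_idx)]
            try:
                beta = np.linalg.solve(A, B)[0]
            except np.linalg.LinAlgError:
                beta = np.full(len(outcomes), np.nan)
            # outcome inside the adjustment set => effect 0 by definition
            inz = np.array([o in zset for o in outcomes])
            beta = np.where(inz, 0.0, beta)
            per_set[s] = beta
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            per_set = np.ma.masked_invalid(per_set)
            amin = np.ma.argmin(np.ma.abs(per_set), axis=0)
        out[i] = per_set[amin, np.arange(len(outcomes))].filled(np.nan)
    return out
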