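"""Test-side Markov-equivalence-class oracle, independent of the library.

The equivalence class of a DAG is enumerated definitionally: every acyclic
orientation of its skeleton with identical v-structures. The CPDAG keeps an
edge directed iff every member agrees on its orientation.
"""

import itertools

import numpy as np

from mirborda.causal import CPDAG


def acyclic(n, edges):
    children = {v: [] for v in range(n)}
    indeg = dict.fromkeys(range(n), 0)
    for a, b in edges:
        children[a].append(b)
        indeg[b] += 1
    stack = [v for v in range(n) if indeg[v] == 0]
    seen = 0
    while stack:
        v = stack.pop()
        seen += 1
        for c in children[v]:
            indeg[c] -= 1
            if indeg[c] == 0:
                stack.append(c)
    return seen == n


def vstructures(n, edges):
    out = set()
    for v in range(n):
        pa = sorted(a for a, b in edges if b == v)
        for a, b in itertools.combinations(pa, 2):
            if (a, b) not in edges and (b, a) not in edges:
                out.add((a, v, b))
    return out


def random_dag(rng, n, p_edge=0.5):
    order = rng.permutation(n)
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                edges.add((int(order[i]), int(order[j])))
    return edges


def equivalence_class(n, dag_edges):
    skel = sorted({frozenset(e) for e in dag_edges}, key=sorted)
    vs = vstructures(n, dag_edges)
    members = []
    for choice in itertools.product(
        *[(tuple(sorted(e)), tuple(sorted(e))[::-1]) for e in skel]
    ):
        cand = set(choice)
        if acyclic(n, cand) and vstructures(n, cand) == vs:
            members.append(cand)
    return members


def definitional_cpdag(n, members):
    directed, undirected = set(), set()
    for e in {frozenset(x) for x in members[0]}:
        u, v = tuple(e)
        if len({(u, v) in m for m in members}) == 2:
            undirected.add(e)
        elif (u, v) in members[0]:
            directed.add((u, v))
        else:
            directed.add((v, u))
    names = [f"V{i}" for i in range(n)]
    return CPDAG(
        nodes=names,
        directed_edges={(names[a], names[b]) for a, b in directed},
        undirected_edges={frozenset((names[a], names[b])) for a, b in undirected},
    )


def simulate_sem(rng, n_nodes, dag_edges, n_samples, beta_range=(0.5, 1.5)):
    """Linear-Gaussian structural equations evaluated in topological order."""
    weights = {e: rng.uniform(*beta_range) * rng.choice([-1, 1]) for e in dag_edges}
    X = np.zeros((n_samples, n_nodes))
    placed, remaining = [], set(range(n_nodes))
    while remaining:
        v = min(
            u for u in remaining if all(a in placed for a, b in dag_edges if b == u)
        )
        X[:, v] = rng.normal(size=n_samples)
        for a, b in dag_edges:
            if b == v:
                X[:, v] += weights[(a, b)] * X[:, a]
        placed.append(v)
        remaining.discard(v)
    return X


def ols_effect(X, xi, yi, zset):
    cols = [xi, *zset]
    A = np.column_stack([X[:, cols], np.ones(len(X))])
    beta, *_ = np.linalg.lstsq(A, X[:, yi], rcond=None)
    return float(beta[0])
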