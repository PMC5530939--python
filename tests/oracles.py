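"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from scratch (Floyd-Warshall
closures, naive agglomeration, Prüfer-sequence tree enumeration) so that
it shares no code path with the package implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


# -- transitive closure and ancestor metrics ---------------------------


def closure_ancestors(nodes: list[str], edges: set[tuple[str, str]]) -> dict[str, set[str]]:
    """Proper-ancestor sets via boolean Floyd-Warshall closure."""
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    reach = np.zeros((n, n), dtype=bool)
    for p, c in edges:
        reach[idx[p], idx[c]] = True
    for k in range(n):
        reach |= np.outer(reach[:, k], reach[k, :])
    return {
        x: {nodes[j] for j in range(n) if reach[j, idx[x]]} for x in nodes
    }


def brute_metrics(ref_nodes, ref_edges, inf_nodes, inf_edges):
    """(EC, AC, AP, AR, F) from first principles on explicit edge sets."""
    ec = len(set(ref_edges) & set(inf_edges)) / len(ref_edges)
    a_ref = closure_ancestors(sorted(ref_nodes), set(ref_edges))
    a_inf = closure_ancestors(sorted(inf_nodes), set(inf_edges))
    shared = set(ref_nodes) & set(inf_nodes)
    ajs, hps, hrs = [], [], []
    for x in shared:
        r, i = a_ref[x], a_inf[x]
        if r or i:
            ajs.append(len(r & i) / len(r | i))
        if i:
            hps.append(len(r & i) / len(i))
        if r:
            hrs.append(len(r & i) / len(r))
    ac = sum(ajs) / len(ajs)
    ap = sum(hps) / len(hps)
    ar = sum(hrs) / len(hrs)
    f = 2 * ap * ar / (ap + ar) if ap + ar else 0.0
    return ec, ac, ap, ar, f


# -- naive complete linkage --------------------------------------------


def naive_complete_linkage(labels, dist):
    """O(n^3) agglomeration recomputing max linkage from the raw matrix.

    Returns the merge heights in order and the final list of merge
    (cluster, cluster) pairs as frozensets of labels.  Tie-break: the
    pair whose (smallest member, smallest member) sorted key is least.
    """
    idx = {lab: i for i, lab in enumerate(labels)}
    clusters = [frozenset([lab]) for lab in labels]
    heights, merged_pairs = [], []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            d = max(dist[idx[x], idx[y]] for x in a for y in b)
            lo, hi = sorted((min(a), min(b)))
            key = (d, lo, hi)
            if best is None or key < best[0]:
                best = (key, a, b)
        (d, _, _), a, b = best
        heights.append(d)
        merged_pairs.append((a, b))
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
    return heights, merged_pairs


# -- spanning tree enumeration -----------------------------------------


def prufer_decode(seq: tuple[int, ...], n: int) -> list[tuple[int, int]]:
    degree = [1] * n
    for x in seq:
        degree[x] += 1
    edges = []
    seq = list(seq)
    for x in seq:
        for v in range(n):
            if degree[v] == 1:
                edges.append((v, x))
                degree[v] -= 1
                degree[x] -= 1
                break
    u, v = [i for i in range(n) if degree[i] == 1]
    edges.append((u, v))
    return edges


def min_spanning_weight(weights: np.ndarray) -> float:
    """Minimum total weight over all n^(n-2) labeled spanning trees."""
    n = weights.shape[0]
    if n == 2:
        return float(weights[0, 1])
    best = np.inf
    for seq in itertools.product(range(n), repeat=n - 2):
        w = sum(weights[u, v] for u, v in prufer_decode(seq, n))
        best = min(best, w)
    return float(best)


# -- random structure generators ---------------------------------------


def random_dag(rng: np.random.Generator, n: int, p: float = 0.3):
    """Random DAG on labels d00..d(n-1); always has at least one edge."""
    labels = [f"d{i:02d}" for i in range(n)]
    order = list(rng.permutation(n))
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.add((labels[order[i]], labels[order[j]]))
    if not edges:
        edges.add((labels[order[0]], labels[order[1]]))
    return labels, edges


def random_distance_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m
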