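"""Independent brute-force oracles, written with plain loops so they share
no code path with the package implementations they check."""

from __future__ import annotations

import itertools
import math


def brute_assortativity(edges, scores):
    """Weighted source/target-end trait correlation over a directed edge
    list ``[(u, v, w), ...]`` with ``scores[node]``; plain-loop reference."""
    W = sum(w for _, _, w in edges)
    ms = sum(w * scores[u] for u, _, w in edges) / W
    mt = sum(w * scores[v] for _, v, w in edges) / W
    vs = sum(w * (scores[u] - ms) ** 2 for u, _, w in edges) / W
    vt = sum(w * (scores[v] - mt) ** 2 for _, v, w in edges) / W
    cov = sum(w * (scores[u] - ms) * (scores[v] - mt) for u, v, w in edges) / W
    return cov / math.sqrt(vs * vt)


def symmetrize(edges):
    """Undirected edge list -> both directions."""
    out = []
    for u, v, w in edges:
        out.append((u, v, w))
        out.append((v, u, w))
    return out


def brute_knn(points, ids, k):
    """Directed k-NN edge index pairs with (distance, id) tie-breaking."""
    n = len(points)
    edges = []
    for i in range(n):
        cand = []
        for j in range(n):
            if j == i:
                continue
            d = math.dist(points[i], points[j])
            cand.append((d, ids[j], j))
        cand.sort()
        for d, _, j in cand[: min(k, n - 1)]:
            edges.append((i, j, d))
    return edges


def brute_null_mean(edges, scores_multiset, nodes):
    """Exact node-permutation null mean of assortativity by enumerating all
    assignments of the score multiset to the nodes."""
    vals = []
    for perm in itertools.permutations(scores_multiset):
        s = dict(zip(nodes, perm))
        vals.append(brute_assortativity(edges, s))
    return sum(vals) / len(vals)


def brute_jackknife_se(edges, scores, units):
    """sqrt(sum over units of (r_without_unit - r)^2); ``units`` is a list of
    lists of edge indices."""
    r = brute_assortativity(edges, scores)
    ss = 0.0
    for unit in units:
        kept = [e for i, e in enumerate(edges) if i not in unit]
        try:
            r_del = brute_assortativity(kept, scores)
        except (ZeroDivisionError, ValueError):
            continue
        ss += (r_del - r) ** 2
    return math.sqrt(ss)
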