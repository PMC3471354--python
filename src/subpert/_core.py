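"""Index-based annealing inner loop.

The loop maintains the score numerator (sum d_g z_g) and the squared-degree
sum incrementally, so every edge toggle is O(1) and a node toggle is O(deg).
All randomness (initial inclusion mask, element choices, acceptance
uniforms) is drawn by the caller and passed in as arrays, which keeps the
loop purely deterministic arithmetic: the optional numba JIT and the
pure-Python fallback produce bit-identical trajectories.

The degree-sum accumulator is an exact integer; only the weighted-z
numerator is floating point, and the winning subgraph's score is recomputed
exactly from its edge set by the caller.
"""

from __future__ import annotations

import numpy as np


def _anneal_loop_py(
    edge_u,       # int64[m] endpoint indices
    edge_v,       # int64[m]
    adj_indptr,   # int64[n_nodes+1] CSR offsets into adj_edges
    adj_edges,    # int64[] incident parent-edge indices per node
    z,            # float64[n_nodes] per-gene z-scores
    incl,         # uint8[m] initial inclusion mask (modified in place)
    elems,        # int64[n_iter] chosen element: <m edge, >=m node (a-m)
    unifs,        # float64[n_iter] acceptance uniforms
    t_start,      # float
    cool,         # float geometric cooling factor per iteration
):
    m = edge_u.shape[0]
    n_nodes = adj_indptr.shape[0] - 1
    deg = np.zeros(n_nodes, dtype=np.int64)
    num = 0.0
    den = 0
    for e in range(m):
        if incl[e]:
            deg[edge_u[e]] += 1
            deg[edge_v[e]] += 1
            num += z[edge_u[e]] + z[edge_v[e]]
    for u in range(n_nodes):
        den += deg[u] * deg[u]
    score = num / np.sqrt(den) if den > 0 else 0.0

    best_score = score
    best_incl = incl.copy()
    toggled = np.empty(m, dtype=np.int64)

    T = t_start
    n_iter = elems.shape[0]
    for i in range(n_iter):
        a = elems[i]
        ntog = 0
        if a < m:
            toggled[0] = a
            ntog = 1
        else:
            node = a - m
            lo = adj_indptr[node]
            hi = adj_indptr[node + 1]
            if deg[node] > 0:
                # node "present": remove all its current edges
                for j in range(lo, hi):
                    e = adj_edges[j]
                    if incl[e]:
                        toggled[ntog] = e
                        ntog += 1
            else:
                # node "absent": add all its parent edges
                for j in range(lo, hi):
                    toggled[ntog] = adj_edges[j]
                    ntog += 1
        if ntog == 0:
            T *= cool
            continue

        for t in range(ntog):
            e = toggled[t]
            u = edge_u[e]
            v = edge_v[e]
            if incl[e]:
                incl[e] = 0
                den -= 2 * deg[u] - 1 + 2 * deg[v] - 1
                deg[u] -= 1
                deg[v] -= 1
                num -= z[u] + z[v]
            else:
                incl[e] = 1
                den += 2 * deg[u] + 1 + 2 * deg[v] + 1
                deg[u] += 1
                deg[v] += 1
                num += z[u] + z[v]

        new_score = num / np.sqrt(den) if den > 0 else 0.0
        delta = new_score - score
        if delta > 0.0 or unifs[i] < np.exp(delta / T):
            score = new_score
            if score > best_score:
                best_score = score
                best_incl[:] = incl
        else:
            # reject: undo the toggles
            for t in range(ntog):
                e = toggled[t]
                u = edge_u[e]
                v = edge_v[e]
                if incl[e]:
                    incl[e] = 0
                    den -= 2 * deg[u] - 1 + 2 * deg[v] - 1
                    deg[u] -= 1
                    deg[v] -= 1
                    num -= z[u] + z[v]
                else:
                    incl[e] = 1
                    den += 2 * deg[u] + 1 + 2 * deg[v] + 1
                    deg[u] += 1
                    deg[v] += 1
                    num += z[u] + z[v]
        T *= cool

    return best_incl, best_score, incl, score, T


try:  # pragma: no cover - exercised implicitly when numba is installed
    from numba import njit

    anneal_loop = njit(cache=False)(_anneal_loop_py)
except ImportError:  # pragma: no cover
    anneal_loop = _anneal_loop_py
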