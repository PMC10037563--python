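"""Discrete MRF solvers for the field-map labeling problem.

The energy minimized is

    E(x) = sum_v U[v, x_v] + lam * sum_{(u,v) in edges} |x_u - x_v|

over integer labels ``x_v in {0..L-1}``.  Because the pairwise term is
convex in the label difference, the global optimum is computable by a
single min-cut on an Ishikawa-style layered graph; :func:`solve_ishikawa`
does exactly that using ``scipy.sparse.csgraph.maximum_flow`` with
integer-scaled capacities.  :func:`solve_chain_dp` (exact for 1-D chains)
and :func:`solve_exhaustive` (tiny instances) serve as independent
oracles.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import breadth_first_order, maximum_flow

__all__ = ["mrf_energy", "solve_chain_dp", "solve_exhaustive", "solve_ishikawa"]


def mrf_energy(labels: np.ndarray, unary: np.ndarray, edges: np.ndarray, lam: float) -> float:
    """Evaluate E(x) in float64 regardless of which solver produced x."""
    labels = np.asarray(labels)
    e = float(unary[np.arange(unary.shape[0]), labels].sum())
    if len(edges):
        edges = np.asarray(edges)
        e += lam * float(np.abs(labels[edges[:, 0]] - labels[edges[:, 1]]).sum())
    return e


def solve_chain_dp(unary: np.ndarray, lam: float) -> np.ndarray:
    """Exact Viterbi-style DP for a 1-D chain (voxels in index order).

    O(V·L²); used as an oracle for the graph-cut solver on strips.
    """
    V, L = unary.shape
    pair = lam * np.abs(np.arange(L)[:, None] - np.arange(L)[None, :])
    cost = unary[0].astype(float).copy()
    back = np.zeros((V, L), dtype=np.intp)
    for v in range(1, V):
        # total[i, j] = best cost ending at label j having had label i at v-1
        total = cost[:, None] + pair
        back[v] = np.argmin(total, axis=0)
        cost = total[back[v], np.arange(L)] + unary[v]
    labels = np.empty(V, dtype=np.intp)
    labels[-1] = int(np.argmin(cost))
    for v in range(V - 1, 0, -1):
        labels[v - 1] = back[v, labels[v]]
    return labels


def solve_exhaustive(unary: np.ndarray, edges: np.ndarray, lam: float) -> np.ndarray:
    """Brute-force enumeration; only for V·log(L) tiny instances."""
    V, L = unary.shape
    if L**V > 2_000_000:
        raise ValueError(f"instance too large for exhaustive search: {L}^{V}")
    best, best_e = None, np.inf
    for labels in itertools.product(range(L), repeat=V):
        e = mrf_energy(np.asarray(labels), unary, edges, lam)
        if e < best_e:
            best, best_e = labels, e
    return np.asarray(best, dtype=np.intp)


def solve_ishikawa(unary: np.ndarray, edges: np.ndarray, lam: float) -> np.ndarray:
    """Globally optimal labeling via a single min-cut.

    Layered construction: each voxel contributes a chain of L-1 nodes;
    cutting the i-th chain arc assigns label i (infinite reverse arcs
    force exactly one cut per chain); inter-voxel arcs of capacity
    ``lam`` between corresponding layers charge lam·|x_u − x_v|.
    Capacities are scaled to integers (int64), so solutions are exact up
    to a ~1e-9 relative rounding of the costs.
    """
    unary = np.asarray(unary, dtype=float)
    V, L = unary.shape
    if L == 1:
        return np.zeros(V, dtype=np.intp)
    edges = np.asarray(edges, dtype=np.intp).reshape(-1, 2)

    scale_ref = max(float(unary.max() - unary.min()), float(lam), 1e-300)
    scale = 1e9 / scale_ref
    u_int = np.round((unary - unary.min(axis=1, keepdims=True)) * scale).astype(np.int64)
    lam_int = np.int64(round(lam * scale))
    INF = np.int64(2**60)

    n_layer = L - 1
    n_nodes = V * n_layer + 2
    source = V * n_layer
    sink = source + 1

    def node(v, i):  # i in 1..L-1
        return v * n_layer + (i - 1)

    rows, cols, caps = [], [], []

    vs = np.arange(V)
    # chain arcs: prev --U[v,i]--> next for i = 0..L-1, plus INF reverse arcs
    for i in range(L):
        prev = np.full(V, source) if i == 0 else node(vs, i)
        nxt = np.full(V, sink) if i == L - 1 else node(vs, i + 1)
        rows.append(prev)
        cols.append(nxt)
        caps.append(u_int[:, i])
    # reverse INF arcs along interior chain segments
    for i in range(1, L - 1):
        rows.append(node(vs, i + 1))
        cols.append(node(vs, i))
        caps.append(np.full(V, INF, dtype=np.int64))

    if len(edges) and lam_int > 0:
        for i in range(1, L):
            a = node(edges[:, 0], i)
            b = node(edges[:, 1], i)
            rows.append(a)
            cols.append(b)
            caps.append(np.full(len(edges), lam_int, dtype=np.int64))
            rows.append(b)
            cols.append(a)
            caps.append(np.full(len(edges), lam_int, dtype=np.int64))

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    caps = np.concatenate(caps)
    graph = csr_array((caps, (rows, cols)), shape=(n_nodes, n_nodes), dtype=np.int64)
    graph.sum_duplicates()

    flow = maximum_flow(graph, int(source), int(sink)).flow
    residual = graph - flow
    residual.data = (residual.data > 0).astype(np.int64)
    residual.eliminate_zeros()
    reach = breadth_first_order(residual, int(source), directed=True, return_predecessors=False)
    in_source_side = np.zeros(n_nodes, dtype=bool)
    in_source_side[reach] = True
    # label = number of this voxel's chain nodes on the source side
    labels = in_source_side[: V * n_layer].reshape(V, n_layer).sum(axis=1)
    return labels.astype(np.intp)
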