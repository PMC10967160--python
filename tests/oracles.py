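"""Independent brute-force oracles for shortest-path quantities.

These enumerate every simple path between every node pair (feasible for
networks of <= 7-8 nodes) and derive closeness, betweenness and their
bridge variants directly from the definitions.  They share only the tie
tolerance with the production code, not any of its algorithmic machinery
(no Dijkstra, no Brandes)."""

from __future__ import annotations

import numpy as np

TOL = 1e-12


def _all_simple_paths(W: np.ndarray, s: int, t: int):
    """Yield (path, length) for every simple s->t path along nonzero edges."""
    p = W.shape[0]

    def extend(path, length):
        v = path[-1]
        if v == t:
            yield list(path), length
            return
        for u in range(p):
            if W[v, u] != 0 and u not in path:
                yield from extend(path + [u], length + 1.0 / abs(W[v, u]))

    yield from extend([s], 0.0)


def _pair_shortest(W: np.ndarray, s: int, t: int):
    """(shortest length, list of shortest paths) between s and t."""
    paths = list(_all_simple_paths(W, s, t))
    if not paths:
        return np.inf, []
    best = min(length for _, length in paths)
    shortest = [path for path, length in paths if length <= best + TOL]
    return best, shortest


def shortest_path_oracle(W: np.ndarray, communities=None):
    """Closeness, betweenness and bridge variants by exhaustive enumeration.

    Betweenness gives pair (j, k), j < k, fractional credit
    (#shortest paths through i) / (#shortest paths) to each interior node.
    Bridge versions restrict targets/pairs to different communities.
    """
    p = W.shape[0]
    comm = None if communities is None else np.asarray(communities)

    dist = np.full((p, p), np.inf)
    betw = np.zeros(p)
    bridge_betw = np.zeros(p)
    for s in range(p):
        dist[s, s] = 0.0
        for t in range(s + 1, p):
            best, shortest = _pair_shortest(W, s, t)
            dist[s, t] = dist[t, s] = best
            if not shortest:
                continue
            cross = comm is not None and comm[s] != comm[t]
            for i in range(p):
                if i in (s, t):
                    continue
                credit = sum(1 for path in shortest if i in path) / len(shortest)
                betw[i] += credit
                if cross:
                    bridge_betw[i] += credit

    closeness = np.zeros(p)
    bridge_closeness = np.zeros(p)
    for i in range(p):
        reach = [j for j in range(p) if j != i and np.isfinite(dist[i, j])]
        if reach:
            closeness[i] = len(reach) / sum(dist[i, j] for j in reach)
        if comm is not None:
            reach_x = [j for j in reach if comm[j] != comm[i]]
            if reach_x:
                bridge_closeness[i] = len(reach_x) / sum(dist[i, j] for j in reach_x)

    out = {"closeness": closeness, "betweenness": betw, "dist": dist}
    if comm is not None:
        out["bridge_closeness"] = bridge_closeness
        out["bridge_betweenness"] = bridge_betw
    return out
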