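"""Node centrality, bridge centrality and layout for weighted networks.

Conventions (standard in psychometric network software):

* strength SC_i = sum_j |w_ij|; expected influence EI_i = sum_j w_ij.
* shortest-path metrics use edge distances d_ij = 1 / |w_ij|;
* closeness CC_i = (number of reachable nodes) / (sum of distances to
  them) — the component-restricted form, so disconnected graphs stay
  finite and isolated nodes get 0;
* betweenness BC_i counts unordered pairs (j, k) whose shortest path runs
  through i, with fractional credit when several shortest paths tie
  (floating-point ties compared with tolerance 1e-12);
* bridge variants restrict the sums/pairs to a pre-specified community
  partition: cross-community neighbors (bridge strength / bridge expected
  influence, 1-step), cross-community targets (bridge closeness), and
  cross-community pairs (bridge betweenness).

Betweenness/closeness are computed by an in-house Dijkstra + Brandes pass
so the tie rule is explicit; the Fruchterman-Reingold layout is delegated
to networkx's seeded spring layout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx

from .ggm import GGMNetwork

__all__ = [
    "strength_and_ei",
    "shortest_path_metrics",
    "centrality_table",
    "bridge_metrics",
    "z_standardize",
    "fruchterman_reingold",
    "distance_matrix",
    "PATH_TIE_TOL",
]

PATH_TIE_TOL = 1e-12


def distance_matrix(W: np.ndarray) -> np.ndarray:
    """Edge distances 1/|w| (inf where there is no edge)."""
    with np.errstate(divide="ignore"):
        D = 1.0 / np.abs(W)
    np.fill_diagonal(D, np.inf)
    return D


def _dijkstra(D: np.ndarray, s: int) -> np.ndarray:
    p = D.shape[0]
    dist = np.full(p, np.inf)
    dist[s] = 0.0
    done = np.zeros(p, dtype=bool)
    for _ in range(p):
        cand = np.where(~done, dist, np.inf)
        u = int(np.argmin(cand))
        if not np.isfinite(cand[u]):
            break
        done[u] = True
        relax = dist[u] + D[u]
        better = relax < dist
        dist[better] = relax[better]
    return dist


def _brandes_pass(
    D: np.ndarray, s: int, target_mask: np.ndarray, tol: float
) -> tuple[np.ndarray, np.ndarray]:
    """Single-source dependencies for betweenness with tolerant tie credit.

    Returns (dist, delta) where delta[w] is the dependency of source s on
    w, summed over targets t with ``target_mask[t]`` true (t != s).
    """
    p = D.shape[0]
    dist = _dijkstra(D, s)
    order = np.argsort(dist, kind="stable")
    finite = order[np.isfinite(dist[order])]

    sigma = np.zeros(p)
    sigma[s] = 1.0
    preds: list[list[int]] = [[] for _ in range(p)]
    for v in finite:
        if v == s:
            continue
        for u in finite:
            if u == v or not np.isfinite(D[u, v]):
                continue
            if abs(dist[u] + D[u, v] - dist[v]) <= tol:
                preds[v].append(u)
                sigma[v] += sigma[u]

    delta = np.zeros(p)
    for v in finite[::-1]:
        if v == s:
            continue
        coeff = (1.0 if (target_mask[v] and v != s) else 0.0) + delta[v]
        for u in preds[v]:
            delta[u] += sigma[u] / sigma[v] * coeff
    delta[s] = 0.0
    return dist, delta


def strength_and_ei(net: GGMNetwork) -> pd.DataFrame:
    """Strength (absolute sum) and expected influence (signed sum)."""
    W = net.weights
    return pd.DataFrame(
        {
            "strength": np.abs(W).sum(axis=1),
            "expected_influence": W.sum(axis=1),
        },
        index=list(net.node_labels),
    )


def shortest_path_metrics(net: GGMNetwork, tol: float = PATH_TIE_TOL) -> pd.DataFrame:
    """Closeness and betweenness on the 1/|w| distance graph."""
    W = net.weights
    p = W.shape[0]
    D = distance_matrix(W)
    all_targets = np.ones(p, dtype=bool)
    closeness = np.zeros(p)
    betweenness = np.zeros(p)
    for s in range(p):
        dist, delta = _brandes_pass(D, s, all_targets, tol)
        reach = np.isfinite(dist) & (np.arange(p) != s)
        if reach.any():
            closeness[s] = reach.sum() / dist[reach].sum()
        betweenness += delta
    betweenness /= 2.0  # each unordered pair counted from both endpoints
    return pd.DataFrame(
        {"closeness": closeness, "betweenness": betweenness},
        index=list(net.node_labels),
    )


def z_standardize(values) -> np.ndarray:
    """(x - mean) / sample SD; all-zero when the SD is zero."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values to standardize")
    sd = arr.std(ddof=1)
    if sd == 0:
        return np.zeros_like(arr)
    return (arr - arr.mean()) / sd


def centrality_table(net: GGMNetwork) -> pd.DataFrame:
    """All four centrality indices plus their z-standardized versions."""
    tab = pd.concat([strength_and_ei(net), shortest_path_metrics(net)], axis=1)
    for col in list(tab.columns):
        tab[f"z_{col}"] = z_standardize(tab[col].to_numpy())
    return tab


def _resolve_communities(
    net: GGMNetwork, communities: dict[str, str] | None
) -> np.ndarray:
    comm = communities if communities is not None else net.communities
    if comm is None:
        raise ValueError("no community partition supplied")
    missing = [v for v in net.node_labels if v not in comm]
    if missing:
        raise ValueError(f"nodes without community assignment: {missing}")
    return np.asarray([comm[v] for v in net.node_labels])


def bridge_metrics(
    net: GGMNetwork,
    communities: dict[str, str] | None = None,
    tol: float = PATH_TIE_TOL,
) -> pd.DataFrame:
    """Bridge strength/EI (1-step cross-community sums), bridge closeness
    (closeness to other communities only) and bridge betweenness
    (shortest paths between cross-community pairs through the node)."""
    labels = _resolve_communities(net, communities)
    W = net.weights
    p = W.shape[0]
    cross = labels[:, None] != labels[None, :]

    Wcross = np.where(cross, W, 0.0)
    bridge_strength = np.abs(Wcross).sum(axis=1)
    bridge_ei = Wcross.sum(axis=1)

    D = distance_matrix(W)
    bridge_closeness = np.zeros(p)
    bridge_betweenness = np.zeros(p)
    for s in range(p):
        target_mask = cross[s]
        dist, delta = _brandes_pass(D, s, target_mask, tol)
        reach = np.isfinite(dist) & target_mask & (np.arange(p) != s)
        if reach.any():
            bridge_closeness[s] = reach.sum() / dist[reach].sum()
        bridge_betweenness += delta
    bridge_betweenness /= 2.0
    tab = pd.DataFrame(
        {
            "bridge_strength": bridge_strength,
            "bridge_expected_influence": bridge_ei,
            "bridge_closeness": bridge_closeness,
            "bridge_betweenness": bridge_betweenness,
        },
        index=list(net.node_labels),
    )
    for col in list(tab.columns):
        tab[f"z_{col}"] = z_standardize(tab[col].to_numpy())
    return tab


def fruchterman_reingold(
    net: GGMNetwork, seed: int = 0, iterations: int = 50
) -> pd.DataFrame:
    """Seeded force-directed (Fruchterman-Reingold) node coordinates.

    Attraction is proportional to |w_ij|, so strongly connected nodes end
    up central and weakly connected ones peripheral.
    """
    labels = list(net.node_labels)
    if len(labels) == 1:
        return pd.DataFrame({"x": [0.0], "y": [0.0]}, index=labels)
    G = nx.Graph()
    G.add_nodes_from(labels)
    p = len(labels)
    for i in range(p):
        for j in range(i + 1, p):
            w = abs(net.weights[i, j])
            if w > 0:
                G.add_edge(labels[i], labels[j], weight=w)
    pos = nx.spring_layout(G, weight="weight", iterations=iterations, seed=seed)
    xy = np.array([pos[v] for v in labels])
    return pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1]}, index=labels)
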