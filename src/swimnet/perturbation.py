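"""Degree-preserving null model and attack-robustness analysis.

The null model rewires the network by double-edge swaps, keeping every
node's degree exactly while shuffling who is connected to whom; edge
weights travel with the first-named endpoint of each swapped edge.
Robustness is probed by deleting nodes of a chosen class in decreasing
intact-network degree order and tracking the average shortest path
(unweighted; disconnected pairs excluded from the mean).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy.sparse.csgraph import shortest_path

from .network import WEIGHT

NODE_CLASSES = ("total-hubs", "party", "date", "fight-club", "switch", "random")

RANDOMIZATION_FLAG = "randomization_degenerate"


def degree_preserving_randomization(
    net: nx.Graph,
    seed: int,
    swap_factor: int = 10,
) -> nx.Graph:
    """Shuffle edges while preserving every node's degree.

    Attempts ``swap_factor * |E|`` double-edge swaps; a proposed swap
    (a-b, c-d) -> (a-d, c-b) is rejected unless all four endpoints are
    distinct and neither new edge already exists, so the result stays a
    simple graph.  If no swap succeeds (e.g. a star or triangle, where
    no legal swap exists) the input is returned unchanged with the
    ``randomization_degenerate`` graph flag set and a warning.
    """
    if net.number_of_edges() < 2:
        raise ValueError("randomization needs at least 2 edges")
    rng = np.random.default_rng(seed)
    out = net.copy()
    edges = [tuple(e) for e in out.edges()]
    n_edges = len(edges)
    attempts = swap_factor * n_edges
    swapped = 0
    pair_draws = rng.integers(0, n_edges, size=(attempts, 2))
    flip_draws = rng.random(attempts) < 0.5
    for (i, j), flip in zip(pair_draws, flip_draws):
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if flip:
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        if out.has_edge(a, d) or out.has_edge(c, b):
            continue
        w_ab = out[a][b][WEIGHT]
        w_cd = out[c][d][WEIGHT]
        out.remove_edge(a, b)
        out.remove_edge(c, d)
        out.add_edge(a, d, weight=w_ab)
        out.add_edge(c, b, weight=w_cd)
        edges[i] = (a, d)
        edges[j] = (c, b)
        swapped += 1
    if swapped == 0:
        warnings.warn("no legal double-edge swap found; returning network unchanged")
        out.graph[RANDOMIZATION_FLAG] = True
    if dict(out.degree()) != dict(net.degree()):  # defining invariant
        raise RuntimeError("degree sequence changed during randomization")
    return out


def _asp_from_adjacency(adj) -> float:
    """Mean unweighted shortest path over reachable pairs (NaN if no edges)."""
    dist = shortest_path(adj, method="D", unweighted=True, directed=False)
    mask = np.isfinite(dist)
    np.fill_diagonal(mask, False)
    if not mask.any():
        return float("nan")
    return float(dist[mask].mean())


def average_shortest_path(net: nx.Graph) -> float:
    """Mean of BFS shortest-path lengths over all connected node pairs.

    Pairs in different components are excluded from the mean; a network
    with no edges has no defined value (NaN).
    """
    if net.number_of_nodes() < 2:
        raise ValueError("average shortest path needs at least 2 nodes")
    if net.number_of_edges() == 0:
        return float("nan")
    adj = nx.to_scipy_sparse_array(net, weight=None, format="csr")
    return _asp_from_adjacency(adj)


@dataclass
class RobustnessCurve:
    """Average shortest path after cumulative node removals."""

    node_class: str
    removed_fraction: np.ndarray
    avg_shortest_path: np.ndarray
    repeats: int | None = None
    removed_nodes: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": self.node_class,
                "step": np.arange(len(self.removed_fraction)),
                "removed_fraction": self.removed_fraction,
                "avg_shortest_path": self.avg_shortest_path,
            }
        )


def _removal_trace(adj_dense: np.ndarray, order: list[int]) -> np.ndarray:
    """ASP of the intact network and after each cumulative removal."""
    n = adj_dense.shape[0]
    alive = np.ones(n, dtype=bool)
    trace = [_asp_from_adjacency(adj_dense)]
    for idx in order:
        alive[idx] = False
        sub = adj_dense[np.ix_(alive, alive)]
        if sub.shape[0] < 2 or sub.sum() == 0:
            trace.append(float("nan"))
        else:
            trace.append(_asp_from_adjacency(sub))
    return np.asarray(trace)


def robustness_curve(
    net: nx.Graph,
    cart: pd.DataFrame,
    node_class: str,
    n_remove: int,
    seed: int = 0,
    repeats: int = 50,
) -> RobustnessCurve:
    """Average shortest path as nodes of one class are deleted.

    Non-random classes are removed one at a time in decreasing degree
    order (degree frozen on the intact network; ties broken by node
    id).  The ``random`` class repeats the experiment ``repeats`` times
    with independently seeded uniform draws over all nodes and reports
    the mean curve.  If the class holds fewer than ``n_remove`` members,
    all of them are used (with a warning).
    """
    if node_class not in NODE_CLASSES:
        raise ValueError(f"unknown node class {node_class!r}; choose from {NODE_CLASSES}")
    nodes = list(net.nodes)
    index_of = {node: i for i, node in enumerate(nodes)}
    adj = nx.to_scipy_sparse_array(net, nodelist=nodes, weight=None, format="csr").toarray()

    if node_class == "random":
        rng_root = np.random.SeedSequence(seed)
        n_remove = min(n_remove, len(nodes))
        traces = []
        for child in rng_root.spawn(repeats):
            rng = np.random.default_rng(child)
            picks = rng.choice(len(nodes), size=n_remove, replace=False)
            traces.append(_removal_trace(adj, list(picks)))
        curve = np.mean(traces, axis=0)
        removed: list = []
    else:
        if node_class == "total-hubs":
            members = cart.index[cart["hub_class"].isin(["date", "party", "fight-club"])]
        elif node_class == "switch":
            members = cart.index[cart["is_switch"]]
        else:
            members = cart.index[cart["hub_class"] == node_class]
        members = [m for m in members if m in index_of]
        if len(members) < n_remove:
            warnings.warn(
                f"class {node_class!r} has only {len(members)} members; removing all of them"
            )
            n_remove = len(members)
        ranked = sorted(members, key=lambda m: (-net.degree(m), str(m)))[:n_remove]
        curve = _removal_trace(adj, [index_of[m] for m in ranked])
        removed = ranked

    fractions = np.arange(len(curve)) / len(nodes)
    return RobustnessCurve(
        node_class=node_class,
        removed_fraction=fractions,
        avg_shortest_path=curve,
        repeats=repeats if node_class == "random" else None,
        removed_nodes=removed,
    )
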