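"""Signed Pearson co-expression network and average neighbor correlation.

Nodes are genes (typically the DEGs); an undirected edge joins two genes
when the absolute Pearson correlation of their expression profiles over
all pooled samples strictly exceeds a cutoff.  Edge weights keep the
*signed* correlation — the sign is what lets the average Pearson
correlation coefficient over a node's neighborhood (APCC) go negative,
the defining feature of fight-club hubs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx

from .expression import ExpressionMatrix

WEIGHT = "weight"


def correlation_matrix(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Pearson correlation between all gene pairs over all S samples.

    Symmetric with unit diagonal; raises if any gene has zero variance
    (its correlation would be undefined) or fewer than 3 samples exist.
    """
    vals = matrix.values.to_numpy(dtype=float)
    if vals.shape[1] < 3:
        raise ValueError("correlation needs at least 3 samples")
    sd = vals.std(axis=1)
    if np.any(sd == 0):
        bad = matrix.values.index[np.flatnonzero(sd == 0)[0]]
        raise ValueError(f"gene {bad!r} has zero variance; correlation undefined")
    corr = np.corrcoef(vals)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=matrix.values.index, columns=matrix.values.index)


def _check_corr(corr: pd.DataFrame) -> None:
    arr = corr.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(arr), 1.0, atol=1e-10):
        raise ValueError("correlation matrix must have unit diagonal")


def build_network(corr: pd.DataFrame, rho_threshold: float) -> nx.Graph:
    """Threshold the correlation matrix into a signed-weight graph.

    Edge (i, j) exists iff ``|corr[i, j]| > rho_threshold`` (strict);
    the edge weight is the signed correlation.  Genes with no edge are
    kept as isolated nodes.
    """
    if not 0 < rho_threshold < 1:
        raise ValueError("rho_threshold must be in the open interval (0, 1)")
    _check_corr(corr)
    arr = corr.to_numpy(dtype=float)
    nodes = list(corr.index)
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    iu, ju = np.triu_indices(len(nodes), k=1)
    mask = np.abs(arr[iu, ju]) > rho_threshold
    graph.add_weighted_edges_from(
        (nodes[i], nodes[j], float(arr[i, j])) for i, j in zip(iu[mask], ju[mask])
    )
    return graph


def largest_component_fraction(graph: nx.Graph) -> float:
    """Fraction of nodes in the largest connected component."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    biggest = max((len(c) for c in nx.connected_components(graph)), default=0)
    return biggest / graph.number_of_nodes()


def threshold_scan(corr: pd.DataFrame, thresholds) -> pd.DataFrame:
    """Edge count and largest-component fraction at each cutoff.

    Advisory output for picking the correlation threshold: the user
    wants as few edges as possible while keeping the network in one
    piece.  Thresholds must be ascending.
    """
    thresholds = list(thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly ascending")
    rows = []
    for thr in thresholds:
        net = build_network(corr, thr)
        rows.append(
            {
                "threshold": thr,
                "n_edges": net.number_of_edges(),
                "largest_component_fraction": largest_component_fraction(net),
            }
        )
    return pd.DataFrame(rows)


def compute_apcc(net: nx.Graph) -> pd.Series:
    """Average Pearson correlation coefficient of each node's neighborhood.

    APCC(i) is the mean of the signed weights of edges incident to i.
    Isolated nodes get NaN and are excluded from hub classification.
    """
    out = {}
    for node in net.nodes:
        weights = [d[WEIGHT] for _, _, d in net.edges(node, data=True)]
        out[node] = float(np.mean(weights)) if weights else np.nan
    return pd.Series(out, name="apcc")
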