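"""k-means partitioning of expression profiles under correlation distance.

Lloyd-style k-means where the proximity of two profiles x, y is
dist(x, y) = 1 - rho(x, y) (Pearson), the objective is the sum of
squared distances to cluster centroids (SSE), and centroids are the
coordinate-wise means of member profiles.  Many randomly initialized
replicates are run and the partition with the lowest SSE wins.  The
number of clusters k is a user choice, guided by the scree (SSE vs k)
output; elbow picking is deliberately not automated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class Partition:
    """Best-of-replicates clustering result.

    ``assignment`` maps node -> module id in 1..k; ``sse`` is the
    minimum over ``replicate_sses``; ``sse_trajectory`` records the
    per-iteration SSE of the winning replicate (nonincreasing).
    """

    assignment: pd.Series
    sse: float
    k: int
    replicate_sses: list = field(default_factory=list)
    sse_trajectory: list = field(default_factory=list)

    def members(self, module: int) -> list:
        return list(self.assignment.index[self.assignment == module])

    @property
    def module_ids(self) -> list:
        return sorted(set(self.assignment))


def correlation_distance(x, y) -> float:
    """1 - Pearson correlation; 0 for identical shape, 2 for exact inversion."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must have equal length")
    if x.size < 3:
        raise ValueError("profiles need length >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValueError("zero-variance profile; correlation distance undefined")
    return float(1.0 - (xc @ yc) / denom)


def _standardize_rows(arr: np.ndarray, what: str) -> np.ndarray:
    """Center and scale rows to zero mean, unit norm (for fast Pearson)."""
    centered = arr - arr.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError(f"zero-variance {what}; correlation distance undefined")
    return centered / norms


def _sse(dist_to_own: np.ndarray) -> float:
    return float(np.sum(dist_to_own**2))


def partition_sse(profiles: pd.DataFrame, assignment: pd.Series) -> float:
    """SSE of a given assignment: sum over nodes of dist(centroid, x)^2."""
    total = 0.0
    for module in sorted(set(assignment)):
        members = assignment.index[assignment == module]
        block = profiles.loc[members].to_numpy(dtype=float)
        centroid = block.mean(axis=0)
        for row in block:
            total += correlation_distance(centroid, row) ** 2
    return total


def _lloyd(z: np.ndarray, raw: np.ndarray, k: int, max_iterations: int, rng: np.random.Generator):
    """One replicate: random-profile init, iterate until assignments settle.

    Returns (labels, sse, trajectory).  The coordinate-mean centroid is
    not the exact minimizer of the squared correlation distance, so an
    iteration that would raise the SSE stops the replicate at the
    previous state; the recorded trajectory is therefore nonincreasing.
    """
    n = raw.shape[0]
    centroids = raw[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    best_sse = np.inf
    trajectory: list = []
    for _ in range(max_iterations):
        zc = _standardize_rows(centroids, "centroid")
        dist = 1.0 - z @ zc.T  # (n, k) correlation distances
        new_labels = np.argmin(dist, axis=1)

        # empty-cluster repair: give the point farthest from its centroid
        # to each empty cluster (one repair pass per iteration)
        own = dist[np.arange(n), new_labels].copy()
        for cluster in range(k):
            if not np.any(new_labels == cluster):
                farthest = int(np.argmax(own))
                new_labels[farthest] = cluster
                own[farthest] = -np.inf
        new_sse = _sse(dist[np.arange(n), new_labels])

        if new_sse > best_sse + 1e-12:
            break
        converged = np.array_equal(new_labels, labels)
        labels = new_labels
        best_sse = new_sse
        trajectory.append(new_sse)
        if converged:
            break
        # a cluster can (rarely) be emptied by the repair pass itself;
        # keep its previous centroid in that case
        centroids = np.vstack(
            [
                raw[labels == c].mean(axis=0) if np.any(labels == c) else centroids[c]
                for c in range(k)
            ]
        )
    return labels, best_sse, trajectory


def kmeans_partition(
    profiles: pd.DataFrame,
    k: int,
    replicates: int = 100,
    max_iterations: int = 300,
    seed: int | np.random.SeedSequence = 0,
) -> Partition:
    """Best-of-``replicates`` k-means under correlation distance.

    ``profiles`` is nodes x features.  Initial centroids of each
    replicate are ``k`` distinct profiles drawn over the canonical
    (sorted-by-node-id) order, so results do not depend on input row
    order.  Deterministic given (seed, replicates, k).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > profiles.shape[0]:
        raise ValueError(f"k={k} exceeds the number of profiles ({profiles.shape[0]})")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")

    profiles = profiles.sort_index(kind="mergesort")
    raw = profiles.to_numpy(dtype=float)
    z = _standardize_rows(raw, "profile")

    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    best = None
    replicate_sses = []
    for child in root.spawn(replicates):
        rng = np.random.default_rng(child)
        labels, sse, trajectory = _lloyd(z, raw, k, max_iterations, rng)
        replicate_sses.append(sse)
        if best is None or sse < best[1]:
            best = (labels, sse, trajectory)

    labels, sse, trajectory = best
    # relabel modules 1..k by first appearance over the canonical order
    order: dict = {}
    for lab in labels:
        if lab not in order:
            order[lab] = len(order) + 1
    assignment = pd.Series([order[lab] for lab in labels], index=profiles.index, name="module")
    return Partition(
        assignment=assignment,
        sse=float(sse),
        k=k,
        replicate_sses=[float(s) for s in replicate_sses],
        sse_trajectory=[float(s) for s in trajectory],
    )


def scree(
    profiles: pd.DataFrame,
    k_values,
    replicates: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Best SSE per k, for elbow inspection.

    Each k gets its own derived random stream, so adding or removing
    values from ``k_values`` never changes the result at the other ks.
    """
    k_values = list(k_values)
    if any(b <= a for a, b in zip(k_values, k_values[1:])):
        raise ValueError("k_values must be strictly ascending")
    rows = []
    for k in k_values:
        part = kmeans_partition(
            profiles,
            k,
            replicates=replicates,
            seed=np.random.SeedSequence([seed, k]),
        )
        rows.append({"k": k, "sse": part.sse})
    return pd.DataFrame(rows)
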