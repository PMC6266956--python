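"""Node role cartography: K_pi, z_g, R1-R7 regions, hub classes, switch genes.

Given the co-expression network and its module partition, every node
gets two coordinates:

* the clusterphobic coefficient ``K_pi = 1 - (k_in / k)^2`` — how much a
  node links *outside* its own module (0 = all links internal, near 1 =
  mostly external);
* the within-module degree ``z_g = (k_in - mean) / sd`` — a z-score of
  the node's internal degree against its module's internal-degree
  distribution (population sd; sd = 0 maps to z_g = 0).

The (K_pi, z_g) plane is carved into seven roles R1-R7 (local hubs are
z_g >= 2.5).  Hubs (degree strictly exceeding a threshold, default 5)
are classed by their average neighbor correlation (APCC): negative =
fight-club, low positive = date, high positive = party.  Switch genes
are the fight-club hubs that sit in region R4 (z_g < 2.5, K_pi > 0.8).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx

from .clustering import Partition
from .network import compute_apcc


@dataclass(frozen=True)
class RegionBounds:
    """Boundaries of the seven-role cartography (all configurable)."""

    r1_max: float = 0.05   # non-hub: K_pi <= r1_max -> R1 (ultra-peripheral)
    r2_max: float = 0.625  # K_pi <= r2_max -> R2 (peripheral)
    r3_max: float = 0.8    # K_pi <= r3_max -> R3 (connector); above -> R4 (kinless)
    r5_max: float = 0.30   # hub: K_pi <= r5_max -> R5 (provincial hub)
    r6_max: float = 0.75   # K_pi <= r6_max -> R6 (connector hub); above -> R7 (kinless hub)
    z_cut: float = 2.5     # z_g >= z_cut marks a local hub


DEFAULT_BOUNDS = RegionBounds()

ROLE_NAMES = {
    "R1": "Ultra-peripheral",
    "R2": "Peripheral",
    "R3": "Non-hub connector",
    "R4": "Non-hub kinless",
    "R5": "Provincial hub",
    "R6": "Connector hub",
    "R7": "Kinless hub",
}

ISOLATED = "isolated"


def _internal_degree(net: nx.Graph, assignment, node) -> int:
    """Number of incident edges whose other endpoint shares the module.

    Edge-weight signs are ignored: K_pi and z_g count links, only APCC
    uses the signed weights.
    """
    if isinstance(assignment, pd.Series):
        assignment = assignment.to_dict()
    module = assignment[node]
    return sum(1 for nbr in net.neighbors(node) if assignment.get(nbr) == module)


def _internal_degrees(net: nx.Graph, assignment: pd.Series) -> dict:
    """Internal degree of every network node, computed in one pass."""
    amap = assignment.to_dict()
    return {
        node: sum(1 for nbr in net.neighbors(node) if amap.get(nbr) == amap[node])
        for node in net.nodes
    }


def clusterphobic_coefficient(net: nx.Graph, partition: Partition, node) -> float:
    """K_pi = 1 - (k_in / k)^2; NaN marker for isolated nodes."""
    k = net.degree(node)
    if k == 0:
        return np.nan
    k_in = _internal_degree(net, partition.assignment, node)
    return 1.0 - (k_in / k) ** 2


def within_module_degree(
    net: nx.Graph,
    partition: Partition,
    node,
    statistic: str = "internal",
    ddof: int = 0,
) -> float:
    """z_g of one node; see :func:`build_cartography` for the conventions."""
    assignment = partition.assignment
    members = assignment.index[assignment == assignment[node]]
    amap = assignment.to_dict()
    if statistic == "internal":
        values = np.array([_internal_degree(net, amap, m) for m in members], dtype=float)
    elif statistic == "total":
        values = np.array([net.degree(m) for m in members], dtype=float)
    else:
        raise ValueError("statistic must be 'internal' or 'total'")
    k_in = _internal_degree(net, amap, node)
    sd = values.std(ddof=ddof) if len(values) > ddof else 0.0
    if sd == 0:
        return 0.0
    return float((k_in - values.mean()) / sd)


def assign_region(K_pi: float, z_g: float, bounds: RegionBounds = DEFAULT_BOUNDS) -> str:
    """Map a (K_pi, z_g) pair to one of the seven roles R1-R7."""
    if not 0.0 <= K_pi <= 1.0:
        raise ValueError(f"K_pi must be in [0, 1], got {K_pi}")
    if z_g < bounds.z_cut:
        if K_pi <= bounds.r1_max:
            return "R1"
        if K_pi <= bounds.r2_max:
            return "R2"
        if K_pi <= bounds.r3_max:
            return "R3"
        return "R4"
    if K_pi <= bounds.r5_max:
        return "R5"
    if K_pi <= bounds.r6_max:
        return "R6"
    return "R7"


def classify_hubs(
    net: nx.Graph,
    apcc: pd.Series,
    hub_degree_threshold: int = 5,
    apcc_split: float = 0.5,
) -> pd.Series:
    """date / party / fight-club / non-hub per node.

    A hub is a node whose degree strictly exceeds ``hub_degree_threshold``
    (default 5, i.e. degree >= 6).  Hubs with negative APCC are
    fight-club hubs; nonnegative APCC below ``apcc_split`` marks date
    hubs, at or above it party hubs.  Isolated nodes are flagged as such.
    """
    out = {}
    for node in net.nodes:
        k = net.degree(node)
        if k == 0:
            out[node] = ISOLATED
        elif k <= hub_degree_threshold:
            out[node] = "non-hub"
        elif apcc[node] < 0:
            out[node] = "fight-club"
        elif apcc[node] < apcc_split:
            out[node] = "date"
        else:
            out[node] = "party"
    return pd.Series(out, name="hub_class")


def build_cartography(
    net: nx.Graph,
    partition: Partition,
    apcc: pd.Series | None = None,
    hub_degree_threshold: int = 5,
    apcc_split: float = 0.5,
    bounds: RegionBounds = DEFAULT_BOUNDS,
    zg_statistic: str = "internal",
    zg_ddof: int = 0,
) -> pd.DataFrame:
    """Full per-node role table.

    ``zg_statistic`` selects whether the module mean/sd behind z_g are
    taken over members' internal degrees (default, consistent with the
    k_in numerator) or their total degrees; ``zg_ddof=0`` uses the
    population standard deviation.

    Returns a DataFrame indexed by node with columns module, degree,
    k_in, k_pi, z_g, apcc, region, hub_class, is_switch.  Isolated
    nodes carry NaN coordinates and the 'isolated' marker; they never
    qualify as hubs or switch genes.
    """
    assignment = partition.assignment
    missing = [n for n in net.nodes if n not in assignment.index]
    if missing:
        raise ValueError(f"node {missing[0]!r} has no module assignment")
    if apcc is None:
        apcc = compute_apcc(net)
    hub_class = classify_hubs(net, apcc, hub_degree_threshold, apcc_split)

    k_in_all = _internal_degrees(net, assignment)
    members_of: dict = {}
    for node in net.nodes:
        members_of.setdefault(assignment[node], []).append(node)
    module_stats = {}
    for module, members in members_of.items():
        if zg_statistic == "internal":
            values = np.array([k_in_all[m] for m in members], dtype=float)
        elif zg_statistic == "total":
            values = np.array([net.degree(m) for m in members], dtype=float)
        else:
            raise ValueError("zg_statistic must be 'internal' or 'total'")
        sd = values.std(ddof=zg_ddof) if len(values) > zg_ddof else 0.0
        module_stats[module] = (values.mean(), sd)

    rows = []
    for node in net.nodes:
        k = net.degree(node)
        if k == 0:
            rows.append(
                {
                    "node": node,
                    "module": assignment[node],
                    "degree": 0,
                    "k_in": 0,
                    "k_pi": np.nan,
                    "z_g": np.nan,
                    "apcc": np.nan,
                    "region": ISOLATED,
                    "hub_class": ISOLATED,
                    "is_switch": False,
                }
            )
            continue
        k_in = k_in_all[node]
        k_pi = 1.0 - (k_in / k) ** 2
        mean, sd = module_stats[assignment[node]]
        z_g = 0.0 if sd == 0 else float((k_in - mean) / sd)
        region = assign_region(k_pi, z_g, bounds)
        is_switch = (
            hub_class[node] == "fight-club" and z_g < bounds.z_cut and k_pi > bounds.r3_max
        )
        rows.append(
            {
                "node": node,
                "module": assignment[node],
                "degree": k,
                "k_in": k_in,
                "k_pi": k_pi,
                "z_g": z_g,
                "apcc": float(apcc[node]),
                "region": region,
                "hub_class": hub_class[node],
                "is_switch": bool(is_switch),
            }
        )
    table = pd.DataFrame(rows).set_index("node")
    return table.sort_index(kind="mergesort")


def find_switch_genes(cart: pd.DataFrame) -> list:
    """Switch genes sorted by ascending APCC, ties broken by node id.

    Switch genes are the fight-club hubs that are not hubs in their own
    module (z_g < 2.5) and link mostly outside it (K_pi > 0.8, region
    R4); being fight-club already implies APCC < 0.
    """
    hits = cart[cart["is_switch"]]
    ordered = hits.sort_index(kind="mergesort").sort_values("apcc", kind="mergesort")
    return list(ordered.index)


def histogram_modes(
    values,
    bin_width: float = 0.1,
    vmin: float = -1.0,
    vmax: float = 1.0,
    min_count: int | None = None,
) -> list:
    """Kernel-free bin-count mode detection over a bounded range.

    A mode is a maximal run of adjacent histogram bins whose counts all
    reach ``min_count``, separated from the next run by at least one
    under-populated bin.  ``min_count`` defaults to 2% of the sample
    (at least 2), so sparsely populated bridge bins do not fuse two
    peaks.  Returns the count-weighted center of each run, ascending.
    Used to check the trimodality of the hub APCC distribution
    (negative / low-positive / high-positive peaks).
    """
    values = np.asarray(list(values), dtype=float)
    values = values[~np.isnan(values)]
    if min_count is None:
        min_count = max(2, int(np.ceil(0.02 * values.size)))
    edges = np.arange(vmin, vmax + bin_width / 2, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    modes = []
    run_counts: list = []
    run_centers: list = []
    for count, center in zip(counts, centers):
        if count >= min_count:
            run_counts.append(count)
            run_centers.append(center)
        elif run_counts:
            modes.append(float(np.average(run_centers, weights=run_counts)))
            run_counts, run_centers = [], []
    if run_counts:
        modes.append(float(np.average(run_centers, weights=run_counts)))
    return modes
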