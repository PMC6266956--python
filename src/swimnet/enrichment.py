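"""Hypergeometric over-representation of a gene list in gene-set collections.

The tail probability follows the convention in which the universe counts
*interactions* (gene-set membership pairs) rather than genes: with M the
total number of interactions in the collection, K the interactions of
the selected set, N the query genes recognized by the collection (member
of at least one set), and X the query genes inside the selected set,

    p = P[hypergeom(M, K, N) >= X] = 1 - sum_{i<X} C(K,i) C(M-K,N-i) / C(M,N).

A conventional gene-counting universe is available behind
``universe="genes"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

ENRICHMENT_COLUMNS = ["set_id", "M", "K", "N", "X", "p_value", "fdr"]


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. one set per miRNA family of target genes)."""

    sets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {sid: frozenset(members) for sid, members in self.sets.items()}
        for sid, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {sid!r} is empty")

    @property
    def universe_genes(self) -> frozenset:
        out: set = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)

    @property
    def n_interactions(self) -> int:
        """Total number of (gene, set) membership pairs in the collection."""
        return sum(len(members) for members in self.sets.values())


def hypergeometric_p(M: int, K: int, N: int, X: int) -> float:
    """Upper-tail hypergeometric probability P[draws >= X].

    Log-space combinatorics (scipy) keep this stable for universes up to
    ~1e7 interactions.  X = 0 gives p = 1 by construction.
    """
    for name, val in (("M", M), ("K", K), ("N", N), ("X", X)):
        if int(val) != val or val < 0:
            raise ValueError(f"{name} must be a nonnegative integer, got {val}")
    if K > M or N > M:
        raise ValueError("K and N must not exceed M")
    if X > min(K, N):
        raise ValueError("X cannot exceed min(K, N)")
    return float(hypergeom.sf(X - 1, M, K, N))


def enrich(query, collection: GeneSetCollection, universe: str = "interactions") -> pd.DataFrame:
    """One hypergeometric test per set; rows sorted by ascending p-value.

    ``universe="interactions"`` (default) counts membership pairs for M
    and set sizes for K; ``universe="genes"`` counts distinct genes.
    N is always the number of query genes present in at least one set,
    X the query genes inside the tested set.  BH-adjusted values are
    appended, but the ordering stays by raw p.
    """
    query = list(query)
    if not query:
        raise ValueError("query gene list is empty")
    if universe not in ("interactions", "genes"):
        raise ValueError("universe must be 'interactions' or 'genes'")
    if not collection.sets:
        raise ValueError("gene-set collection is empty")

    query_set = set(query)
    recognized = query_set & collection.universe_genes
    if not recognized:
        warnings.warn("query is disjoint from the collection universe; all p-values are 1")
    N = len(recognized)
    M = collection.n_interactions if universe == "interactions" else len(collection.universe_genes)

    rows = []
    for set_id in sorted(collection.sets):
        members = collection.sets[set_id]
        K = len(members)
        X = len(query_set & members)
        rows.append(
            {
                "set_id": set_id,
                "M": M,
                "K": K,
                "N": N,
                "X": X,
                "p_value": hypergeometric_p(M, K, N, X),
            }
        )
    table = pd.DataFrame(rows)
    table["fdr"] = multipletests(table["p_value"].to_numpy(), method="fdr_bh")[1]
    table = table.sort_values(["p_value", "set_id"], kind="mergesort").reset_index(drop=True)
    return table[ENRICHMENT_COLUMNS]
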