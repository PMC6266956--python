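"""Shared fixtures: small handcrafted matrices and one full default-preset run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import swimnet as sw
from swimnet.synthetic import SimulationConfig, generate_expression


def make_matrix(values, gene_ids, n_a, n_b, scale="log2"):
    """ExpressionMatrix from a raw array with n_a condition-A samples first."""
    values = np.asarray(values, dtype=float)
    samples = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
    return sw.ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=samples),
        condition=pd.Series(["A"] * n_a + ["B"] * n_b, index=samples),
        scale=scale,
    )


@pytest.fixture
def small_matrix():
    """6 genes x 8 samples, log2 scale, with planted contrasts."""
    rng = np.random.default_rng(42)
    base = rng.normal(5, 1, size=(6, 8))
    base[0, :4] += 3.0  # up in A
    base[1, :4] -= 3.0  # down in A
    return make_matrix(base, [f"g{i}" for i in range(6)], 4, 4)


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline products on the default synthetic preset (seed 1)."""
    config = SimulationConfig(seed=1)
    matrix, truth = generate_expression(config)
    deg = sw.differential_expression(matrix, 1.5, 0.05)
    sub = matrix.subset_genes(deg["gene_id"])
    corr = sw.correlation_matrix(sub)
    net = sw.build_network(corr, 0.71)
    partition = sw.kmeans_partition(sub.values, 3, replicates=100, seed=1)
    cart = sw.build_cartography(net, partition)
    return {
        "config": config,
        "matrix": matrix,
        "truth": truth,
        "deg": deg,
        "deg_matrix": sub,
        "corr": corr,
        "net": net,
        "partition": partition,
        "cart": cart,
        "switch": sw.find_switch_genes(cart),
    }
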