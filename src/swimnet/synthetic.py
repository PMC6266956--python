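"""Seeded generators for two-condition expression data with planted structure.

The expression generator uses a latent-factor model: each co-expression
module is driven by one standard-normal factor per sample, and a gene
in that module is ``baseline + condition shift + noise_sd * (a * factor
+ sqrt(1 - a^2) * eps)`` with loading ``a = sqrt(intra_module_rho)``, so
the expected within-module (within-condition) Pearson correlation is
``intra_module_rho``.  Planted switch-like regulators load *negatively*
on the first module's factor (expected gene-regulator correlation
``regulator_anticorr_rho``) and are shifted down in condition A while
module genes are shifted up, mirroring down-regulated anti-correlated
regulators of an activated module.  Filler genes are i.i.d. noise.

Note the condition shifts add between-condition covariance on top of
the factor structure, so pooled-sample correlations exceed the
within-condition targets — exactly the property that makes the planted
regulators strongly anti-correlated with module 1 in the pooled
network.

All randomness derives from a single seed through named substreams
(one per generator), so e.g. adding gene sets never perturbs the
expression values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection
from .expression import ExpressionMatrix

_STREAMS = {"expression": 0, "genesets": 1, "clinical": 2}


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic two-condition dataset.

    Defaults plant 3 modules of 100 genes plus 20 anti-correlated
    down-regulated regulators among 1000 genes over 15 + 15 samples,
    with within-module correlation 0.8, regulator-module correlation
    -0.7 and a log2 fold-change of 2 on log2-scale intensities.
    """

    n_genes: int = 1000
    n_samples_a: int = 15
    n_samples_b: int = 15
    n_modules: int = 3
    module_sizes: tuple = (100, 100, 100)
    intra_module_rho: float = 0.8
    n_switch_regulators: int = 20
    regulator_anticorr_rho: float = -0.7
    de_log_fc: float = 2.0
    noise_sd: float = 1.0
    baseline_range: tuple = (4.0, 8.0)
    seed: int = 1

    def __post_init__(self) -> None:
        self.module_sizes = tuple(self.module_sizes)
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes must have n_modules entries")
        if sum(self.module_sizes) + self.n_switch_regulators > self.n_genes:
            raise ValueError("module sizes plus regulators exceed n_genes")
        if not 0 < self.intra_module_rho < 1:
            raise ValueError("intra_module_rho must be in (0, 1)")
        if not -1 < self.regulator_anticorr_rho < 0:
            raise ValueError("regulator_anticorr_rho must be in (-1, 0)")
        if abs(self.regulator_anticorr_rho) >= np.sqrt(self.intra_module_rho):
            raise ValueError(
                "infeasible correlation targets: |regulator_anticorr_rho| must be "
                "< sqrt(intra_module_rho) for a one-factor construction"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_samples_a < 2 or self.n_samples_b < 2:
            raise ValueError("each condition needs at least 2 samples")

    def stream(self, name: str) -> np.random.Generator:
        """Named, order-independent substream of the master seed."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, _STREAMS[name]]))


TRUTH_COLUMNS = ["gene_id", "module", "is_regulator", "is_de", "true_log_fc"]


def _latent_factors(rng: np.random.Generator, n_modules: int, in_a: np.ndarray) -> np.ndarray:
    """One standard-normal factor per module, decorrelated per condition.

    The module programs are independent by design, but with few samples
    chance correlation between two raw factor draws (sd ~ 1/sqrt(n))
    would leak into *every* gene pair of the two modules at once.  Each
    factor realization is therefore centered, orthogonalized against
    the other factors and scaled to unit variance within each condition
    block, enforcing the designed independence — and keeping the
    planted fold-change unconfounded by factor sampling noise.
    """
    factors = rng.standard_normal((n_modules, in_a.size))
    for mask in (in_a, ~in_a):
        block = factors[:, mask] - factors[:, mask].mean(axis=1, keepdims=True)
        if mask.sum() > n_modules:
            q, r = np.linalg.qr(block.T)
            q = q * np.sign(np.diag(r))  # keep each factor's original direction
            block = (q * np.sqrt(mask.sum())).T
        factors[:, mask] = block
    return factors


def generate_expression(config: SimulationConfig):
    """Simulate the two-condition matrix; returns (ExpressionMatrix, truth).

    Truth is a DataFrame with one row per gene: planted module id (0 =
    none; regulators carry the module they regulate), regulator flag,
    differential-expression flag and the planted log2 fold-change
    (module genes +de_log_fc in condition A, regulators -de_log_fc).
    """
    rng = config.stream("expression")
    n_a, n_b = config.n_samples_a, config.n_samples_b
    n_samples = n_a + n_b
    n_module_genes = sum(config.module_sizes)
    n_reg = config.n_switch_regulators

    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    sample_ids = [f"A{i + 1:02d}" for i in range(n_a)] + [f"B{i + 1:02d}" for i in range(n_b)]
    in_a = np.array([1] * n_a + [0] * n_b, dtype=bool)

    factors = _latent_factors(rng, config.n_modules, in_a)
    baseline = rng.uniform(*config.baseline_range, size=config.n_genes)
    noise = rng.standard_normal((config.n_genes, n_samples))

    module_of = np.zeros(config.n_genes, dtype=int)
    is_reg = np.zeros(config.n_genes, dtype=bool)
    true_lfc = np.zeros(config.n_genes)

    values = np.empty((config.n_genes, n_samples))
    a_mod = np.sqrt(config.intra_module_rho)
    a_reg = config.regulator_anticorr_rho / a_mod  # negative loading on factor 1

    g = 0
    for m, size in enumerate(config.module_sizes, start=1):
        for _ in range(size):
            module_of[g] = m
            true_lfc[g] = config.de_log_fc
            signal = a_mod * factors[m - 1] + np.sqrt(1 - a_mod**2) * noise[g]
            values[g] = baseline[g] + config.noise_sd * signal
            g += 1
    for _ in range(n_reg):
        module_of[g] = 1
        is_reg[g] = True
        true_lfc[g] = -config.de_log_fc
        signal = a_reg * factors[0] + np.sqrt(1 - a_reg**2) * noise[g]
        values[g] = baseline[g] + config.noise_sd * signal
        g += 1
    values[g:] = baseline[g:, None] + config.noise_sd * noise[g:]

    # split the planted fold-change symmetrically between the conditions
    values += np.where(in_a, 0.5, -0.5)[None, :] * true_lfc[:, None]

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        condition=pd.Series(np.where(in_a, "A", "B"), index=sample_ids),
        scale="log2",
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "module": module_of,
            "is_regulator": is_reg,
            "is_de": true_lfc != 0,
            "true_log_fc": true_lfc,
        }
    )
    return matrix, truth


def generate_genesets(
    config: SimulationConfig,
    truth: pd.DataFrame | None = None,
    n_sets: int = 25,
    set_size: int = 30,
    planted_overlap: float = 0.8,
) -> GeneSetCollection:
    """Random gene sets plus one set planted on the regulators.

    The set named ``"planted"`` contains ``round(planted_overlap *
    n_switch_regulators)`` regulator genes, filled up to ``set_size``
    with random non-regulator genes; the remaining ``n_sets - 1`` sets
    are uniform random draws from all genes.
    """
    if not 0 <= planted_overlap <= 1:
        raise ValueError("planted_overlap must be in [0, 1]")
    if truth is None:
        _, truth = generate_expression(config)
    rng = config.stream("genesets")
    genes = truth["gene_id"].to_numpy()
    regulators = truth.loc[truth["is_regulator"], "gene_id"].to_numpy()
    others = truth.loc[~truth["is_regulator"], "gene_id"].to_numpy()

    n_from_reg = min(int(round(planted_overlap * len(regulators))), set_size)
    planted = list(rng.choice(regulators, size=n_from_reg, replace=False))
    planted += list(rng.choice(others, size=set_size - n_from_reg, replace=False))

    sets = {"planted": planted}
    for i in range(n_sets - 1):
        sets[f"set{i + 1:03d}"] = list(rng.choice(genes, size=set_size, replace=False))
    return GeneSetCollection(sets=sets)


def generate_switch_network(
    n_modules: int = 3,
    module_size: int = 40,
    n_connectors: int = 15,
    intra_p: float = 0.9,
    links_per_module: int = 6,
    intra_weight: float = 0.9,
    connector_weight: float = -0.8,
    seed: int = 0,
):
    """Network fixture whose only inter-module bridges are switch-like hubs.

    Builds dense positive-weight modules with *no* direct module-module
    edges, plus anti-correlated connector nodes that each link to a few
    genes in every module with negative weights — the topology in which
    fight-club hubs act as global connectors, so their targeted removal
    stretches shortest paths far more than random deletions.  Returns
    ``(graph, assignment)`` where the assignment maps module genes to
    their module and each connector to module 1 (its links still count
    as mostly external).
    """
    import networkx as nx

    rng = np.random.default_rng(seed)
    net = nx.Graph()
    assignment = {}
    modules = []
    for m in range(1, n_modules + 1):
        genes = [f"M{m}_{i:02d}" for i in range(module_size)]
        modules.append(genes)
        net.add_nodes_from(genes)
        for gene in genes:
            assignment[gene] = m
        for i in range(module_size):
            for j in range(i + 1, module_size):
                if rng.random() < intra_p:
                    net.add_edge(genes[i], genes[j], weight=intra_weight)
    for c in range(n_connectors):
        connector = f"SW_{c:02d}"
        assignment[connector] = 1
        net.add_node(connector)
        for genes in modules:
            for g in rng.choice(module_size, size=links_per_module, replace=False):
                net.add_edge(connector, genes[g], weight=connector_weight)
    return net, pd.Series(assignment, name="module")


def generate_clinical(
    config: SimulationConfig,
    expr: ExpressionMatrix | None = None,
    gene: str | None = None,
    hazard_coef: float = 1.0,
    baseline_hazard: float = 0.01,
    censoring_hazard: float = 0.005,
) -> pd.DataFrame:
    """Exponential survival with hazard log-linear in one gene's expression.

    Each sample's death time is exponential with rate
    ``baseline_hazard * exp(hazard_coef * z)`` where z is the chosen
    gene's standardized expression; censoring times are independent
    exponentials with rate ``censoring_hazard``.  The default prognostic
    gene is the first planted regulator.  Returns a (sample_id, time,
    event) DataFrame.
    """
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be positive")
    if censoring_hazard < 0:
        raise ValueError("censoring_hazard must be nonnegative")
    if expr is None:
        expr, truth = generate_expression(config)
        if gene is None:
            gene = truth.loc[truth["is_regulator"], "gene_id"].iloc[0] if truth["is_regulator"].any() else truth["gene_id"].iloc[0]
    elif gene is None:
        gene = expr.gene_ids[0]

    rng = config.stream("clinical")
    profile = expr.profile(gene)
    sd = profile.std()
    z = (profile - profile.mean()) / sd if sd > 0 else np.zeros_like(profile)
    rates = baseline_hazard * np.exp(hazard_coef * z)
    death = rng.exponential(1.0 / rates)
    if censoring_hazard > 0:
        censor = rng.exponential(1.0 / censoring_hazard, size=len(death))
    else:
        censor = np.full(len(death), np.inf)
    return pd.DataFrame(
        {
            "sample_id": expr.sample_ids,
            "time": np.minimum(death, censor),
            "event": (death <= censor).astype(int),
        }
    )
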