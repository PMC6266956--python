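"""End-to-end orchestration of the six-stage switch-gene pipeline.

filter -> differential expression -> correlation network -> k-means
modules -> cartography -> switch genes, with every stage's table
written next to a MANIFEST (file hashes + completion state), the
resolved configuration and a run log of per-stage counts.  Outputs are
byte-identical across reruns with the same inputs, config and seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, asdict, fields
from pathlib import Path

from . import io as swio
from .cartography import build_cartography, find_switch_genes
from .clustering import kmeans_partition
from .expression import ExpressionMatrix
from .network import build_network, compute_apcc, correlation_matrix
from .preprocess import NoGenesError, differential_expression, filter_low_expression

STAGES = ("filter", "deg", "network", "cluster", "cartography", "switch")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Flat bag of all stage parameters; round-trips through key=value files."""

    max_zero_samples: int | None = None  # default: half the samples, resolved at run time
    iqr_percentile: float = 25.0
    fc_threshold: float = 1.5
    fdr_threshold: float = 0.05
    rho_threshold: float = 0.71
    k: int = 3
    replicates: int = 100
    max_iterations: int = 300
    seed: int = 1
    hub_degree_threshold: int = 5
    apcc_split: float = 0.5

    def to_file(self, path) -> None:
        lines = [f"{key} = {value}" for key, value in asdict(self).items()]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        kinds = {f.name: f for f in fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = (part.strip() for part in line.partition("="))
            if key not in kinds:
                raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
            if value == "None":
                kwargs[key] = None
            elif key in ("max_zero_samples", "k", "replicates", "max_iterations", "seed",
                         "hub_degree_threshold"):
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, matrix: ExpressionMatrix, outdir) -> dict:
    """Execute all six stages, writing tables, log and MANIFEST to ``outdir``.

    Returns a summary dict with per-stage counts and the in-memory
    products (deg table, network, partition, cartography, switch list).
    On a stage failure the outputs of completed stages are kept and the
    MANIFEST records how far the run got, then :class:`PipelineError`
    is raised.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    max_zero = config.max_zero_samples
    if max_zero is None:
        max_zero = matrix.n_samples // 2

    completed: list[str] = []
    outputs: list[Path] = []
    counts: dict = {"input_genes": matrix.n_genes, "samples": matrix.n_samples}
    summary: dict = {"counts": counts}

    def finish_stage(stage: str, *paths: Path) -> None:
        completed.append(stage)
        outputs.extend(paths)
        _write_manifest(outdir, outputs, completed)

    config.to_file(outdir / "swim.config")
    outputs.append(outdir / "swim.config")

    try:
        stage = "filter"
        filtered = filter_low_expression(matrix, max_zero, config.iqr_percentile)
        counts["filtered_genes"] = filtered.n_genes
        finish_stage(stage)

        stage = "deg"
        deg = differential_expression(filtered, config.fc_threshold, config.fdr_threshold)
        if deg.empty:
            raise NoGenesError("no genes survive filtering (fold-change/FDR thresholds)")
        counts["degs"] = len(deg)
        swio.write_deg(deg, outdir / "deg.tsv")
        summary["deg"] = deg
        finish_stage(stage, outdir / "deg.tsv")

        stage = "network"
        deg_matrix = filtered.subset_genes(deg["gene_id"])
        corr = correlation_matrix(deg_matrix)
        net = build_network(corr, config.rho_threshold)
        counts["network_nodes"] = net.number_of_nodes()
        counts["network_edges"] = net.number_of_edges()
        swio.write_edgelist(net, outdir / "network.tsv")
        summary["network"] = net
        finish_stage(stage, outdir / "network.tsv")

        stage = "cluster"
        partition = kmeans_partition(
            deg_matrix.values,
            k=config.k,
            replicates=config.replicates,
            max_iterations=config.max_iterations,
            seed=config.seed,
        )
        counts["modules"] = len(partition.module_ids)
        counts["kmeans_sse"] = partition.sse
        swio.write_partition(partition.assignment, outdir / "partition.tsv")
        summary["partition"] = partition
        finish_stage(stage, outdir / "partition.tsv")

        stage = "cartography"
        apcc = compute_apcc(net)
        cart = build_cartography(
            net,
            partition,
            apcc=apcc,
            hub_degree_threshold=config.hub_degree_threshold,
            apcc_split=config.apcc_split,
        )
        for hub_class in ("date", "party", "fight-club"):
            counts[f"{hub_class}_hubs"] = int((cart["hub_class"] == hub_class).sum())
        swio.write_cartography(cart, outdir / "cartography.tsv")
        summary["cartography"] = cart
        finish_stage(stage, outdir / "cartography.tsv")

        stage = "switch"
        switch = find_switch_genes(cart)
        counts["switch_genes"] = len(switch)
        swio.write_gene_list(switch, outdir / "switch_genes.tsv")
        summary["switch_genes"] = switch
        finish_stage(stage, outdir / "switch_genes.tsv")
    except Exception as exc:
        _write_manifest(outdir, outputs, completed, failed_stage=stage)
        _write_log(outdir, config, max_zero, counts)
        raise PipelineError(stage, exc) from exc

    _write_log(outdir, config, max_zero, counts)
    outputs.append(outdir / "run.log")
    _write_manifest(outdir, outputs, completed)
    return summary


def _write_log(outdir: Path, config: PipelineConfig, max_zero: int, counts: dict) -> None:
    lines = [
        "swimnet pipeline run",
        f"seed = {config.seed}",
        f"max_zero_samples (resolved) = {max_zero}",
    ]
    lines += [f"{key} = {value}" for key, value in counts.items()]
    (outdir / "run.log").write_text("\n".join(lines) + "\n", encoding="utf-8")


def _write_manifest(outdir: Path, outputs, completed, failed_stage: str | None = None) -> None:
    lines = []
    for path in outputs:
        if Path(path).exists():
            lines.append(f"file\t{Path(path).name}\t{_sha256(Path(path))}")
    for stage in STAGES:
        if stage in completed:
            state = "completed"
        elif stage == failed_stage:
            state = "failed"
        else:
            state = "not-run"
        lines.append(f"stage\t{stage}\t{state}")
    (outdir / "MANIFEST").write_text("\n".join(lines) + "\n", encoding="utf-8")
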