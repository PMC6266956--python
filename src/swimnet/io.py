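"""Readers and writers for the tab-separated interchange formats.

All tables are TSV, UTF-8, '.' decimal separator.  Parsing is strict:
duplicate identifiers, ragged rows, non-numeric bodies and NaN values
are rejected with the offending id or line number.  CRLF line endings
are accepted.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx

from .enrichment import GeneSetCollection
from .expression import CONDITION_A, CONDITION_B, ExpressionMatrix
from .survival import CLINICAL_COLUMNS, validate_clinical

CARTOGRAPHY_HEADER = [
    "nodeName", "module", "hub", "Region", "Type", "Kp", "zg", "APCC",
    "Degree", "Date-Party", "is_switch",
]

_ROLE_BY_REGION = {
    "R1": "Ultra-peripheral",
    "R2": "Peripheral",
    "R3": "Non-hub connector",
    "R4": "Non-hub kinless",
    "R5": "Provincial hub",
    "R6": "Connector hub",
    "R7": "Kinless hub",
    "isolated": "isolated",
}


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed TSV ({exc})") from exc


# -- expression and conditions -----------------------------------------------


def read_conditions(path, cond_a: str | None = None, cond_b: str | None = None) -> pd.Series:
    """Two-column TSV (sample_id, condition) with a header row.

    Labels other than A/B may be mapped via ``cond_a``/``cond_b``.
    """
    table = _read_tsv(path, dtype=str)
    if list(table.columns[:2]) != ["sample_id", "condition"]:
        raise ValueError(f"{path}: expected header 'sample_id<TAB>condition'")
    if table["sample_id"].duplicated().any():
        dup = table["sample_id"][table["sample_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    cond = table.set_index("sample_id")["condition"]
    mapping = {}
    if cond_a is not None:
        mapping[cond_a] = CONDITION_A
    if cond_b is not None:
        mapping[cond_b] = CONDITION_B
    if mapping:
        cond = cond.map(lambda c: mapping.get(c, c))
    return cond


def read_expression(
    expr_path,
    conditions_path,
    scale: str = "log2",
    cond_a: str | None = None,
    cond_b: str | None = None,
) -> ExpressionMatrix:
    """Expression TSV (first column gene id, header of sample ids) + condition map."""
    values = _read_tsv(expr_path, index_col=0)
    if values.index.has_duplicates:
        dup = values.index[values.index.duplicated()][0]
        raise ValueError(f"{expr_path}: duplicate gene id {dup!r}")
    try:
        values = values.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{expr_path}: non-numeric expression value ({exc})") from exc
    if values.isna().to_numpy().any():
        gene = values.index[values.isna().any(axis=1)][0]
        raise ValueError(f"{expr_path}: NaN value at gene {gene!r}; missing values are not supported")
    condition = read_conditions(conditions_path, cond_a=cond_a, cond_b=cond_b)
    return ExpressionMatrix(values=values, condition=condition, scale=scale)


def write_expression(matrix: ExpressionMatrix, expr_path, conditions_path=None) -> None:
    matrix.values.to_csv(expr_path, sep="\t", index_label="gene_id")
    if conditions_path is not None:
        write_conditions(matrix.condition, conditions_path)


def write_conditions(condition: pd.Series, path) -> None:
    condition.rename("condition").to_csv(path, sep="\t", index_label="sample_id")


# -- DEG table ----------------------------------------------------------------


def write_deg(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_deg(path) -> pd.DataFrame:
    table = _read_tsv(path)
    expected = ["gene_id", "log_fc", "p_value", "fdr", "direction"]
    if list(table.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}")
    return table


# -- edge list ----------------------------------------------------------------


def write_edgelist(net: nx.Graph, path) -> None:
    """3-column TSV (source, target, weight), Cytoscape-importable."""
    rows = [
        {"source": u, "target": v, "weight": d["weight"]}
        for u, v, d in sorted(net.edges(data=True), key=lambda e: (str(e[0]), str(e[1])))
    ]
    frame = pd.DataFrame(rows, columns=["source", "target", "weight"])
    frame.to_csv(path, sep="\t", index=False)


def read_edgelist(path, nodes=None) -> nx.Graph:
    table = _read_tsv(path)
    if list(table.columns) != ["source", "target", "weight"]:
        raise ValueError(f"{path}: expected columns source, target, weight")
    net = nx.Graph()
    if nodes is not None:
        net.add_nodes_from(nodes)
    for row in table.itertuples(index=False):
        net.add_edge(row.source, row.target, weight=float(row.weight))
    return net


# -- partition / scree / scans ------------------------------------------------


def write_partition(assignment: pd.Series, path) -> None:
    assignment.rename("module").to_csv(path, sep="\t", index_label="node")


def read_partition(path) -> pd.Series:
    table = _read_tsv(path)
    if list(table.columns) != ["node", "module"]:
        raise ValueError(f"{path}: expected columns node, module")
    return table.set_index("node")["module"].astype(int)


def write_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


# -- cartography --------------------------------------------------------------


def write_cartography(cart: pd.DataFrame, path) -> None:
    """Role table with the conventional column names (Kp, zg, APCC, ...)."""
    out = pd.DataFrame(
        {
            "nodeName": cart.index,
            "module": cart["module"].to_numpy(),
            "hub": np.where(cart["z_g"] >= 2.5, "yes", "no"),
            "Region": cart["region"].to_numpy(),
            "Type": [_ROLE_BY_REGION[r] for r in cart["region"]],
            "Kp": cart["k_pi"].to_numpy(),
            "zg": cart["z_g"].to_numpy(),
            "APCC": cart["apcc"].to_numpy(),
            "Degree": cart["degree"].to_numpy(),
            "Date-Party": cart["hub_class"].to_numpy(),
            "is_switch": cart["is_switch"].to_numpy(),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_cartography(path) -> pd.DataFrame:
    table = _read_tsv(path)
    if list(table.columns) != CARTOGRAPHY_HEADER:
        raise ValueError(f"{path}: expected columns {CARTOGRAPHY_HEADER}")
    out = pd.DataFrame(
        {
            "node": table["nodeName"],
            "module": table["module"].astype(int),
            "degree": table["Degree"].astype(int),
            "k_pi": table["Kp"].astype(float),
            "z_g": table["zg"].astype(float),
            "apcc": table["APCC"].astype(float),
            "region": table["Region"],
            "hub_class": table["Date-Party"],
            "is_switch": table["is_switch"].astype(bool),
        }
    ).set_index("node")
    return out


# -- GMT gene sets ------------------------------------------------------------


def read_gmt(path) -> GeneSetCollection:
    """GMT: set_id <TAB> description <TAB> member genes..., one set per line."""
    sets = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs set id, description and >= 1 gene")
            set_id = fields[0]
            if set_id in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            sets[set_id] = [g for g in fields[2:] if g]
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for set_id in sorted(collection.sets):
            members = sorted(collection.sets[set_id])
            handle.write("\t".join([set_id, description, *members]) + "\n")


# -- clinical -----------------------------------------------------------------


def read_clinical(path) -> pd.DataFrame:
    table = _read_tsv(path)
    if list(table.columns) != CLINICAL_COLUMNS:
        raise ValueError(f"{path}: expected columns {CLINICAL_COLUMNS}")
    return validate_clinical(table)


def write_clinical(clinical: pd.DataFrame, path) -> None:
    validate_clinical(clinical).to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> list:
    """One gene id per line; blank lines ignored."""
    with open(path, encoding="utf-8") as handle:
        return [line.strip() for line in handle if line.strip()]


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes), encoding="utf-8")
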