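"""Reading and writing pipeline artifacts as plain delimited text.

Expression matrices are genes x samples TSV/CSV (optional GCT dialect);
gene lists are GMT; sample annotations are TSV keyed by ``sample_id``.
Every derived artifact (ternary codes + threshold side table,
implication tables, cluster graphs, scores) round-trips through a
deterministic text serialization.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .network import ClusterGraph
from .stepminer import TernaryMatrix

__all__ = [
    "read_expression",
    "write_expression",
    "read_annotations",
    "write_annotations",
    "read_gmt",
    "write_gmt",
    "write_ternary",
    "read_ternary",
    "write_table",
    "read_implications",
    "write_cluster_graph",
    "read_cluster_graph",
]


def _check_unique(ids, what: str) -> None:
    counts = pd.Series(ids).value_counts()
    dups = counts[counts > 1]
    if len(dups):
        raise ValueError(f"duplicate {what} id(s): {', '.join(map(str, dups.index[:10]))}")


def read_expression(
    path,
    sep: str = "\t",
    na_token: str | None = "NA",
    gct: bool = False,
    log2_transform: bool = False,
) -> pd.DataFrame:
    """Read a genes x samples expression matrix from delimited text.

    One header row of sample ids, gene ids in the first column.  Blank
    cells and ``na_token`` become missing.  The GCT dialect skips the
    two GCT header lines and drops a leading ``Description`` column.
    ``log2_transform`` applies log2(x + 1) for raw-scale input.

    Raises
    ------
    ValueError
        On duplicate gene or sample ids (naming them) or ragged rows
        (with the offending line number, from the parser).
    """
    na_values = [na_token] if na_token else []
    try:
        df = pd.read_csv(
            path,
            sep=sep,
            index_col=0,
            skiprows=2 if gct else 0,
            na_values=na_values,
        )
    except pd.errors.ParserError as exc:  # message carries the line number
        raise ValueError(f"malformed expression file {path}: {exc}") from exc
    if gct and len(df.columns) and df.columns[0].lower() == "description":
        df = df.drop(columns=df.columns[0])
    _check_unique(df.index, "gene")
    _check_unique(df.columns, "sample")
    df = df.apply(pd.to_numeric, errors="raise")
    values = df.to_numpy(dtype=float)
    if np.isinf(values).any():
        raise ValueError(f"non-finite expression values in {path}")
    if log2_transform:
        df = np.log2(df + 1.0)
    df.index.name = matrix_index_name(df)
    return df


def matrix_index_name(df: pd.DataFrame) -> str:
    return df.index.name or "gene_id"


def write_expression(matrix: pd.DataFrame, path, sep: str = "\t", na_token: str = "NA") -> None:
    matrix.to_csv(path, sep=sep, na_rep=na_token, index_label=matrix_index_name(matrix))


def read_annotations(path, sep: str = "\t") -> pd.DataFrame:
    """Read a sample annotation table keyed by a ``sample_id`` column."""
    df = pd.read_csv(path, sep=sep)
    if "sample_id" not in df.columns:
        raise ValueError(f"annotation file {path} lacks a 'sample_id' column")
    _check_unique(df["sample_id"], "sample")
    return df.set_index("sample_id")


def write_annotations(annotations: pd.DataFrame, path, sep: str = "\t") -> None:
    annotations.to_csv(path, sep=sep, index_label="sample_id")


def validate_annotations(annotations: pd.DataFrame, matrix: pd.DataFrame) -> None:
    """Every annotated sample must exist in the matrix it accompanies."""
    unknown = [s for s in annotations.index if s not in matrix.columns]
    if unknown:
        raise ValueError(f"annotated sample(s) absent from matrix: {', '.join(map(str, unknown[:10]))}")


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from GMT (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT lines need name, description, >=1 gene")
        name = fields[0]
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate gene set {name!r}")
        sets[name] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "") -> None:
    lines = [
        "\t".join([name, description, *genes]) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Derived artifacts


def write_ternary(ternary: TernaryMatrix, codes_path, thresholds_path, sep: str = "\t") -> None:
    """Write ternary codes plus the per-gene threshold side table."""
    ternary.codes.to_csv(codes_path, sep=sep, index_label="gene_id")
    side = ternary.fits.copy()
    side["informative"] = ternary.informative.astype(int)
    side["margin"] = ternary.margin
    side.to_csv(thresholds_path, sep=sep, index_label="gene_id")


def read_ternary(codes_path, thresholds_path, sep: str = "\t") -> TernaryMatrix:
    codes = pd.read_csv(codes_path, sep=sep, index_col=0).astype(np.int8)
    side = pd.read_csv(thresholds_path, sep=sep, index_col=0)
    margin = float(side["margin"].iloc[0]) if len(side) else 0.5
    informative = side["informative"].astype(bool).rename("informative")
    fits = side.drop(columns=["informative", "margin"])
    return TernaryMatrix(codes=codes, fits=fits, informative=informative, margin=margin)


def write_table(table: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a record table (implications, scores, reports) without index."""
    table.to_csv(path, sep=sep, index=False)


def read_implications(path, sep: str = "\t") -> pd.DataFrame:
    table = pd.read_csv(path, sep=sep)
    if "passes" in table.columns:
        table["passes"] = table["passes"].astype(bool)
    return table


def write_cluster_graph(graph: ClusterGraph, path, tables_prefix=None) -> None:
    """Serialize a cluster graph as JSON; optionally also node/edge TSVs.

    ``tables_prefix`` writes GraphML-compatible ``<prefix>.nodes.tsv``
    and ``<prefix>.edges.tsv`` companions for inspection.
    """
    Path(path).write_text(json.dumps(graph.to_dict(), indent=1, sort_keys=True) + "\n")
    if tables_prefix is not None:
        graph.node_table().to_csv(f"{tables_prefix}.nodes.tsv", sep="\t", index=False)
        graph.edge_table().to_csv(f"{tables_prefix}.edges.tsv", sep="\t", index=False)


def read_cluster_graph(path) -> ClusterGraph:
    return ClusterGraph.from_dict(json.loads(Path(path).read_text()))
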