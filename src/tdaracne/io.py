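"""Readers and writers for expression matrices and network files.

Expression matrices are delimited text with genes on rows: first column
gene id, header row of time labels, remaining cells numeric.  Networks
travel as edge-list TSV (source, target, influence, delay), SIF or DOT.
"""

from __future__ import annotations

import csv

import numpy as np
import pandas as pd
import networkx as nx


def read_expression(path, delimiter: str | None = None, normalize: bool = False) -> pd.DataFrame:
    """Load and validate a genes x time expression matrix.

    The delimiter is sniffed (tab or comma) unless given.  Raises
    ``ValueError`` naming the offending gene/column for duplicate ids,
    non-numeric cells, non-finite values or fewer than two time points.
    No global normalisation is applied by default (there is no accepted
    rule for it); ``normalize=True`` min-max scales each profile to
    [0, 1], which is harmless for the rank-based pipeline but eases
    eyeballing heterogeneous datasets.
    """
    try:
        df = pd.read_csv(
            path,
            sep=delimiter,
            index_col=0,
            engine="python" if delimiter is None else "c",
        )
    except (pd.errors.EmptyDataError, csv.Error) as exc:
        raise ValueError(f"{path}: empty or unparseable expression file") from exc
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least 2 time points, found {df.shape[1]}")
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicated gene ids {dup}")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() & df[col].notna()].tolist()
        if bad or numeric.isna().any():
            missing = df.index[numeric.isna()].tolist()
            raise ValueError(f"{path}: non-numeric or missing cells in column {col!r} for genes {bad or missing}")
        df[col] = numeric
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        genes = df.index[~np.isfinite(values).all(axis=1)].tolist()
        raise ValueError(f"{path}: non-finite values for genes {genes}")
    df.index = df.index.astype(str)
    if normalize:
        span = values.max(axis=1) - values.min(axis=1)
        span[span == 0] = 1.0
        df = df.sub(values.min(axis=1), axis=0).div(span, axis=0)
    return df


def write_expression(matrix: pd.DataFrame, path, delimiter: str = "\t") -> None:
    """Write a genes x time matrix as delimited text (gene ids first column)."""
    matrix.to_csv(path, sep=delimiter, index_label="gene")


def write_network_tsv(network: nx.DiGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\tinfluence\tdelay\n")
        for u, v, data in sorted(network.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data.get('weight', float('nan')):.6g}\t{data.get('delay', '')}\n")


def read_network_tsv(path) -> nx.DiGraph:
    """Round-trip reader for the edge-list TSV written by write_network_tsv."""
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    g = nx.DiGraph()
    for row in df.itertuples(index=False):
        attrs = {}
        if hasattr(row, "influence") and pd.notna(row.influence):
            attrs["weight"] = float(row.influence)
        if hasattr(row, "delay") and pd.notna(row.delay):
            attrs["delay"] = int(row.delay)
        g.add_edge(row.source, row.target, **attrs)
    return g


def write_network_sif(network: nx.DiGraph, path, relation: str = "regulates") -> None:
    with open(path, "w") as fh:
        for u, v in sorted(network.edges()):
            fh.write(f"{u}\t{relation}\t{v}\n")


def write_network_dot(network: nx.DiGraph, path, name: str = "grn") -> None:
    """Minimal Graphviz DOT export with influence weights as edge labels."""
    lines = [f"digraph {name} {{"]
    for node in sorted(network.nodes):
        lines.append(f'    "{node}";')
    for u, v, data in sorted(network.edges(data=True)):
        label = f'{data["weight"]:.3f}' if "weight" in data else ""
        lines.append(f'    "{u}" -> "{v}" [label="{label}"];')
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_edge_list(path) -> set[tuple]:
    """Read a 2-column (source, target) TSV, with or without a header row."""
    edges = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if not line.strip():
                continue
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            if lineno == 1 and parts[0].lower() in {"source", "src", "from"}:
                continue
            edges.add((parts[0], parts[1]))
    return edges
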