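"""Readers and writers for the plain-text formats used across the toolkit.

Expression matrices are tab-delimited with a feature-id first column and a
header row of sample ids; tables are tab-delimited with an id first column;
gene sets travel as GMT; networks as two-column edge lists.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List

import networkx as nx
import pandas as pd

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_table",
    "write_table",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
    "read_gene_list",
    "write_gene_list",
]


def read_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a features x samples matrix (tab-delimited, id first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index_label=df.index.name or "feature_id")


def read_table(path: str | os.PathLike, index_col: int | str | None = 0) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=index_col)
    if index_col is not None:
        df.index = df.index.astype(str)
    return df


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index_label=df.index.name or "id")


def read_gmt(path: str | os.PathLike) -> Dict[str, List[str]]:
    """Read GMT gene sets: name <tab> description <tab> member ids..."""
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name, members = parts[0], [m for m in parts[2:] if m]
            sets[name] = members
    return sets


def write_gmt(sets: Dict[str, Iterable[str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, name, *map(str, members)]) + "\n")


def read_edge_list(path: str | os.PathLike) -> nx.Graph:
    """Read an undirected two-column edge list (tab-delimited, no header detection:
    a first line of 'node1\\tnode2' style headers is tolerated and skipped)."""
    g = nx.Graph()
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            u, v = line.split("\t")[:2]
            if i == 0 and {u.lower(), v.lower()} & {"node1", "source", "from"}:
                continue
            if u != v:
                g.add_edge(u, v)
    return g


def write_edge_list(graph: nx.Graph, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted((str(a), str(b)))) for a, b in graph.edges()):
            fh.write(f"{u}\t{v}\n")


def read_gene_list(path: str | os.PathLike) -> List[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Iterable[str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
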