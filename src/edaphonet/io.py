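"""Readers and writers for the pipeline's tabular and graph formats.

On disk the OTU table follows the classic amplicon convention (OTUs as
rows, samples as columns, first header cell ``#OTU ID``); in memory samples
are rows.  Metadata and soil tables are plain TSV keyed by ``sample_id``.
Networks are written as GraphML and as an edge-list TSV
(source, target, rho, q) that round-trips losslessly.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import FormatError, OtuTable, validate_metadata, validate_soil

__all__ = [
    "read_otu_table", "write_otu_table",
    "read_metadata", "write_metadata",
    "read_soil_table", "write_soil_table",
    "write_network", "read_edgelist",
]


def read_otu_table(path: str | Path) -> OtuTable:
    """Read an OTU table TSV (OTUs as rows, ``#OTU ID`` header)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    seen: set[str] = set()
    for col in header:
        if col in seen:
            raise FormatError(f"duplicate sample column: {col!r}")
        seen.add(col)
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    if df.columns[0] != "#OTU ID":
        raise FormatError(
            f"expected first column header '#OTU ID', got {df.columns[0]!r}"
        )
    df = df.set_index(df.columns[0])
    counts = df.T  # samples as rows in memory
    counts.index.name = "sample_id"
    return OtuTable(counts)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    out = table.counts.T.rename_axis("#OTU ID")
    out.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return validate_metadata(df)


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_soil_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["sample_id"] = df["sample_id"].astype(str)
    return validate_soil(df)


def write_soil_table(soil: pd.DataFrame, path: str | Path) -> None:
    soil.to_csv(path, sep="\t", index=False)


def write_network(net: nx.Graph, path: str | Path, format: str = "edgelist") -> None:
    """Write a co-occurrence network as GraphML or edge-list TSV."""
    path = Path(path)
    if format == "graphml":
        g = nx.Graph(**{k: v for k, v in net.graph.items() if v is not None})
        for u in net.nodes:
            g.add_node(u, otu_id=str(u))
        for u, v, d in net.edges(data=True):
            g.add_edge(u, v, weight=float(d.get("rho", d.get("weight", 0.0))),
                       q=float(d.get("q", np.nan)))
        nx.write_graphml(g, path)
    elif format == "edgelist":
        rows = [
            {"source": u, "target": v,
             "rho": repr(float(d.get("rho", d.get("weight", 0.0)))),
             "q": repr(float(d.get("q", np.nan)))}
            for u, v, d in net.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "rho", "q"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_edgelist(path: str | Path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    g = nx.Graph()
    for _, row in df.iterrows():
        r = float(row["rho"])
        g.add_edge(row["source"], row["target"], rho=r, q=float(row["q"]), weight=r)
    return g
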