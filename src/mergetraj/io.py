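"""Plain-text formats: TSV matrices, edge lists, GMT gene sets, JSON.

All tables are tab-separated with header rows; ids are strings; round
trips preserve values to full precision (floats are written with repr
fidelity via pandas' default float_format=None).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import TimeSeriesPanel, WeightedGraph
from .enrichment import GeneSetCollection
from .merging import PhenotypeMap
from .transcriptome import RegionGeometry

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_edge_list",
    "read_edge_list",
    "graph_to_edge_list",
    "edge_list_to_graph",
    "write_gmt",
    "read_gmt",
    "write_map",
    "read_map",
    "write_geometry",
    "read_geometry",
    "write_panel",
    "read_panel",
    "write_json",
    "read_json",
]


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=True)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


def write_panel(panel: TimeSeriesPanel, path: str | Path) -> None:
    df = pd.DataFrame(panel.data, index=panel.node_ids)
    df.index.name = "node"
    df.to_csv(path, sep="\t")


def read_panel(path: str | Path, subject_id: str | None = None) -> TimeSeriesPanel:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    sid = subject_id if subject_id is not None else Path(path).stem
    return TimeSeriesPanel(subject_id=sid, data=df.to_numpy(dtype=float),
                           node_ids=[str(x) for x in df.index])


def graph_to_edge_list(graph: WeightedGraph) -> pd.DataFrame:
    iu = np.triu_indices(graph.n_nodes, k=1)
    w = graph.weights[iu]
    keep = w > 0
    return pd.DataFrame(
        {
            "node_i": [graph.node_ids[i] for i in iu[0][keep]],
            "node_j": [graph.node_ids[j] for j in iu[1][keep]],
            "weight": w[keep],
        }
    )


def edge_list_to_graph(edges: pd.DataFrame, node_ids: list[str]) -> WeightedGraph:
    idx = {v: i for i, v in enumerate(node_ids)}
    w = np.zeros((len(node_ids), len(node_ids)))
    for _, row in edges.iterrows():
        i, j = idx[str(row["node_i"])], idx[str(row["node_j"])]
        w[i, j] = w[j, i] = float(row["weight"])
    return WeightedGraph(node_ids=list(node_ids), weights=w)


def write_edge_list(graph: WeightedGraph, path: str | Path) -> None:
    graph_to_edge_list(graph).to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path, node_ids: list[str] | None = None) -> WeightedGraph:
    edges = pd.read_csv(path, sep="\t", dtype={"node_i": str, "node_j": str})
    if node_ids is None:
        node_ids = sorted(set(edges["node_i"]) | set(edges["node_j"]))
    return edge_list_to_graph(edges, node_ids)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tid in collection.terms:
            name = collection.names.get(tid, tid)
            genes = "\t".join(sorted(collection.terms[tid]))
            fh.write(f"{tid}\t{name}\t{genes}\n")


def read_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetCollection:
    """Parse a GMT file: one term per line, ``id<TAB>description<TAB>genes...``."""
    terms: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: malformed GMT line (<3 fields)")
            tid, name, genes = fields[0], fields[1], fields[2:]
            terms[tid] = frozenset(genes)
            names[tid] = name
    if universe is None:
        universe = set().union(*terms.values()) if terms else set()
    return GeneSetCollection(terms=terms, universe=frozenset(universe), names=names)


def write_map(map_: PhenotypeMap, path: str | Path) -> None:
    pd.DataFrame({"region": map_.region_ids, "value": map_.values}).to_csv(
        path, sep="\t", index=False
    )


def read_map(path: str | Path, kind: str = "S_minus_I") -> PhenotypeMap:
    df = pd.read_csv(path, sep="\t", dtype={"region": str})
    return PhenotypeMap(df["region"].tolist(), df["value"].to_numpy(), kind)


def write_geometry(geom: RegionGeometry, path: str | Path) -> None:
    pd.DataFrame(
        {
            "region": geom.region_ids,
            "x": geom.centroids[:, 0],
            "y": geom.centroids[:, 1],
            "z": geom.centroids[:, 2],
        }
    ).to_csv(path, sep="\t", index=False)


def read_geometry(path: str | Path) -> RegionGeometry:
    df = pd.read_csv(path, sep="\t", dtype={"region": str})
    cent = df[["x", "y", "z"]].to_numpy(dtype=float)
    diff = cent[:, None, :] - cent[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    return RegionGeometry(region_ids=df["region"].tolist(), centroids=cent, distances=dist)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
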