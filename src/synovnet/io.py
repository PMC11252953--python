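"""Reading and writing the package's tabular and graph formats."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .preprocess import IntensityMatrix


def write_intensity(matrix: IntensityMatrix, path: str | Path) -> None:
    df = matrix.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path)


def read_intensity(path: str | Path, scale: str = "linear") -> IntensityMatrix:
    df = pd.read_csv(path, index_col="sample_id")
    return IntensityMatrix(df, scale=scale)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])


def write_edges(graphs: dict[str, nx.Graph], path: str | Path,
                frequencies: dict[str, pd.DataFrame] | None = None) -> None:
    """Edge-list TSV with columns node_a, node_b, group, frequency."""
    rows = []
    for group, G in graphs.items():
        freq_lut = {}
        if frequencies and group in frequencies:
            for _, r in frequencies[group].iterrows():
                freq_lut[frozenset((r["node_a"], r["node_b"]))] = r["frequency"]
        for u, v in sorted(tuple(sorted(e)) for e in G.edges):
            rows.append(
                dict(node_a=u, node_b=v, group=group,
                     frequency=freq_lut.get(frozenset((u, v)), ""))
            )
    pd.DataFrame(rows, columns=["node_a", "node_b", "group", "frequency"]).to_csv(
        path, sep="\t", index=False
    )


def read_edges(path: str | Path) -> dict[str, nx.Graph]:
    df = pd.read_csv(path, sep="\t")
    graphs: dict[str, nx.Graph] = {}
    for group, sub in df.groupby("group"):
        G = nx.Graph()
        G.add_edges_from(zip(sub["node_a"], sub["node_b"]))
        graphs[str(group)] = G
    return graphs


def write_graphml(G: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(G, str(path))


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=str))
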