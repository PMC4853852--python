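"""Readers and writers for the pipeline's delimited-text interfaces.

Matrices travel as TSV (first column feature id, header row of sample ids),
class labels as two-column TSV, edge lists as 2-column TSV or SIF, gene
sets as GMT, graphs additionally as GraphML, ground truth and manifests as
JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .preprocess import OmicsStudy


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def read_labels(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def write_labels(labels: pd.Series, path) -> None:
    labels.rename("label").rename_axis("sample_id").to_csv(path, sep="\t")


def read_study(matrix_path, labels_path, study_id: str, layer: str) -> OmicsStudy:
    return OmicsStudy(
        study_id=study_id,
        layer=layer,
        matrix=read_matrix(matrix_path),
        classes=read_labels(labels_path),
    )


def write_study(study: OmicsStudy, outdir, prefix: str | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prefix = prefix or study.study_id
    write_matrix(study.matrix, outdir / f"{prefix}.matrix.tsv")
    write_labels(study.classes, outdir / f"{prefix}.labels.tsv")


def read_edge_list(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("edge list needs >= 2 columns")
    return df


def write_edge_list(edges, path) -> None:
    if isinstance(edges, nx.Graph):
        edges = pd.DataFrame(list(edges.edges()), columns=["source", "target"])
    edges.to_csv(path, sep="\t", index=False)


def write_sif(graph: nx.Graph, path, default_relation: str = "pp") -> None:
    with open(path, "w") as fh:
        for u, v, data in graph.edges(data=True):
            rel = data.get("source", default_relation)
            fh.write(f"{u}\t{rel}\t{v}\n")
        for n in nx.isolates(graph):
            fh.write(f"{n}\n")


def read_sif(path) -> nx.Graph:
    G = nx.Graph()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                G.add_edge(parts[0], parts[2], source=parts[1])
            elif parts[0]:
                G.add_node(parts[0])
    return G


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_survival_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("time", "event"):
        if col not in df.columns:
            raise ValueError(f"survival table lacks required column {col!r}")
    return df


def write_survival_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if hasattr(o, "item"):
            return o.item()
        if isinstance(o, pd.Series):
            return o.to_dict()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
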