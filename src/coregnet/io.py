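"""TSV readers and writers for every artifact the pipeline exchanges.

All tables are tab-separated with a header line. Edge lists are 3-column
(source, target, type), node tables 2-column (id, type), gene lists
1-column.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from coregnet.netbuild import EnrichmentRecord, RegulatoryNetwork
from coregnet.simdata import (
    CountMatrix,
    DiseaseAnnotation,
    InteractionDB,
    SimConfig,
    TruthTable,
)

__all__ = [
    "write_counts",
    "read_counts",
    "write_interaction_db",
    "read_interaction_db",
    "write_disease",
    "read_disease",
    "write_gene_list",
    "read_gene_list",
    "write_network",
    "read_network",
    "write_enrichment",
    "write_truth",
    "write_sim_config",
    "read_sim_config",
]


def write_counts(cm: CountMatrix, counts_path, groups_path) -> None:
    df = cm.to_frame()
    df.index.name = "gene_id"
    df.to_csv(counts_path, sep="\t")
    pd.DataFrame({"sample_id": cm.sample_ids, "group": cm.group_labels}).to_csv(
        groups_path, sep="\t", index=False
    )


def read_counts(counts_path, groups_path) -> CountMatrix:
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    ann = pd.read_csv(groups_path, sep="\t")
    ann = ann.set_index("sample_id").loc[list(df.columns)]
    return CountMatrix(
        gene_ids=list(df.index.astype(str)),
        sample_ids=list(df.columns.astype(str)),
        counts=df.to_numpy(dtype=np.int64),
        group_labels=list(ann["group"].astype(str)),
    )


def write_interaction_db(db: InteractionDB, edges_path, nodes_path) -> None:
    pd.DataFrame(db.edges, columns=["source", "target", "type"]).to_csv(
        edges_path, sep="\t", index=False
    )
    pd.DataFrame(
        sorted(db.node_types.items()), columns=["id", "type"]
    ).to_csv(nodes_path, sep="\t", index=False)


def read_interaction_db(edges_path, nodes_path) -> InteractionDB:
    e = pd.read_csv(edges_path, sep="\t")
    n = pd.read_csv(nodes_path, sep="\t")
    return InteractionDB(
        edges=[tuple(r) for r in e[["source", "target", "type"]].itertuples(index=False)],
        node_types=dict(zip(n["id"].astype(str), n["type"].astype(str))),
    )


def write_disease(disease: DiseaseAnnotation, path) -> None:
    pd.DataFrame({"node_id": sorted(disease.nodes)}).to_csv(path, sep="\t", index=False)


def read_disease(path, disease_name: str = "disease") -> DiseaseAnnotation:
    df = pd.read_csv(path, sep="\t")
    return DiseaseAnnotation(disease_name, set(df.iloc[:, 0].astype(str)))


def write_gene_list(genes, path) -> None:
    pd.DataFrame({"gene_id": sorted(genes)}).to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> set[str]:
    df = pd.read_csv(path, sep="\t")
    return set(df.iloc[:, 0].astype(str))


def write_network(net: RegulatoryNetwork, edges_path, nodes_path) -> None:
    rows = sorted(net.edges)
    pd.DataFrame(rows, columns=["source", "target", "type"]).to_csv(
        edges_path, sep="\t", index=False
    )
    nodes = sorted((v, net.node_type(v)) for v in net.nodes)
    pd.DataFrame(nodes, columns=["id", "type"]).to_csv(nodes_path, sep="\t", index=False)


def read_network(edges_path, nodes_path, provenance: str = "unknown") -> RegulatoryNetwork:
    e = pd.read_csv(edges_path, sep="\t")
    n = pd.read_csv(nodes_path, sep="\t")
    g = nx.DiGraph()
    for _, row in n.iterrows():
        g.add_node(str(row["id"]), node_type=str(row["type"]))
    for _, row in e.iterrows():
        g.add_edge(str(row["source"]), str(row["target"]), edge_type=str(row["type"]))
    return RegulatoryNetwork(graph=g, provenance=provenance)


def write_enrichment(records: list[EnrichmentRecord], path) -> None:
    pd.DataFrame([asdict(r) for r in records]).to_csv(path, sep="\t", index=False)


def write_truth(truth: TruthTable, table_path, size_factor_path) -> None:
    truth.table.to_csv(table_path, sep="\t", index=False)
    pd.DataFrame({"size_factor": truth.size_factors}).to_csv(
        size_factor_path, sep="\t", index=False
    )


def write_sim_config(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        for key, val in asdict(config).items():
            fh.write(f"{key}: {val}\n")


def read_sim_config(path) -> SimConfig:
    kwargs = {}
    fields = SimConfig.__dataclass_fields__
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        key, _, val = line.partition(":")
        key = key.strip()
        if key not in fields:
            raise ValueError(f"unknown config key {key!r}")
        typ = fields[key].type
        kwargs[key] = int(val) if "int" in str(typ) else float(val)
    return SimConfig(**kwargs)
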