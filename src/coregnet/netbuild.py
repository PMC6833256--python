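"""Disease-specific TF-miRNA co-regulatory network construction.

Given a DE gene set and a typed interaction database, missing miRNAs whose
targets AND regulator TFs are enriched in the DE set (hypergeometric test,
BH-adjusted below a cutoff in each family) are recovered; the network is the
database restricted to DE genes plus recovered miRNAs, optionally filtered
to disease-annotated nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
from scipy import stats

from coregnet.de_methods import DEGeneSet, bh_adjust
from coregnet.simdata import DiseaseAnnotation, InteractionDB

__all__ = [
    "RegulatoryNetwork",
    "EnrichmentRecord",
    "hypergeom_pvalue",
    "recover_mirnas",
    "build_network",
    "disease_filter",
]


@dataclass
class RegulatoryNetwork:
    """Directed typed regulatory graph with construction provenance."""

    graph: nx.DiGraph
    provenance: str = "unknown"  # DE method that produced the input gene set
    disease_name: str = "unfiltered"

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str, str]]:
        return {(u, v, d["edge_type"]) for u, v, d in self.graph.edges(data=True)}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_type(self, node: str) -> str:
        return self.graph.nodes[node]["node_type"]


@dataclass
class EnrichmentRecord:
    mirna_id: str
    p_target: float
    p_tf: float
    adj_p_target: float = 1.0
    adj_p_tf: float = 1.0
    recovered: bool = False
    n_targets_in_de: int = 0
    n_tfs_in_de: int = 0


def hypergeom_pvalue(overlap: int, sample_size: int, successes: int, universe: int) -> float:
    """Upper-tail P(X >= overlap) for X ~ Hypergeom(universe, successes, sample_size)."""
    if not 0 <= overlap <= min(sample_size, successes):
        raise ValueError("overlap must not exceed sample_size or successes")
    if max(sample_size, successes) > universe:
        raise ValueError("sample_size and successes must not exceed the universe")
    if overlap == 0:
        return 1.0
    return float(stats.hypergeom.sf(overlap - 1, universe, successes, sample_size))


def recover_mirnas(
    db: InteractionDB, de_genes: DEGeneSet, cutoff: float = 0.001
) -> list[EnrichmentRecord]:
    """Identify miRNAs whose targets and regulator TFs are DE-enriched.

    Target enrichment is tested against the database gene universe, TF
    enrichment against the database TF universe; each p-value family is
    BH-adjusted separately across miRNAs. A miRNA is recovered when both
    adjusted p-values fall strictly below ``cutoff``.
    """
    gene_universe = db.gene_universe()
    tf_universe = db.tfs()
    de = set(de_genes.genes) & gene_universe
    de_tfs = de & tf_universe
    targets = db.mirna_targets()
    reg_tfs = db.mirna_regulator_tfs()

    records: list[EnrichmentRecord] = []
    for m in sorted(db.mirnas()):
        tg = targets.get(m, set()) & gene_universe
        tf = reg_tfs.get(m, set()) & tf_universe
        ov_t = len(tg & de)
        ov_f = len(tf & de_tfs)
        p_t = (
            hypergeom_pvalue(ov_t, len(tg), len(de), len(gene_universe))
            if tg and de
            else 1.0
        )
        p_f = (
            hypergeom_pvalue(ov_f, len(tf), len(de_tfs), len(tf_universe))
            if tf and de_tfs
            else 1.0
        )
        records.append(
            EnrichmentRecord(
                mirna_id=m,
                p_target=p_t,
                p_tf=p_f,
                n_targets_in_de=ov_t,
                n_tfs_in_de=ov_f,
            )
        )
    if records:
        adj_t = bh_adjust([r.p_target for r in records])
        adj_f = bh_adjust([r.p_tf for r in records])
        for r, at, af in zip(records, adj_t, adj_f):
            r.adj_p_target = float(at)
            r.adj_p_tf = float(af)
            r.recovered = at < cutoff and af < cutoff
    return records


def build_network(
    db: InteractionDB, de_genes: DEGeneSet, recovered: set[str]
) -> RegulatoryNetwork:
    """Database subgraph on DE genes plus recovered miRNAs; isolates dropped.

    miRNA endpoints must belong to the recovered set (the DE input here is
    genes-only), which the candidate-set restriction enforces.
    """
    candidates = set(de_genes.genes) | set(recovered)
    g = nx.DiGraph()
    for src, tgt, etype in db.edges:
        if src in candidates and tgt in candidates:
            g.add_node(src, node_type=db.node_types[src])
            g.add_node(tgt, node_type=db.node_types[tgt])
            g.add_edge(src, tgt, edge_type=etype)
    return RegulatoryNetwork(graph=g, provenance=de_genes.method_name)


def disease_filter(
    net: RegulatoryNetwork,
    disease: DiseaseAnnotation,
    require_both_endpoints: bool = True,
) -> RegulatoryNetwork:
    """Restrict the network to disease-annotated interactions.

    By default an edge survives only if BOTH endpoints are disease-annotated;
    with ``require_both_endpoints=False`` one annotated endpoint suffices.
    Nodes left isolated are dropped.
    """
    keep = disease.nodes
    g = nx.DiGraph()
    for u, v, d in net.graph.edges(data=True):
        ok = (u in keep and v in keep) if require_both_endpoints else (u in keep or v in keep)
        if ok:
            g.add_node(u, **net.graph.nodes[u])
            g.add_node(v, **net.graph.nodes[v])
            g.add_edge(u, v, **d)
    return RegulatoryNetwork(
        graph=g, provenance=net.provenance, disease_name=disease.disease_name
    )
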