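"""Seeded synthetic data generators for the network-consistency pipeline.

Produces the three inputs the downstream stages consume — an overdispersed
count matrix with planted differential expression, a typed regulatory
interaction database with heavy-tailed out-degrees, and a disease-annotation
node set enriched around the planted regulators — together with ground-truth
tables for recovery tests.

Negative-binomial parameterization used throughout the package: a count with
mean ``mu`` and dispersion ``alpha`` has variance ``mu + alpha * mu**2``.
The dispersion follows the mean-dependent trend ``alpha(mu) = a1 + a0 / mu``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TF_GENE",
    "TF_MIRNA",
    "MIRNA_GENE",
    "MIRNA_MIRNA",
    "EDGE_TYPES",
    "SimConfig",
    "CountMatrix",
    "TruthTable",
    "InteractionDB",
    "DiseaseAnnotation",
    "simulate_counts",
    "simulate_interaction_db",
    "simulate_disease_annotation",
]

TF_GENE = "TF->gene"
TF_MIRNA = "TF->miRNA"
MIRNA_GENE = "miRNA->gene"
MIRNA_MIRNA = "miRNA->miRNA"
EDGE_TYPES = (TF_GENE, TF_MIRNA, MIRNA_GENE, MIRNA_MIRNA)

#: node-type labels
TF, MIRNA, GENE = "TF", "miRNA", "gene"

_EDGE_ENDPOINT_TYPES = {
    TF_GENE: (TF, GENE),
    TF_MIRNA: (TF, MIRNA),
    MIRNA_GENE: (MIRNA, GENE),
    MIRNA_MIRNA: (MIRNA, MIRNA),
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic experiment.

    ``n_genes`` counts all measured genes; the first ``n_tfs`` of them are
    transcription factors (they appear in the count matrix like any gene).
    miRNAs are regulator-only nodes and are not measured.
    """

    n_genes: int = 2000
    n_tfs: int = 150
    n_mirnas: int = 60
    n_per_group: int = 12
    de_fraction: float = 0.5
    lfc_scale: float = 1.0
    disp_a0: float = 0.5
    disp_a1: float = 0.05
    libsize_cv: float = 0.1
    disease_fraction: float = 0.5
    seed: int = 0
    # fraction of non-TF genes forming the preferentially-targeted core module
    module_fraction: float = 0.25
    # sampling weight of DE-adjacent nodes when drawing the disease set
    disease_hot_weight: float = 8.0
    # dynamic-range knobs for the baseline means (log-normal, clipped at 1)
    mu_meanlog: float = 4.0
    mu_sdlog: float = 2.0
    # minimum |log2 fold change| of planted DE genes
    lfc_min: float = 1.5

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_per_group"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        for name in ("n_tfs", "n_mirnas"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        for name in ("de_fraction", "disease_fraction"):
            v = getattr(self, name)
            if not math.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        for name in ("lfc_scale", "disp_a0", "disp_a1", "libsize_cv", "mu_sdlog"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.n_tfs > self.n_genes:
            raise ValueError("n_tfs cannot exceed n_genes (TFs are measured genes)")

    # --- identifier layout -------------------------------------------------
    def tf_ids(self) -> list[str]:
        return [f"TF{i + 1:04d}" for i in range(self.n_tfs)]

    def nontf_gene_ids(self) -> list[str]:
        return [f"G{i + 1:05d}" for i in range(self.n_genes - self.n_tfs)]

    def gene_ids(self) -> list[str]:
        """All measured genes: TFs first, then ordinary genes."""
        return self.tf_ids() + self.nontf_gene_ids()

    def mirna_ids(self) -> list[str]:
        return [f"MIR{i + 1:04d}" for i in range(self.n_mirnas)]


@dataclass
class CountMatrix:
    """Integer read counts, genes x samples, with a two-group annotation."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    group_labels: list[str]

    def __post_init__(self) -> None:
        # force one memory layout: reduction order affects floats at ~1e-16
        self.counts = np.ascontiguousarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("counts shape does not match gene/sample ids")
        if len(self.gene_ids) != len(set(self.gene_ids)):
            raise ValueError("gene_ids must be unique")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)) or np.any(self.counts < 0):
                raise ValueError("counts must be non-negative integers")
            self.counts = self.counts.astype(np.int64)
        groups = set(self.group_labels)
        if len(self.group_labels) != len(self.sample_ids) or len(groups) != 2:
            raise ValueError("exactly two non-empty sample groups are required")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def group_masks(self) -> tuple[np.ndarray, np.ndarray]:
        """Boolean masks for the two groups in label-sorted order."""
        labels = sorted(set(self.group_labels))
        arr = np.asarray(self.group_labels)
        return arr == labels[0], arr == labels[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class TruthTable:
    """Ground truth of a simulated count matrix.

    ``table`` has one row per gene: gene_id, is_de, true_log2fc, true_mu,
    true_dispersion. ``size_factors`` holds the planted per-sample scaling.
    """

    table: pd.DataFrame
    size_factors: np.ndarray

    @property
    def de_genes(self) -> set[str]:
        return set(self.table.loc[self.table["is_de"], "gene_id"])


@dataclass
class InteractionDB:
    """Typed directed regulatory interactions plus node-type annotation."""

    edges: list[tuple[str, str, str]]
    node_types: dict[str, str]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        for src, tgt, etype in self.edges:
            if etype not in _EDGE_ENDPOINT_TYPES:
                raise ValueError(f"unknown edge type {etype!r}")
            want_src, want_tgt = _EDGE_ENDPOINT_TYPES[etype]
            if self.node_types.get(src) != want_src or self.node_types.get(tgt) != want_tgt:
                raise ValueError(
                    f"edge ({src}, {tgt}, {etype}) inconsistent with node types "
                    f"({self.node_types.get(src)}, {self.node_types.get(tgt)})"
                )
            if src == tgt:
                raise ValueError(f"self-loop on {src}")
            key = (src, tgt, etype)
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)

    @property
    def nodes(self) -> set[str]:
        return set(self.node_types)

    def gene_universe(self) -> set[str]:
        """Nodes eligible as DE-input genes: measured genes including TFs."""
        return {n for n, t in self.node_types.items() if t in (GENE, TF)}

    def mirnas(self) -> set[str]:
        return {n for n, t in self.node_types.items() if t == MIRNA}

    def tfs(self) -> set[str]:
        return {n for n, t in self.node_types.items() if t == TF}

    def mirna_targets(self) -> dict[str, set[str]]:
        """miRNA -> set of gene targets (miRNA->gene edges)."""
        out: dict[str, set[str]] = {m: set() for m in self.mirnas()}
        for src, tgt, etype in self.edges:
            if etype == MIRNA_GENE:
                out[src].add(tgt)
        return out

    def mirna_regulator_tfs(self) -> dict[str, set[str]]:
        """miRNA -> set of TFs regulating it (TF->miRNA edges)."""
        out: dict[str, set[str]] = {m: set() for m in self.mirnas()}
        for src, tgt, etype in self.edges:
            if etype == TF_MIRNA:
                out[tgt].add(src)
        return out


@dataclass
class DiseaseAnnotation:
    """A named subset of the interaction-database node universe."""

    disease_name: str
    nodes: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# sampling primitives
# ---------------------------------------------------------------------------

def nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: np.ndarray) -> np.ndarray:
    """Draw NB(mean, variance = mean + dispersion * mean**2) counts.

    dispersion <= 1e-12 falls back to the Poisson limit.
    """
    mean = np.asarray(mean, dtype=float)
    dispersion = np.broadcast_to(np.asarray(dispersion, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    pois = dispersion <= 1e-12
    if np.any(pois):
        out[pois] = rng.poisson(mean[pois])
    if np.any(~pois):
        a = dispersion[~pois]
        m = mean[~pois]
        n = 1.0 / a
        p = 1.0 / (1.0 + a * m)
        out[~pois] = rng.negative_binomial(n, p)
    return out


def _weighted_sample_without_replacement(
    rng: np.random.Generator, items: list[str], weights: np.ndarray, k: int
) -> set[str]:
    # Efraimidis-Spirakis: keys u^(1/w), take the k largest
    if k >= len(items):
        return set(items)
    if k <= 0:
        return set()
    u = rng.random(len(items))
    keys = u ** (1.0 / np.asarray(weights, dtype=float))
    order = np.argsort(-keys, kind="stable")
    return {items[i] for i in order[:k]}


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def simulate_counts(
    config: SimConfig, db: InteractionDB | None = None
) -> tuple[CountMatrix, TruthTable]:
    """Simulate an overdispersed two-group count matrix with planted DE genes.

    Counts are NB with mean ``s_j * mu_i * 2**(±lfc_i/2)`` (group A down,
    group B up) and dispersion ``alpha(mu_i) = a1 + a0/mu_i``. Exactly
    ``round(de_fraction * n_genes)`` genes receive a nonzero log2 fold change
    whose magnitude is ``lfc_min + Exponential(lfc_scale)``.

    When ``db`` is given, DE genes are preferentially planted (weight 3:1) on
    regulator genes and regulator targets so downstream disease networks
    share structure across DE methods.
    """
    genes = config.gene_ids()
    n = config.n_genes
    rng = np.random.default_rng([config.seed, 11])

    mu = np.exp(rng.normal(config.mu_meanlog, config.mu_sdlog, n))
    mu = np.clip(mu, 1.0, None)
    alpha = config.disp_a1 + config.disp_a0 / mu

    n_de = int(round(config.de_fraction * n))
    weights = np.ones(n)
    if n_de > 0:
        hot = _regulatory_hot_genes(config, db)
        idx = {g: i for i, g in enumerate(genes)}
        for g in hot:
            if g in idx:
                weights[idx[g]] = 3.0
    de_idx = np.array(sorted(
        _weighted_sample_without_replacement(rng, list(range(n)), weights, n_de)
    ), dtype=int) if n_de else np.array([], dtype=int)

    lfc = np.zeros(n)
    if n_de:
        signs = rng.choice([-1.0, 1.0], size=n_de)
        lfc[de_idx] = signs * (config.lfc_min + rng.exponential(config.lfc_scale, n_de))

    n_samp = 2 * config.n_per_group
    if config.libsize_cv > 0:
        sigma = math.sqrt(math.log1p(config.libsize_cv**2))
        sf = np.exp(rng.normal(0.0, sigma, n_samp))
        sf /= np.exp(np.mean(np.log(sf)))  # geometric mean 1
    else:
        sf = np.ones(n_samp)

    groups = ["A"] * config.n_per_group + ["B"] * config.n_per_group
    samples = [f"{g}{i + 1:03d}" for g in ("A", "B") for i in range(config.n_per_group)]
    shift = np.where(np.asarray(groups) == "A", -0.5, 0.5)
    mean = mu[:, None] * 2.0 ** (lfc[:, None] * shift[None, :]) * sf[None, :]
    counts = nb_sample(rng, mean, alpha[:, None])

    cm = CountMatrix(genes, samples, counts, groups)
    is_de = np.zeros(n, dtype=bool)
    is_de[de_idx] = True
    truth = TruthTable(
        table=pd.DataFrame(
            {
                "gene_id": genes,
                "is_de": is_de,
                "true_log2fc": lfc,
                "true_mu": mu,
                "true_dispersion": alpha,
            }
        ),
        size_factors=sf,
    )
    return cm, truth


def _regulatory_hot_genes(config: SimConfig, db: InteractionDB | None) -> set[str]:
    """Measured genes favoured for DE planting: regulators and their targets."""
    if db is None:
        return set(config.tf_ids())
    hot = set(db.tfs())
    for src, tgt, etype in db.edges:
        if etype in (TF_GENE, MIRNA_GENE):
            hot.add(tgt)
    return hot


def simulate_interaction_db(config: SimConfig) -> InteractionDB:
    """Generate a typed interaction database with heavy-tailed out-degrees.

    Each regulator (TF or miRNA) receives a Pareto-tailed out-degree.
    Targets are drawn preferentially from a core module of genes
    (``module_fraction`` of the non-TF genes), which concentrates regulation
    the way curated repositories concentrate on well-studied pathways and
    gives DE-derived networks a coherent largest component. All four edge
    types are guaranteed present whenever both regulator classes exist.
    """
    if config.n_tfs == 0 and config.n_mirnas == 0:
        raise ValueError("interaction database needs at least one regulator class")
    rng = np.random.default_rng([config.seed, 23])
    tfs = config.tf_ids()
    genes = config.nontf_gene_ids()
    mirnas = config.mirna_ids()
    n_module = int(round(config.module_fraction * len(genes)))
    module = genes[:n_module] if n_module else genes

    node_types: dict[str, str] = {}
    node_types.update({t: TF for t in tfs})
    node_types.update({g: GENE for g in genes})
    node_types.update({m: MIRNA for m in mirnas})

    edges: dict[tuple[str, str, str], None] = {}

    def add(src: str, tgt: str, etype: str) -> None:
        if src != tgt:
            edges.setdefault((src, tgt, etype), None)

    def out_degree() -> int:
        return 3 + int(rng.pareto(1.05) * 5)

    def gene_target() -> str:
        pool = module if rng.random() < 0.7 else genes
        return pool[rng.integers(len(pool))]

    for tf in tfs:
        deg = min(out_degree(), max(1, len(genes) + len(mirnas) - 1))
        for _ in range(deg):
            if mirnas and rng.random() < 0.15:
                add(tf, mirnas[rng.integers(len(mirnas))], TF_MIRNA)
            elif genes:
                add(tf, gene_target(), TF_GENE)
    for mi in mirnas:
        deg = min(out_degree(), max(1, len(genes) + len(mirnas) - 1))
        for _ in range(deg):
            if len(mirnas) > 1 and rng.random() < 0.15:
                add(mi, mirnas[rng.integers(len(mirnas))], MIRNA_MIRNA)
            elif genes:
                add(mi, gene_target(), MIRNA_GENE)

    # guarantee every representable edge type shows up
    if tfs and genes:
        add(tfs[0], genes[0], TF_GENE)
    if tfs and mirnas:
        add(tfs[0], mirnas[0], TF_MIRNA)
    if mirnas and genes:
        add(mirnas[0], genes[0], MIRNA_GENE)
    if len(mirnas) > 1:
        add(mirnas[0], mirnas[1], MIRNA_MIRNA)

    return InteractionDB(edges=list(edges), node_types=node_types)


def simulate_disease_annotation(
    db: InteractionDB, config: SimConfig, truth: TruthTable
) -> DiseaseAnnotation:
    """Sample a disease node set enriched around the planted-DE neighbourhood.

    Nodes that are planted-DE genes, or direct graph neighbours of one, carry
    sampling weight ``disease_hot_weight``; regulators (TFs/miRNAs) wired into
    the planted-DE neighbourhood carry four times that; all others weight 1.
    Set size is ``round(disease_fraction * |nodes|)``.
    """
    if not db.nodes:
        raise ValueError("interaction database is empty")
    nodes = sorted(db.node_types)
    k = int(round(config.disease_fraction * len(nodes)))
    if k == 0:
        return DiseaseAnnotation("synthetic_disease", set())
    if k >= len(nodes):
        return DiseaseAnnotation("synthetic_disease", set(nodes))

    de = truth.de_genes
    hot = set(de)
    regulators = {n for n, t in db.node_types.items() if t in (TF, MIRNA)}
    reg_hot = set()  # regulators wired into the planted-DE neighbourhood
    for src, tgt, _ in db.edges:
        if tgt in de:
            hot.add(src)
            if src in regulators:
                reg_hot.add(src)
        if src in de:
            hot.add(tgt)
    reg_hot |= de & regulators
    w = config.disease_hot_weight
    weights = np.array(
        [4.0 * w if nd in reg_hot else w if nd in hot else 1.0 for nd in nodes]
    )
    rng = np.random.default_rng([config.seed, 37])
    chosen = _weighted_sample_without_replacement(rng, nodes, weights, k)
    return DiseaseAnnotation("synthetic_disease", chosen)
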