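"""Cross-method topology consistency and random-gene-set robustness.

The consistency statistic throughout is the overlap coefficient
``|X ∩ Y| / min(|X|, |Y|)``. The robustness test rebuilds the network
pipeline on random pseudo-DE gene sets and reports an add-one empirical
p-value ``(r + 1) / (N + 1)`` for each key-player feature.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from coregnet.de_methods import DEGeneSet
from coregnet.keyplayers import KeyPlayerReport, key_player_report
from coregnet.netbuild import (
    RegulatoryNetwork,
    build_network,
    disease_filter,
    recover_mirnas,
)
from coregnet.simdata import DiseaseAnnotation, InteractionDB

__all__ = [
    "OverlapReport",
    "RobustnessReport",
    "NetworkStageConfig",
    "overlap_coefficient",
    "pairwise_overlap_matrix",
    "common_across_methods",
    "venn_counts",
    "network_from_genes",
    "random_baseline",
]

FEATURES = ("hubs", "mds", "mcds")


@dataclass
class OverlapReport:
    feature: str
    method_pair: tuple[str, str]
    overlap_pct: float | None  # None when either feature set is empty
    intersection_size: int
    set_sizes: tuple[int, int]


@dataclass
class RobustnessReport:
    feature: str
    real_overlap_pct: float
    random_overlaps: list[float]
    empirical_p: float
    n_random: int
    random_set_size: int
    seed: int


@dataclass
class NetworkStageConfig:
    """Everything needed to turn a gene set into a key-player report."""

    db: InteractionDB
    disease: DiseaseAnnotation | None = None
    enrich_cutoff: float = 0.001
    hub_fraction: float = 0.10
    mds_exact: bool = True
    require_both_endpoints: bool = True


def overlap_coefficient(x: set, y: set) -> float:
    """``|X ∩ Y| / min(|X|, |Y|)``; errors on empty input sets."""
    if not x or not y:
        raise ValueError("overlap coefficient is undefined for empty sets")
    return len(set(x) & set(y)) / min(len(x), len(y))


def pairwise_overlap_matrix(
    reports: dict[str, KeyPlayerReport], features: tuple[str, ...] = FEATURES
) -> list[OverlapReport]:
    """One overlap record per unordered method pair and feature.

    An empty feature set yields ``overlap_pct=None`` (missing, not zero).
    """
    if len(reports) < 2:
        raise ValueError("need at least two methods to compare")
    out: list[OverlapReport] = []
    for m1, m2 in itertools.combinations(sorted(reports), 2):
        for feat in features:
            x = reports[m1].feature(feat)
            y = reports[m2].feature(feat)
            pct = 100.0 * overlap_coefficient(x, y) if x and y else None
            out.append(
                OverlapReport(
                    feature=feat,
                    method_pair=(m1, m2),
                    overlap_pct=pct,
                    intersection_size=len(x & y),
                    set_sizes=(len(x), len(y)),
                )
            )
    return out


def common_across_methods(sets: list[set]) -> set:
    """Intersection of all given sets."""
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    out = set(sets[0])
    for s in sets[1:]:
        out &= set(s)
    return out


def venn_counts(
    networks: dict[str, RegulatoryNetwork]
) -> dict[str, dict[tuple[str, ...], int]]:
    """Venn-region counts over node-id sets and over typed edge sets.

    Regions are keyed by the sorted tuple of methods containing the element.
    """
    if len(networks) < 2:
        raise ValueError("need at least two networks")
    out: dict[str, dict[tuple[str, ...], int]] = {}
    for kind in ("nodes", "edges"):
        sets = {
            m: (net.nodes if kind == "nodes" else net.edges)
            for m, net in networks.items()
        }
        regions: dict[tuple[str, ...], int] = {}
        universe = set().union(*sets.values())
        for el in universe:
            key = tuple(sorted(m for m, s in sets.items() if el in s))
            regions[key] = regions.get(key, 0) + 1
        out[kind] = regions
    return out


def network_from_genes(
    genes: set[str], method_name: str, cfg: NetworkStageConfig
) -> RegulatoryNetwork:
    """Run miRNA recovery, network construction and the disease filter."""
    de = DEGeneSet(method_name=method_name, genes=set(genes), alpha=float("nan"))
    recs = recover_mirnas(cfg.db, de, cutoff=cfg.enrich_cutoff)
    recovered = {r.mirna_id for r in recs if r.recovered}
    net = build_network(cfg.db, de, recovered)
    if cfg.disease is not None:
        net = disease_filter(
            net, cfg.disease, require_both_endpoints=cfg.require_both_endpoints
        )
    return net


def random_baseline(
    universe: list[str],
    m: int,
    n_random: int,
    reference: KeyPlayerReport,
    cfg: NetworkStageConfig,
    seed: int,
    real_overlap_pct: dict[str, float] | None = None,
) -> list[RobustnessReport]:
    """Key-player overlap of the reference against random pseudo-DE networks.

    Draws ``n_random`` gene sets of size ``m`` without replacement, runs the
    identical network stage on each, and scores the overlap of every feature
    with the reference report (0 when the random feature set or network is
    empty). ``real_overlap_pct`` supplies the observed per-feature overlap
    (e.g. minimum across method pairs); when absent, 100 is used per feature
    (self-overlap of the reference).

    Empirical p per feature is ``(r + 1)/(n_random + 1)`` with
    ``r = #{random >= real}``.
    """
    if n_random <= 0:
        raise ValueError("n_random must be positive")
    if m > len(universe):
        raise ValueError("random set size exceeds the gene universe")
    rng = np.random.default_rng(seed)
    universe = sorted(universe)
    overlaps: dict[str, list[float]] = {f: [] for f in FEATURES}
    for _ in range(n_random):
        genes = set(rng.choice(universe, size=m, replace=False))
        net = network_from_genes(genes, "random", cfg)
        if net.n_nodes == 0:
            for f in FEATURES:
                overlaps[f].append(0.0)
            continue
        rep = key_player_report(
            net, "random", hub_fraction=cfg.hub_fraction, mds_exact=cfg.mds_exact
        )
        for f in FEATURES:
            x = reference.feature(f)
            y = rep.feature(f)
            overlaps[f].append(100.0 * overlap_coefficient(x, y) if x and y else 0.0)

    reports = []
    for f in FEATURES:
        real = 100.0 if real_overlap_pct is None else real_overlap_pct[f]
        r = sum(1 for v in overlaps[f] if v >= real)
        reports.append(
            RobustnessReport(
                feature=f,
                real_overlap_pct=real,
                random_overlaps=overlaps[f],
                empirical_p=(r + 1) / (n_random + 1),
                n_random=n_random,
                random_set_size=m,
                seed=seed,
            )
        )
    return reports
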