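"""End-to-end orchestration: simulate/load, DE, networks, key players,
consistency tables, Venn counts and the robustness experiment.

Every stage writes its outputs as TSV under the run directory so any stage
can be re-run from its persisted inputs; a JSON manifest records the
configuration, seed and resulting cardinalities.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from coregnet import io
from coregnet.consistency import (
    FEATURES,
    NetworkStageConfig,
    common_across_methods,
    network_from_genes,
    overlap_coefficient,
    pairwise_overlap_matrix,
    random_baseline,
    venn_counts,
)
from coregnet.de_methods import (
    DEResult,
    run_deseq_like,
    run_edger_like,
    run_voom_like,
    run_vst_like,
    significant_genes,
)
from coregnet.keyplayers import key_player_report
from coregnet.simdata import (
    CountMatrix,
    DiseaseAnnotation,
    InteractionDB,
    SimConfig,
    simulate_counts,
    simulate_disease_annotation,
    simulate_interaction_db,
)

log = logging.getLogger("coregnet")

METHOD_RUNNERS = {
    "deseq_like": run_deseq_like,
    "edger_like": run_edger_like,
    "vst_like": run_vst_like,
    "voom_like": run_voom_like,
}

ALL_METHODS = tuple(METHOD_RUNNERS)


@dataclass
class PipelineConfig:
    """Configuration of one full study run."""

    out_dir: str = "run"
    sim: SimConfig | None = None  # simulate inputs when set
    counts_path: str | None = None
    groups_path: str | None = None
    db_edges_path: str | None = None
    db_nodes_path: str | None = None
    disease_path: str | None = None
    methods: tuple[str, ...] = ALL_METHODS
    de_alpha: float = 0.05
    enrich_cutoff: float = 0.001
    hub_fraction: float = 0.10
    n_random: int = 100
    random_set_size: int | None = None  # default: size of the reference DE set
    reference_method: str = "deseq_like"
    mds_exact: bool = True
    apply_disease_filter: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("method list must be non-empty")
        unknown = set(self.methods) - set(METHOD_RUNNERS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        for name in ("de_alpha", "enrich_cutoff", "hub_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")


@dataclass
class StudyResult:
    """In-memory handle on everything a full run produced."""

    de_results: dict[str, DEResult]
    de_sets: dict[str, set[str]]
    networks: dict
    reports: dict
    de_overlaps: list
    keyplayer_overlaps: list
    robustness: list
    out_dir: Path


def _load_inputs(cfg: PipelineConfig, out: Path):
    if cfg.sim is not None:
        sim = cfg.sim
        db = simulate_interaction_db(sim)
        cm, truth = simulate_counts(sim, db=db)
        disease = simulate_disease_annotation(db, sim, truth)
        inputs = out / "inputs"
        inputs.mkdir(parents=True, exist_ok=True)
        io.write_sim_config(sim, inputs / "sim_config.txt")
        io.write_counts(cm, inputs / "counts.tsv", inputs / "groups.tsv")
        io.write_interaction_db(db, inputs / "db_edges.tsv", inputs / "db_nodes.tsv")
        io.write_disease(disease, inputs / "disease.tsv")
        io.write_truth(truth, inputs / "truth.tsv", inputs / "size_factors.tsv")
        return cm, db, disease
    if not (cfg.counts_path and cfg.groups_path and cfg.db_edges_path and cfg.db_nodes_path):
        raise ValueError("either sim or all input paths must be provided")
    cm = io.read_counts(cfg.counts_path, cfg.groups_path)
    db = io.read_interaction_db(cfg.db_edges_path, cfg.db_nodes_path)
    disease = (
        io.read_disease(cfg.disease_path) if cfg.disease_path else DiseaseAnnotation("all", set())
    )
    return cm, db, disease


def run_full_study(cfg: PipelineConfig) -> StudyResult:
    """Execute the whole pipeline and persist every report under out_dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        cm, db, disease = _load_inputs(cfg, out)
    except Exception:
        log.error("stage failed: inputs")
        raise

    # --- stage: differential expression -----------------------------------
    de_results: dict[str, DEResult] = {}
    de_sets: dict[str, set[str]] = {}
    de_dir = out / "de"
    de_dir.mkdir(exist_ok=True)
    for method in cfg.methods:
        try:
            res = METHOD_RUNNERS[method](cm)
        except Exception:
            log.error("stage failed: de (%s)", method)
            raise
        de_results[method] = res
        de_sets[method] = significant_genes(res, cfg.de_alpha).genes
        res.table.to_csv(de_dir / f"{method}.tsv", sep="\t", index=False)
        io.write_gene_list(de_sets[method], de_dir / f"{method}_genes.tsv")
        log.info("de %s: %d significant genes", method, len(de_sets[method]))

    de_overlaps = []
    if len(cfg.methods) >= 2:
        import itertools

        for m1, m2 in itertools.combinations(sorted(cfg.methods), 2):
            x, y = de_sets[m1], de_sets[m2]
            pct = 100.0 * overlap_coefficient(x, y) if x and y else None
            de_overlaps.append(
                {"method_1": m1, "method_2": m2, "overlap_pct": pct,
                 "intersection": len(x & y), "size_1": len(x), "size_2": len(y)}
            )
        pd.DataFrame(de_overlaps).to_csv(out / "de_overlap.tsv", sep="\t", index=False)
    else:
        log.info("single method: overlap tables skipped")

    # --- stage: networks + key players -------------------------------------
    stage_cfg = NetworkStageConfig(
        db=db,
        disease=disease if cfg.apply_disease_filter else None,
        enrich_cutoff=cfg.enrich_cutoff,
        hub_fraction=cfg.hub_fraction,
        mds_exact=cfg.mds_exact,
    )
    networks, reports = {}, {}
    net_dir = out / "networks"
    net_dir.mkdir(exist_ok=True)
    for method in cfg.methods:
        try:
            net = network_from_genes(de_sets[method], method, stage_cfg)
        except Exception:
            log.error("stage failed: netbuild (%s)", method)
            raise
        networks[method] = net
        io.write_network(net, net_dir / f"{method}_edges.tsv", net_dir / f"{method}_nodes.tsv")
        log.info("network %s: %d nodes, %d edges", method, net.n_nodes, net.n_edges)
        if net.n_nodes == 0:
            log.warning("network %s is empty; key players skipped", method)
            continue
        rep = key_player_report(
            net, method, hub_fraction=cfg.hub_fraction, mds_exact=cfg.mds_exact
        )
        reports[method] = rep
        rows = [
            {"node": v, "in_hubs": v in rep.hubs, "in_mds": v in rep.mds,
             "in_mcds": v in rep.mcds}
            for v in sorted(net.nodes)
        ]
        pd.DataFrame(rows).to_csv(net_dir / f"{method}_keyplayers.tsv", sep="\t", index=False)

    # --- stage: consistency -------------------------------------------------
    keyplayer_overlaps = []
    if len(reports) >= 2:
        keyplayer_overlaps = pairwise_overlap_matrix(reports)
        pd.DataFrame(
            [
                {"feature": r.feature, "method_1": r.method_pair[0],
                 "method_2": r.method_pair[1],
                 "overlap_pct": None if r.overlap_pct is None else round(r.overlap_pct),
                 "overlap_pct_exact": r.overlap_pct,
                 "intersection": r.intersection_size,
                 "size_1": r.set_sizes[0], "size_2": r.set_sizes[1]}
                for r in keyplayer_overlaps
            ]
        ).to_csv(out / "keyplayer_overlap.tsv", sep="\t", index=False)
        for feat in FEATURES:
            sets = [rep.feature(feat) for rep in reports.values()]
            io.write_gene_list(common_across_methods(sets), out / f"common_{feat}.tsv")
        vc = venn_counts(networks={m: networks[m] for m in reports})
        with open(out / "venn_counts.json", "w") as fh:
            json.dump(
                {kind: {"|".join(k): v for k, v in regions.items()}
                 for kind, regions in vc.items()},
                fh, indent=2, sort_keys=True,
            )

    # --- stage: robustness --------------------------------------------------
    robustness = []
    ref = cfg.reference_method if cfg.reference_method in reports else None
    if ref is None and reports:
        ref = sorted(reports)[0]
    if ref is not None and cfg.n_random > 0:
        real = _real_overlap_vs_reference(reports, ref)
        m = cfg.random_set_size or len(de_sets[ref])
        universe = sorted(set(cm.gene_ids))
        try:
            robustness = random_baseline(
                universe, m, cfg.n_random, reports[ref], stage_cfg,
                seed=cfg.seed + 1000, real_overlap_pct=real,
            )
        except Exception:
            log.error("stage failed: robustness")
            raise
        pd.DataFrame(
            [
                {"feature": r.feature, "real_overlap_pct": r.real_overlap_pct,
                 "empirical_p": r.empirical_p, "n_random": r.n_random,
                 "random_set_size": r.random_set_size,
                 "max_random_overlap": max(r.random_overlaps)}
                for r in robustness
            ]
        ).to_csv(out / "robustness.tsv", sep="\t", index=False)
        pd.DataFrame(
            {r.feature: r.random_overlaps for r in robustness}
        ).to_csv(out / "robustness_replicates.tsv", sep="\t", index=False)

    manifest = {
        "config": _manifest_config(cfg),
        "n_genes": cm.n_genes,
        "n_samples": cm.n_samples,
        "de_set_sizes": {m: len(s) for m, s in de_sets.items()},
        "network_sizes": {m: [networks[m].n_nodes, networks[m].n_edges] for m in networks},
        "versions": _versions(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return StudyResult(
        de_results=de_results,
        de_sets=de_sets,
        networks=networks,
        reports=reports,
        de_overlaps=de_overlaps,
        keyplayer_overlaps=keyplayer_overlaps,
        robustness=robustness,
        out_dir=out,
    )


def _real_overlap_vs_reference(reports: dict, ref: str) -> dict[str, float]:
    """Per feature: the minimum overlap of the reference with any other method.

    With a single method the reference's self-overlap (100) is used.
    """
    real = {}
    for feat in FEATURES:
        vals = []
        for m, rep in reports.items():
            if m == ref:
                continue
            x, y = reports[ref].feature(feat), rep.feature(feat)
            if x and y:
                vals.append(100.0 * overlap_coefficient(x, y))
        real[feat] = min(vals) if vals else 100.0
    return real


def _manifest_config(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    d.pop("out_dir")  # keep the manifest location-independent
    if cfg.sim is not None:
        d["sim"] = asdict(cfg.sim)
    d["methods"] = list(cfg.methods)
    return d


def _versions() -> dict[str, str]:
    import networkx
    import numpy
    import pandas as pd_
    import scipy

    import coregnet

    return {
        "coregnet": coregnet.__version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pd_.__version__,
        "networkx": networkx.__version__,
    }
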