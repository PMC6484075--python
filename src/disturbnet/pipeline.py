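"""End-to-end orchestration: classify -> community stats -> infer(before)
-> infer(after) -> topology comparison, with a reproducibility manifest."""

from __future__ import annotations

import time
from pathlib import Path

import pandas as pd

from . import classification as clf
from . import community, network, topology
from .config import RunConfig
from .io import AbundanceTable, PhaseDesign, write_results

__all__ = ["run_pipeline"]


def run_pipeline(
    table: AbundanceTable,
    design: PhaseDesign,
    out_dir: str | Path,
    config: RunConfig | None = None,
    annotations: pd.DataFrame | None = None,
) -> dict:
    """Execute every stage and write all artifacts.

    Returns a dict with the in-memory results (labels, networks, niche
    table, summaries) and the artifact paths.  Outputs are byte-identical
    across runs with the same inputs and seed.
    """
    config = config or RunConfig()
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    labels = clf.classify_all(
        table,
        design,
        alpha=config.alpha,
        ha_threshold=config.ha_threshold,
        la_threshold=config.la_threshold,
        ncore_min_presence=config.ncore_min_presence,
    )
    summary = clf.class_summary(labels)
    timings["classify"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    stats = community.sample_summary(table, annotations)
    pca, explained, _ = community.pca_scores(table)
    pca.loc["explained_var"] = explained[: pca.shape[1]]
    timings["stats"] = time.perf_counter() - t0

    nets = {}
    for phase in ("before", "after"):
        t0 = time.perf_counter()
        nets[phase] = network.infer_network(
            table,
            design,
            phase=phase,
            n_replicates=config.n_replicates,
            subsample_fraction=config.subsample_fraction,
            p0=config.p0,
            mode=config.mode,
            alpha=config.consensus_alpha,
            top_frac=config.top_frac,
            ridge=config.ridge,
            pseudocount=config.pseudocount,
            renormalize=config.renormalize,
            seed=config.seed,
        )
        timings[f"infer_{phase}"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    niches = topology.compare_networks(nets["before"], nets["after"])
    for tag in ("before", "after"):
        betw = topology.betweenness(nets[tag])
        for node, value in betw.items():
            nets[tag].nodes[node]["betweenness"] = value
            nets[tag].nodes[node]["in_degree"] = int(nets[tag].in_degree(node))
    summaries = {
        "class_summary": summary.set_index(
            ["presence_class", "abundance_class", "stability_class"]
        ),
        "sample_summary": stats.set_index("sample"),
        "pca_scores": pca,
        "niches": niches.set_index("taxon"),
    }
    if annotations is not None:
        props = clf.aggregate_properties(labels, annotations)
        summaries["genomic_summary"] = props["genomic"].set_index(
            ["metric", "stability_class"]
        )
        summaries["genomic_tests"] = props["genomic_tests"].set_index("metric")
        summaries["pathway_summary"] = props["pathways"].set_index("abundance_class")
        for tag in ("before", "after"):
            nets[tag], _ = topology.overlay_pathways(nets[tag], annotations)
        summaries["niche_pathways"] = topology.niche_pathway_summary(
            niches, annotations
        ).set_index(["pathway_category", "network"])
    timings["topology"] = time.perf_counter() - t0

    cfg = config.to_dict()
    cfg["stage_timings_s"] = {k: round(v, 3) for k, v in timings.items()}
    written = write_results(
        out_dir,
        classification=labels,
        networks=nets,
        summaries=summaries,
        config=cfg,
        seed=config.seed,
    )
    return {
        "labels": labels,
        "networks": nets,
        "niches": niches,
        "summaries": summaries,
        "artifacts": written,
    }
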