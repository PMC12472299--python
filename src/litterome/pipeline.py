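"""End-to-end orchestration: normalize → diversity/substrate → assembly/network/biomarkers.

A single :class:`PipelineConfig` names the inputs, toggles stages and carries
one global seed; every stochastic stage derives its own seed from it, so one
integer reproduces the whole run byte-for-byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, assembly, diversity, io, lefse, network, substrate
from .containers import CommunityTable

log = logging.getLogger("litterome")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    table_path: str | None = None
    tree_path: str | None = None
    metadata_path: str | None = None
    enzymes_path: str | None = None
    bands_path: str | None = None
    out_dir: str = "litterome_out"
    seed: int = 0

    run_diversity: bool = False
    run_substrate: bool = False
    run_assembly: bool = False
    run_network: bool = False
    run_lefse: bool = False

    rarefy_depth: int | None = None  # None = minimum sample total
    n_perm: int = 999
    n_null: int = 999
    pairs: str = "within-group"
    rho_min: float = 0.8
    q_max: float = 0.01
    min_abundance: float = 1e-4
    min_occupancy: float = 0.8
    kw_alpha: float = 0.01
    lda_min: float = 3.0


def _preflight(config: PipelineConfig) -> None:
    needs = []
    if config.run_diversity or config.run_assembly or config.run_network or config.run_lefse:
        needs.append(("table_path", config.table_path))
        needs.append(("metadata_path", config.metadata_path))
    if config.run_assembly:
        needs.append(("tree_path", config.tree_path))
    if config.run_substrate:
        if config.enzymes_path is None and config.bands_path is None:
            raise ValueError("substrate stage enabled but neither enzymes nor bands given")
    gaps = [name for name, value in needs if value is None]
    if gaps:
        raise ValueError(f"enabled stages are missing inputs: {gaps}")
    for name, value in needs:
        if value is not None and not Path(value).exists():
            raise FileNotFoundError(f"{name} does not exist: {value}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute enabled stages in dependency order; return the report dict.

    Writes per-stage tables under ``out_dir`` plus ``report.json`` and
    ``report.md``.
    """
    _preflight(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {k: v for k, v in vars(config).items()},
        "stages": {},
    }

    table = tree = metadata = None
    if config.table_path:
        metadata = io.read_metadata(config.metadata_path) if config.metadata_path else None
        table = io.read_community(config.table_path, metadata=metadata)
    if config.tree_path:
        tree = io.read_tree(config.tree_path)

    norm = None
    if table is not None and (config.run_diversity or config.run_assembly
                              or config.run_network or config.run_lefse):
        log.info("normalize: rarefying to common depth")
        norm = diversity.rarefy(table, depth=config.rarefy_depth, seed=config.seed)
        io.write_community(norm, out / "rarefied.tsv", stage="normalize", seed=config.seed)

    if config.run_diversity:
        log.info("diversity stage")
        alpha = diversity.alpha_diversity(norm)
        io.write_csv_table(alpha, out / "alpha_diversity.csv", stage="diversity")
        rel = diversity.relative_abundance(norm)
        dm = diversity.bray_curtis(rel)
        io.write_distance_matrix(dm, out / "bray_curtis.tsv", stage="diversity")
        ord_res = diversity.pcoa(dm)
        io.write_csv_table(ord_res.coordinates, out / "pcoa_coordinates.csv", stage="diversity")
        pnova = diversity.permanova(dm, norm.groups(), n_perm=config.n_perm, seed=config.seed + 1)
        pdisp = diversity.permdisp(dm, norm.groups(), n_perm=config.n_perm, seed=config.seed + 2)
        report["stages"]["diversity"] = {
            "permanova": vars(pnova),
            "permdisp": vars(pdisp),
            "proportion_explained": list(ord_res.proportion_explained[:3]),
        }

    if config.run_substrate:
        log.info("substrate stage")
        stage: dict = {}
        if config.enzymes_path:
            enz = io.read_csv_table(config.enzymes_path)
            stoich = substrate.stoichiometry_table(enz)
            io.write_csv_table(stoich, out / "enzyme_stoichiometry.csv", stage="substrate")
            stage["mean_vector_length"] = float(stoich["vector_length"].mean())
            stage["mean_vector_angle"] = float(stoich["vector_angle"].mean())
        if config.bands_path:
            bands = io.read_csv_table(config.bands_path)
            idx = substrate.indices_table(bands)
            io.write_csv_table(idx, out / "quality_indices.csv", stage="substrate")
            stage["mean_index_I"] = float(idx["index_I"].mean())
            stage["mean_index_II"] = float(idx["index_II"].mean())
        report["stages"]["substrate"] = stage

    if config.run_assembly:
        log.info("assembly stage (null models)")
        pairs = assembly.assembly_pairs(
            norm, tree, n_null=config.n_null, seed=config.seed + 3, pairs=config.pairs
        )
        pairs.to_csv(out / "assembly_pairs.tsv", sep="\t", index=False)
        summary = assembly.summarize(pairs)
        io.write_csv_table(summary, out / "assembly_summary.csv",
                           stage="assembly", index_label="group")
        pooled = assembly.summarize(pairs.assign(pooled="all"), by="pooled")
        report["stages"]["assembly"] = {
            "stochastic_fraction": float(pooled["stochastic"].iloc[0]),
            "n_pairs": int(pooled["n_pairs"].iloc[0]),
        }

    if config.run_network:
        log.info("network stage")
        filtered = network.prevalence_filter(
            norm, min_abundance=config.min_abundance, min_occupancy=config.min_occupancy
        )
        graph = network.correlation_network(filtered, rho_min=config.rho_min, q_max=config.q_max)
        modules = network.detect_modules(graph, seed=config.seed + 4)
        roles = network.node_roles(graph, modules)
        io.write_network(graph, out / "network", roles=roles)
        coh = network.cohesion(diversity.relative_abundance(filtered), seed=config.seed + 5)
        io.write_csv_table(coh, out / "cohesion.csv", stage="network", seed=config.seed + 5)
        report["stages"]["network"] = {
            "n_nodes": graph.number_of_nodes(),
            "n_edges": graph.number_of_edges(),
            "n_modules": len(set(modules.values())),
            "n_keystone": int(roles["keystone"].sum()),
        }

    if config.run_lefse:
        log.info("biomarker stage")
        features = lefse.build_clade_features(norm)
        result = lefse.lefse(
            features, norm.groups(), kw_alpha=config.kw_alpha,
            lda_min=config.lda_min, seed=config.seed + 6,
        )
        result.biomarkers.to_csv(out / "biomarkers.csv", index=False)
        report["stages"]["lefse"] = {"n_biomarkers": len(result.biomarkers)}

    io.write_json(report, out / "report.json")
    _write_markdown_report(report, out / "report.md")
    return report


def _write_markdown_report(report: dict, path: Path) -> None:
    lines = [
        f"# litterome pipeline report (v{report['version']})",
        "",
        f"Seed: {report['seed']}",
        "",
        "## Parameters",
        "",
    ]
    lines += [f"- {k}: {v}" for k, v in report["parameters"].items()]
    for stage, payload in report["stages"].items():
        lines += ["", f"## {stage}", ""]
        lines += [f"- {k}: {v}" for k, v in payload.items()]
    path.write_text("\n".join(lines) + "\n")
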