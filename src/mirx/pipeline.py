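"""End-to-end orchestration: hybridize -> screen -> network -> enrich.

`generate_inputs` materializes a synthetic study directory from a
:class:`~mirx.synthgen.SynthConfig`; `run_pipeline` executes the full
analysis from a :class:`PipelineConfig`, writing per-stage TSVs, a run log
and a machine-readable summary.  Outputs are deterministic for a fixed
config: reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from . import fileio
from .enrich import classify_tissue_levels, enrich_module, map_to_slim
from .hybridize import assign_pvalues, calibrate_null, scan_transcript
from .netcore import build_graph, decompose_modules, pagerank_weights, \
    select_bridges
from .screen import PROFILES, FilterProfile, apply_filters, rank_targets, \
    validate_three_level, validation_summary
from .synthgen import SynthConfig, gen_annotations, gen_expression, \
    gen_mirnas, gen_network, gen_transcripts_with_sites, validated_targets


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass(frozen=True)
class PipelineConfig:
    """Validated run configuration; unknown keys are rejected on load."""

    mirnas: str
    targets: str
    edges: str
    ontology: str
    annotations: str
    slim: str
    expression: str
    validated: Optional[str] = None
    profile: str = "plant"
    p_max: Optional[float] = None
    mfe_max: Optional[float] = None
    k_bridges: int = 15
    mode: str = "adjacency"
    tol: float = 0.005
    min_module_size: int = 3
    alpha: float = 0.1
    propagate: bool = True
    detect_thresh: float = 1.0
    z_thresh: float = 1.0
    n_shuffles: int = 200
    report_max: float = -10.0
    seed: int = 42

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def filter_profile(self) -> FilterProfile:
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        prof = PROFILES[self.profile]
        overrides = {}
        if self.p_max is not None:
            overrides["p_max"] = self.p_max
        if self.mfe_max is not None:
            overrides["mfe_max"] = self.mfe_max
        return dataclasses.replace(prof, **overrides) if overrides else prof


def _mirna_seed(base_seed: int, idx: int) -> int:
    return (base_seed + 7919 * (idx + 1)) % (2 ** 31)


def generate_inputs(cfg: SynthConfig, outdir) -> dict:
    """Write every synthetic input plus truth tables; return the paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)

    mirnas = gen_mirnas(cfg)
    regions, site_truth = gen_transcripts_with_sites(cfg, mirnas)
    net, net_truth = gen_network(cfg)
    annotation, slim, term_truth = gen_annotations(cfg, net_truth)
    genes = sorted(net.graph.nodes)
    expr, tier_truth = gen_expression(cfg, genes)

    paths = {
        "mirnas": str(out / "mirnas.fa"),
        "targets": str(out / "targets.fa"),
        "edges": str(out / "edges.tsv"),
        "ontology": str(out / "ontology.obo"),
        "annotations": str(out / "annotations.tsv"),
        "slim": str(out / "slim.txt"),
        "expression": str(out / "expression.tsv"),
        "validated": str(out / "validated.tsv"),
    }
    fileio.write_mirnas(mirnas, paths["mirnas"])
    fileio.write_regions(regions, paths["targets"])
    fileio.write_edges_tsv(net.graph.edges(), paths["edges"])
    fileio.write_obo(annotation.ontology, paths["ontology"])
    fileio.write_annotations_tsv(annotation.gene2terms, paths["annotations"])
    fileio.write_slim_list(slim, paths["slim"])
    fileio.write_expression_tsv(expr, paths["expression"])
    fileio.write_validated_tsv(validated_targets(site_truth),
                               paths["validated"])

    site_truth.to_csv(truth_dir / "planted_sites.tsv", sep="\t", index=False)
    with open(truth_dir / "network_modules.tsv", "w", newline="\n") as fh:
        fh.write("gene_id\tmodule_index\n")
        for mi, members in enumerate(net_truth["modules"]):
            for g in members:
                fh.write(f"{g}\t{mi}\n")
    with open(truth_dir / "bridges.txt", "w", newline="\n") as fh:
        fh.writelines(b + "\n" for b in net_truth["bridges"])
    term_truth.to_csv(truth_dir / "planted_terms.tsv", sep="\t", index=False)
    tier_truth.to_frame().to_csv(truth_dir / "expression_tiers.tsv", sep="\t",
                                 index_label="gene_id")
    return paths


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Execute all stages; returns the summary dict written to summary.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(stage, msg):
        log_lines.append(f"{stage}: {msg}")

    with open(out / "config.yaml", "w", newline="\n") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)

    summary: dict = {}
    profile = cfg.filter_profile()

    # --- hybridize -----------------------------------------------------
    stage = "hybridize"
    try:
        mirnas = fileio.read_mirnas(cfg.mirnas)
        regions = fileio.read_regions_synth(cfg.targets)
        primary = []
        for idx, mir in enumerate(mirnas):
            hits = []
            for region in regions:
                hits.extend(scan_transcript(mir, region,
                                            report_max=cfg.report_max))
            calib = calibrate_null(mir, regions, n_shuffles=cfg.n_shuffles,
                                   seed=_mirna_seed(cfg.seed, idx))
            primary.extend(assign_pvalues(hits, calib))
        fileio.write_hits_tsv(primary, out / "primary_hits.tsv")
        summary["n_mirnas"] = len(mirnas)
        summary["n_regions"] = len(regions)
        summary["n_primary_hits"] = len(primary)
        log(stage, f"{len(primary)} primary hits")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- screen --------------------------------------------------------
    stage = "screen"
    try:
        refined = []
        for mir in mirnas:
            mine = [h for h in primary if h.mirna_id == mir.id]
            refined.extend(rank_targets(apply_filters(mine, profile)))
        fileio.write_hits_tsv(refined, out / "refined_hits.tsv")
        summary["n_refined_hits"] = len(refined)
        if cfg.validated:
            validated = fileio.read_validated_tsv(cfg.validated)
            mrna_set = {r.gene_id for r in regions}
            records = validate_three_level(validated, mrna_set, primary,
                                           refined)
            fileio.write_validation_report(records,
                                           out / "validation_report.tsv")
            summary.update(validation_summary(records))
        log(stage, f"{len(refined)} refined hits")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- network -------------------------------------------------------
    stage = "network"
    try:
        net = build_graph(cfg.edges)
        weights = pagerank_weights(net, mode=cfg.mode, tol=cfg.tol)
        if not weights.converged:
            log(stage, "WARNING: weight iteration did not converge")
        bridges = select_bridges(weights, k=cfg.k_bridges)
        decomp = decompose_modules(net, bridges,
                                   min_size=cfg.min_module_size)
        order = sorted(range(len(weights.nodes)),
                       key=lambda i: (-weights.weights[i], weights.nodes[i]))
        rank_of = {weights.nodes[i]: r + 1 for r, i in enumerate(order)}
        fileio._write_tsv(out / "weights.tsv", ("gene_id", "weight", "rank"),
                          [(n, float(w), rank_of[n])
                           for n, w in zip(weights.nodes, weights.weights)])
        rows = []
        for mod in decomp.modules:
            for g in sorted(mod.member_genes):
                rows.append((mod.module_id, g, "N"))
            for b in sorted(mod.central_bridges):
                rows.append((mod.module_id, b, "Y"))
        fileio._write_tsv(out / "modules.tsv",
                          ("module_id", "gene_id", "is_central_bridge"), rows)
        summary["n_nodes"] = net.n_nodes
        summary["n_edges"] = net.n_edges
        summary["n_bridges"] = len(bridges)
        summary["n_modules"] = len(decomp.modules)
        summary["n_residue_components"] = len(decomp.residue)
        summary["weight_iterations"] = weights.iteration_count
        log(stage, f"{net.n_nodes} nodes, {net.n_edges} edges, "
                   f"{len(decomp.modules)} modules")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- enrich --------------------------------------------------------
    stage = "enrich"
    try:
        ontology = fileio.read_obo(cfg.ontology)
        annotation = fileio.read_annotations_tsv(cfg.annotations, ontology)
        slim = fileio.read_slim_list(cfg.slim)
        background = sorted(net.graph.nodes)
        enriched_rows = []
        category_rows = []
        n_enriched = 0
        for mod in decomp.modules:
            results = enrich_module(mod, annotation, background,
                                    alpha=cfg.alpha, propagate=cfg.propagate)
            n_enriched += len(results)
            for r in results:
                enriched_rows.append((r.module_id, r.term_id,
                                      ontology.name(r.term_id), r.k, r.n,
                                      r.K, r.N_bg, r.p_raw, r.p_adj))
            slim_map = map_to_slim([r.term_id for r in results], slim,
                                   ontology)
            for term in sorted(slim_map.mapping):
                for cat in sorted(slim_map.mapping[term]):
                    category_rows.append((mod.module_id, term, cat))
        fileio._write_tsv(out / "enrichment.tsv",
                          ("module_id", "term_id", "name", "k", "n", "K",
                           "N_bg", "p_raw", "p_adj"), enriched_rows)
        fileio._write_tsv(out / "module_categories.tsv",
                          ("module_id", "term_id", "category"), category_rows)
        summary["n_enriched_terms"] = n_enriched
        log(stage, f"{n_enriched} enriched terms across modules")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- tissues -------------------------------------------------------
    stage = "tissues"
    try:
        expr = fileio.read_expression_tsv(cfg.expression)
        levels = classify_tissue_levels(expr, detect_thresh=cfg.detect_thresh,
                                        z_thresh=cfg.z_thresh)
        levels.to_csv(out / "tissue_levels.tsv", sep="\t",
                      index_label="gene_id", lineterminator="\n")
        counts = levels["level"].value_counts().to_dict()
        summary["tissue_level_counts"] = {k: int(v)
                                          for k, v in sorted(counts.items())}
        log(stage, f"tiers: {summary['tissue_level_counts']}")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    with open(out / "summary.json", "w", newline="\n") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "run.log", "w", newline="\n") as fh:
        fh.writelines(line + "\n" for line in log_lines)
    return summary


def synth_pipeline_config(paths: dict, profile: str = "plant",
                          seed: int = 42, **overrides) -> PipelineConfig:
    """A PipelineConfig wired to a `generate_inputs` directory."""
    return PipelineConfig(profile=profile, seed=seed, **paths, **overrides)
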