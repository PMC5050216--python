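"""End-to-end orchestration: simulate -> effects -> call -> network -> enrich.

Every stage writes plain-text tables into a run directory and the pipeline
records a JSON manifest (config hash, per-stage counts, fits and thresholds)
so that a rerun with the same seed reproduces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import caller, enrichment, factorial, network, simulate
from .io_formats import (
    StudyDesign,
    read_annotation,
    read_design,
    read_edgelist,
    read_expression,
    read_genesets,
    write_annotation,
    write_design,
    write_edgelist,
    write_expression,
    write_genesets,
)

__all__ = ["RunConfig", "run_pipeline", "overlap_lists"]

log = logging.getLogger("fqgdemar")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    With no input paths the pipeline simulates its inputs (seeded); paths,
    when given, override the corresponding simulated input.
    """

    out_dir: str = "fqgdemar_run"
    seed: int = 0
    fdr_target: float = 0.05
    age_cutoff: float = 64.0
    min_links: int = 2
    correction: str = "bh"
    weight_mode: str = "term_frequency"
    expression_path: str | None = None
    annotation_path: str | None = None
    design_path: str | None = None
    interactome_path: str | None = None
    genesets_path: str | None = None
    simulation: dict = field(default_factory=dict)
    interactome_nodes: int = 400
    interactome_density: float = 0.02
    n_terms: int = 40
    term_size: tuple[int, int] = (10, 40)
    log_level: str = "INFO"

    def validate(self) -> None:
        if not (0 < self.fdr_target < 1):
            raise ValueError("fdr_target must be in (0, 1)")
        if self.min_links < 1:
            raise ValueError("min_links must be >= 1")
        for path in (
            self.expression_path,
            self.annotation_path,
            self.design_path,
            self.interactome_path,
            self.genesets_path,
        ):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_or_simulate(cfg: RunConfig):
    if cfg.expression_path and cfg.design_path:
        log.info("stage simulate: loading provided inputs")
        matrix = read_expression(cfg.expression_path, cfg.annotation_path)
        design = read_design(cfg.design_path, age_cutoff=cfg.age_cutoff)
        truth = None
    else:
        sim_cfg = simulate.SimulationConfig(
            seed=cfg.seed, age_cutoff=cfg.age_cutoff, **cfg.simulation
        )
        matrix, design, truth = simulate.simulate_expression(sim_cfg)
    if cfg.interactome_path:
        interactome = read_edgelist(cfg.interactome_path)
    else:
        genes = sorted(set(matrix.annotation) - {""})
        n = min(cfg.interactome_nodes, len(genes))
        interactome = simulate.simulate_interactome(
            n, cfg.interactome_density, seed=cfg.seed + 1, nodes=genes[:n]
        )
    if cfg.genesets_path:
        genesets = read_genesets(cfg.genesets_path)
    else:
        genes = sorted(set(matrix.annotation) - {""})
        hi = min(cfg.term_size[1], len(genes))
        lo = min(cfg.term_size[0], hi)
        genesets = simulate.simulate_genesets(
            genes, cfg.n_terms, (lo, hi), seed=cfg.seed + 2
        )
    return matrix, design, truth, interactome, genesets


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage, write all outputs under ``cfg.out_dir``, return the
    manifest (also written as ``manifest.json``)."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))

    manifest: dict = {"config_hash": cfg.config_hash(), "config": dataclasses.asdict(cfg), "stages": {}}

    # stage 1: inputs
    matrix, design, truth, interactome, genesets = _load_or_simulate(cfg)
    write_expression(matrix, out / "expression.tsv")
    write_annotation(matrix.annotation, out / "annotation.tsv")
    write_design(design, out / "design.tsv")
    write_edgelist(interactome, out / "interactome.sif")
    write_genesets(genesets, out / "genesets.gmt")
    if truth is not None:
        truth.table.to_csv(out / "ground_truth.tsv", sep="\t")
    manifest["stages"]["inputs"] = {
        "n_probes": int(matrix.values.shape[0]),
        "n_samples": int(matrix.values.shape[1]),
        "n_interactome_edges": int(len(interactome)),
        "n_terms": len(genesets),
        "cell_sizes": {f"{i}:{j}": n for (i, j), n in design.cell_sizes.items()},
    }
    log.info("inputs ready: %s", manifest["stages"]["inputs"])

    # stage 2: factorial effects
    effects = factorial.effect_table(matrix, design)
    effects.to_csv(out / "effects.tsv", sep="\t", float_format="%.10g")
    manifest["stages"]["effects"] = {
        "n_probes": int(len(effects)),
        "n_excluded_from_ratios": int(effects["excluded"].sum()),
    }

    # stage 3: deconvolution calling
    result = caller.classify_all(effects, cfg.fdr_target, annotation=matrix.annotation)
    result.summary_table().to_csv(out / "call_summary.tsv", sep="\t", index=False)
    call_rows = []
    for lbl, cs in result.call_sets.items():
        for probe, score in cs.calls.items():
            call_rows.append(
                {
                    "probe_id": probe,
                    "gene": matrix.annotation.get(probe, ""),
                    "score": score,
                    "class": lbl,
                    "block_fdr": cs.block_fdr,
                }
            )
    pd.DataFrame(
        call_rows, columns=["probe_id", "gene", "score", "class", "block_fdr"]
    ).to_csv(out / "calls.tsv", sep="\t", index=False, float_format="%.10g")
    qc = caller.incidence_ratio(
        result.call_sets["interaction+"],
        result.call_sets["interaction-"],
        matrix.annotation,
    )
    manifest["stages"]["calls"] = {
        "classes": {
            lbl: {"n": cs.n_calls, "block_fdr": cs.block_fdr, "threshold": cs.threshold}
            for lbl, cs in result.call_sets.items()
        },
        "fits": {
            f: {"mu0": fit.mu0, "sigma0": fit.sigma0, "fallback": fit.fallback_used}
            for f, fit in result.fits.items()
        },
        "super_ratio_thresholds": result.super_ratio_thresholds,
        "interaction_incidence_qc": qc,
    }

    # stage 4: networks per factor
    manifest["stages"]["network"] = {}
    for factor in ("interaction", "age", "sex"):
        genes = result.call_sets[f"{factor}+"].genes(matrix.annotation) | result.call_sets[
            f"{factor}-"
        ].genes(matrix.annotation)
        if not genes:
            manifest["stages"]["network"][factor] = {"n_called_genes": 0}
            continue
        nucleus, absent = network.build_nucleus(genes, interactome)
        augmented = network.augment(nucleus, interactome, min_links=cfg.min_links)
        scc = network.strongly_connected_component(augmented)
        network_dir = out / "network"
        network_dir.mkdir(exist_ok=True)
        for name, g in (("nucleus", nucleus), ("augmented", augmented), ("scc", scc)):
            write_edgelist(g.edge_records(), network_dir / f"{factor}_{name}.sif")
            g.node_attribute_table().to_csv(
                network_dir / f"{factor}_{name}_nodes.tsv", sep="\t", index=False
            )
        n_added = sum(1 for n in augmented.nodes if augmented.origin(n) == "added")
        manifest["stages"]["network"][factor] = {
            "n_called_genes": len(genes),
            "n_absent_from_interactome": len(absent),
            "nucleus_nodes": len(nucleus.nodes),
            "augmented_nodes": len(augmented.nodes),
            "fraction_added": n_added / max(len(augmented.nodes), 1),
            "scc_nodes": len(scc.nodes),
        }

    # stage 5: enrichment of the augmented network node sets
    universe = sorted(set(matrix.annotation) - {""})
    manifest["stages"]["enrichment"] = {}
    for factor in ("interaction", "age", "sex"):
        genes = result.call_sets[f"{factor}+"].genes(matrix.annotation) | result.call_sets[
            f"{factor}-"
        ].genes(matrix.annotation)
        query = sorted(set(genes) & set(universe))
        if not query:
            continue
        records = enrichment.hypergeom_enrich(
            query, genesets, universe, correction=cfg.correction
        )
        records.to_csv(out / f"enrichment_{factor}.tsv", sep="\t", index=False)
        manifest["stages"]["enrichment"][factor] = {
            "n_terms_tested": int(len(records)),
            "n_significant_0.05": int((records["p_corrected"] < 0.05).sum()),
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def overlap_lists(ours, external, per_class: dict[str, set] | None = None) -> dict:
    """Case-insensitive overlap of a called gene list with an external list.

    The hit fraction is reported relative to the external list (the
    validation denominator). ``per_class`` optionally maps a class label
    (e.g. a factor) to its gene set for a per-class breakdown of the hits.
    """
    external_set = {network.normalize_symbol(g) for g in external}
    if not external_set:
        raise ValueError("empty external list")
    ours_set = {network.normalize_symbol(g) for g in ours}
    hits = sorted(ours_set & external_set)
    report = {
        "ours_size": len(ours_set),
        "external_size": len(external_set),
        "hits": len(hits),
        "hit_fraction": len(hits) / len(external_set),
        "hit_genes": hits,
    }
    if per_class is not None:
        report["per_class"] = {
            label: len({network.normalize_symbol(g) for g in genes} & set(hits))
            for label, genes in per_class.items()
        }
    return report
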