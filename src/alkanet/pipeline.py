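"""Stage orchestration: filter -> network -> dereplicate -> scaffold-map -> tree -> iTOL.

Each stage reads its inputs from the config paths, writes its artifact under
``out_dir`` and appends a machine-readable run report (JSON) with input
counts, output counts, parameters used and removals with reasons, so every
count in the pipeline can be reconstructed from the reports alone.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from .config import PipelineConfig
from .dereplication import hits_to_frame, library_search, load_library, masst_search
from .features import filter_feature_table, organ_abundance, read_feature_table, write_feature_table
from .masses import write_mass_deltas
from .networking import attach_node_metadata, build_network, molecular_families, write_edge_list, write_graphml
from .phylo import annotate_tree, export_itol, load_tree
from .scaffolds import (
    assign_scaffolds,
    build_presence_matrix,
    curate_reports,
    load_reports,
    load_scaffold_queries,
)
from .simulate import SimulationConfig, write_fixtures
from .spectra import preprocess_spectrum, read_mgf

logger = logging.getLogger(__name__)

STAGES = ("simulate", "filter", "network", "annotate", "masst", "scaffold-map", "tree", "itol")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _report(out_dir: Path, stage: str, payload: dict) -> None:
    payload = {"stage": stage, "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"), **payload}
    (out_dir / f"report_{stage.replace('-', '_')}.json").write_text(
        json.dumps(payload, indent=2, default=str) + "\n"
    )


def validate_config(config: PipelineConfig, stages: list[str]) -> None:
    """Fail before any work when a requested stage's inputs are missing."""
    need: dict[str, list[str]] = {
        "filter": ["feature_csv", "sample_csv"],
        "network": ["spectra_mgf"],
        "annotate": ["spectra_mgf", "library_mgf"],
        "masst": ["spectra_mgf", "library_mgf"],
        "scaffold-map": ["reports_csv"],
        "tree": ["reports_csv", "tree_newick", "backbone_csv"],
        "itol": ["reports_csv", "tree_newick", "backbone_csv"],
    }
    if "simulate" in stages:
        return  # simulate generates the inputs itself
    for stage in stages:
        for key in need.get(stage, []):
            val = getattr(config, key)
            if val is None or not Path(val).exists():
                raise StageError(stage, f"required input {key!r} missing ({val})")


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Run the requested stages in canonical order; returns summary counts."""
    stages = list(stages) if stages else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    overrides = config.overrides_from_defaults()
    if overrides:
        logger.info("config overrides from defaults: %s", overrides)

    if "simulate" in stages:
        sim = SimulationConfig(seed=config.seed)
        fixture_dir = out_dir / "fixtures"
        paths = write_fixtures(sim, fixture_dir)
        config.spectra_mgf = str(paths["spectra"])
        config.feature_csv = str(paths["areas"])
        config.sample_csv = str(paths["samples"])
        config.reports_csv = str(paths["reports"])
        config.tree_newick = str(paths["tree"])
        config.backbone_csv = str(paths["backbone"])
        if config.library_mgf is None:
            config.library_mgf = str(paths["spectra"])  # self-search smoke index
        _report(out_dir, "simulate", {"seed": config.seed, "paths": {k: str(v) for k, v in paths.items()}})

    validate_config(config, stages)
    summary: dict = {"stages": stages}

    table = None
    if "filter" in stages:
        table = read_feature_table(config.feature_csv, config.sample_csv)
        n_in = len(table.feature_ids)
        filtered = filter_feature_table(table, config.blank_fold, config.min_samples)
        write_feature_table(filtered, out_dir / "features_filtered.csv", out_dir / "samples.csv")
        removed = filtered.removal_log
        removed.to_csv(out_dir / "features_removed.csv", index=False)
        _report(
            out_dir,
            "filter",
            {
                "params": {"blank_fold": config.blank_fold, "min_samples": config.min_samples},
                "n_in": n_in,
                "n_out": len(filtered.feature_ids),
                "n_removed": n_in - len(filtered.feature_ids),
                "removal_reasons": removed["reason"].value_counts().to_dict(),
            },
        )
        summary["features_in"] = n_in
        summary["features_retained"] = len(filtered.feature_ids)
        table = filtered

    net = None
    spectra = None
    if {"network", "annotate", "masst"} & set(stages):
        spectra = read_mgf(config.spectra_mgf)
        if table is not None:
            keep = set(table.feature_ids)
            spectra = [s for s in spectra if s.feature_id in keep]
        spectra = [
            preprocess_spectrum(
                s, config.precursor_window, config.window_size or None, config.window_top_k or None
            )
            for s in spectra
        ]
        spectra = [s for s in spectra if not s.is_empty()]

    if "network" in stages:
        net = build_network(
            spectra,
            min_cosine=config.min_cosine,
            min_matched=config.min_matched,
            frag_tol=config.frag_tol_network,
            top_k=config.top_k,
            max_component=config.max_component,
        )
        if table is not None:
            organ = organ_abundance(table, [f for f in table.feature_ids if f in net])
            attach_node_metadata(net, organ.add_prefix("log10_"))
        families, singletons = molecular_families(net)
        write_graphml(net, out_dir / "network.graphml")
        write_edge_list(net, out_dir / "network_edges.csv")
        fam_rows = [
            {"family": i + 1, "size": len(f), "members": ";".join(map(str, f))}
            for i, f in enumerate(families)
        ]
        pd.DataFrame(fam_rows, columns=["family", "size", "members"]).to_csv(
            out_dir / "molecular_families.csv", index=False
        )
        _report(
            out_dir,
            "network",
            {
                "params": {
                    "min_cosine": config.min_cosine,
                    "min_matched": config.min_matched,
                    "frag_tol": config.frag_tol_network,
                    "top_k": config.top_k,
                    "max_component": config.max_component,
                },
                "n_spectra": len(spectra),
                "n_edges": net.number_of_edges(),
                "n_families": len(families),
                "n_singletons": len(singletons),
            },
        )
        summary["molecular_families"] = len(families)
        summary["singletons"] = len(singletons)

    if "annotate" in stages:
        library = load_library(config.library_mgf, config.library_csv)
        exact = library_search(
            spectra,
            library,
            prec_tol=config.prec_tol_library,
            frag_tol=config.frag_tol_network,
            min_cosine=config.min_cosine,
            min_matched=config.min_matched,
            mode="exact",
        )
        analog = library_search(
            spectra,
            library,
            prec_tol=config.prec_tol_library,
            frag_tol=config.frag_tol_network,
            min_cosine=config.min_cosine,
            min_matched=config.min_matched,
            mode="analog",
            max_delta=config.analog_max_delta,
        )
        hits_to_frame(exact).to_csv(out_dir / "hits_exact.csv", index=False)
        hits_to_frame(analog).to_csv(out_dir / "hits_analog.csv", index=False)
        write_mass_deltas(out_dir / "mass_deltas.csv")
        _report(
            out_dir,
            "annotate",
            {
                "n_queries": len(spectra),
                "n_library": len(library),
                "n_exact_hits": len(exact),
                "n_analog_hits": len(analog),
            },
        )
        summary["exact_hits"] = len(exact)
        summary["analog_hits"] = len(analog)

    if "masst" in stages:
        library = load_library(config.library_mgf, config.library_csv)
        agg_rows = []
        for s in spectra:
            res = masst_search(
                s,
                library,
                prec_tol=config.masst_prec_tol,
                frag_tol=config.masst_frag_tol,
                min_cosine=config.masst_min_cosine,
                min_matched=config.masst_min_matched,
                analog=config.masst_analog,
            )
            agg_rows.append(
                {
                    "feature_id": s.feature_id,
                    "n_hits": len(res.hits),
                    "n_species": len(res.species_counts),
                    "n_genera": len(res.genus_counts),
                    "n_families": len(res.family_counts),
                    "novel": res.is_novel,
                }
            )
        pd.DataFrame(agg_rows).to_csv(out_dir / "masst_summary.csv", index=False)
        _report(out_dir, "masst", {"n_queries": len(spectra), "n_novel": int(sum(r["novel"] for r in agg_rows))})
        summary["masst_novel"] = int(sum(r["novel"] for r in agg_rows))

    matrix = None
    if {"scaffold-map", "tree", "itol"} & set(stages):
        queries = load_scaffold_queries(config.scaffolds_yaml)
        reports, rejects = load_reports(config.reports_csv, out_dir / "reports_rejected.csv")
        reports = assign_scaffolds(reports, queries)
        curated, audit = curate_reports(reports, queries)
        audit.to_csv(out_dir / "curation_audit.csv", index=False)
        matrix = build_presence_matrix(curated)
        matrix.matrix.to_csv(out_dir / "presence_matrix.csv")
        matrix.scaffold_summary().to_csv(out_dir / "scaffold_summary.csv", index=False)
        _report(
            out_dir,
            "scaffold-map",
            {
                "n_reports_in": len(reports) + len(rejects),
                "n_rejected": len(rejects),
                "n_curated_out": len(audit),
                "n_reports_kept": len(curated),
                "n_genera": int(len(matrix.matrix)),
                "all_scaffold_genera": matrix.all_scaffold_genera(),
            },
        )
        summary["presence_genera"] = int(len(matrix.matrix))
        summary["all_scaffold_genera"] = matrix.all_scaffold_genera()

    if {"tree", "itol"} & set(stages):
        gt = load_tree(config.tree_newick)
        backbone = pd.read_csv(config.backbone_csv, dtype=str)
        annotated = annotate_tree(gt, matrix, backbone=backbone, prune=config.prune_orders)
        pd.Series(annotated.unmapped_genera, name="genus").to_csv(
            out_dir / "unmapped_genera.csv", index=False
        )
        _report(
            out_dir,
            "tree",
            {
                "n_tree_leaves": len(gt.leaf_labels),
                "n_leaves_after_prune": len(annotated.leaf_labels),
                "n_matrix_genera": int(len(matrix.matrix)),
                "n_unmapped": len(annotated.unmapped_genera),
                "pruned": config.prune_orders,
            },
        )
        summary["unmapped_genera"] = len(annotated.unmapped_genera)
        if "itol" in stages:
            files = export_itol(annotated, out_dir / "itol")
            _report(out_dir, "itol", {"files": [str(f) for f in files]})
            summary["itol_files"] = len(files)

    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, default=str) + "\n")
    return summary
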