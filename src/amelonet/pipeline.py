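"""End-to-end run on synthetic inputs: simulate, call and filter somatic
variants, build the co-expression network, test GO enrichment of the
disease-associated module, extract the mutation sub-network, and run the
VAF-based two-hit ordering test.  All declared outputs are written as
plain-text files."""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import pandas as pd

from . import io as io_formats
from .config import PipelineConfig
from .coexpression import build_network
from .enrichment import GOStructure, hypergeom_enrich, nonredundant_filter
from .integration import (
    build_subnetwork,
    map_mutations_to_modules,
    module_mutation_counts,
    vaf_ordering_test,
)
from .simulate import SimulationPlan, annotate_simulated, simulate_expression, simulate_go, simulate_variants
from .variants import recurrence_summary, run_cascade

#: Every file a full run writes into its output directory.
OUTPUT_FILES = (
    "config.json",
    "variants.tsv",
    "truth.tsv",
    "expression.tsv",
    "traits.tsv",
    "qc.tsv",
    "rare.tsv",
    "severe.tsv",
    "final.tsv",
    "recurrence.tsv",
    "modules.tsv",
    "eigengenes.tsv",
    "kme.tsv",
    "module_trait.tsv",
    "enrichment.tsv",
    "subnetwork.sif",
    "subnetwork_edges.tsv",
    "node_attributes.tsv",
    "module_mutation_counts.tsv",
    "two_hit_report.json",
)


def _variant_frame(variants) -> pd.DataFrame:
    rows = []
    for v in variants:
        c = v.candidate
        rows.append(
            {
                "patient_id": c.patient_id,
                "chrom": c.chrom,
                "pos": c.pos,
                "ref": c.ref,
                "alt": c.alt,
                "gene": v.gene,
                "consequence": v.consequence,
                "fisher_p": v.call.fisher_p,
                "normal_vaf": v.call.normal_vaf,
                "tumor_vaf": v.call.tumor_vaf,
                "is_rare": v.is_rare,
                "is_severe": v.is_severe,
                "is_final": v.is_final,
            }
        )
    return pd.DataFrame(rows)


def run_all(
    outdir: str | Path,
    plan: SimulationPlan | None = None,
    cfg: PipelineConfig | None = None,
    seed: int | None = None,
) -> dict:
    """Run the whole pipeline on synthetic inputs and write all outputs.

    Returns a dict with the in-memory results (cascade, network model,
    enrichment table, sub-network, two-hit report).
    """
    cfg = cfg or PipelineConfig()
    plan = plan or SimulationPlan()
    if seed is not None:
        plan = replace(plan, seed=int(seed))
        cfg = replace(cfg, rng_seed=int(seed))
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    with open(out / "config.json", "w") as fh:
        json.dump({"config": cfg.to_dict(), "seed": plan.seed}, fh, indent=2)

    # --- somatic variants -------------------------------------------------
    candidates, annotation, truth = simulate_variants(plan, cfg)
    io_formats.write_variant_table(candidates, out / "variants.tsv")
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    annotated = annotate_simulated(candidates, annotation, cfg)
    cascade = run_cascade(annotated, cfg)
    for stage, variants in (
        ("qc", cascade.qc),
        ("rare", cascade.rare),
        ("severe", cascade.severe),
        ("final", cascade.final),
    ):
        _variant_frame(variants).to_csv(
            out / f"{stage}.tsv", sep="\t", index=False
        )
    recurrence = recurrence_summary(cascade.final)
    recurrence.to_csv(out / "recurrence.tsv", sep="\t", index=False)

    # --- co-expression network --------------------------------------------
    expr, planted_labels = simulate_expression(plan)
    io_formats.write_expression_matrix(
        expr, out / "expression.tsv", out / "traits.tsv"
    )
    model = build_network(expr, cfg)
    pd.DataFrame(
        {"gene": model.gene_ids,
         "module": [model.module_of[g] for g in model.gene_ids]}
    ).to_csv(out / "modules.tsv", sep="\t", index=False)
    model.eigengenes.to_csv(out / "eigengenes.tsv", sep="\t")
    model.kme.to_csv(out / "kme.tsv", sep="\t")
    model.module_trait.to_csv(out / "module_trait.tsv", sep="\t", index=False)
    anchor = model.anchor_module

    # --- GO enrichment of the anchor module --------------------------------
    term_to_genes, parent_of = simulate_go(plan, planted_labels, cfg)
    structure = GOStructure(term_to_genes=term_to_genes, parent_of=parent_of)
    query = model.genes_in_module(anchor)
    enrich = nonredundant_filter(
        hypergeom_enrich(query, structure, cfg), structure, cfg
    )
    enrich.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    # --- integration --------------------------------------------------------
    mutated_patients: dict[str, list] = {}
    for v in cascade.final:
        mutated_patients.setdefault(v.gene, []).append(
            v.candidate.patient_id
        )
    mutated_genes = sorted(mutated_patients)
    subnet = build_subnetwork(
        model, mutated_genes, anchor, cfg, mutated_patients=mutated_patients
    )
    io_formats.write_edge_list(subnet, out / "subnetwork.sif", fmt="sif")
    io_formats.write_edge_list(
        subnet, out / "subnetwork_edges.tsv", fmt="tsv"
    )
    subnet.node_table().to_csv(
        out / "node_attributes.tsv", sep="\t", index=False
    )
    mapped = map_mutations_to_modules(cascade.final, model.module_of)
    module_mutation_counts(mapped).to_csv(
        out / "module_mutation_counts.tsv", sep="\t"
    )
    report = vaf_ordering_test(cascade.final, model.module_of, anchor)
    io_formats.write_two_hit_report(report, out / "two_hit_report.json")

    return {
        "cascade": cascade,
        "recurrence": recurrence,
        "expression": expr,
        "planted_labels": planted_labels,
        "model": model,
        "anchor_module": anchor,
        "enrichment": enrich,
        "subnetwork": subnet,
        "two_hit_report": report,
    }
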