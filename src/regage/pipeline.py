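"""End-to-end orchestration of the regulatory-aging pipeline on a study.

``run_all`` generates (or accepts) a synthetic study, runs every stage in
method order — bulk DE on two replicate comparisons, concordance
intersection, dual-window motif enrichment, signed regulon construction,
single-cell filtering / AUCell scoring / overexpression validation, miRNA
DE with consensus targeting, and the functional-term network — and writes
all result tables plus a machine-readable summary into the output
directory. Given the same config and seed, two runs produce byte-identical
result files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import diffexpr, mirna, motifenrich, regulon, synthdata, termnet
from .core_io import echo_config, load_config, write_network
from .regulon import TFRole

log = logging.getLogger("regage.pipeline")


def roles_from_truth(truth: synthdata.TruthLedger) -> list[TFRole]:
    """The TF role table a user would curate, taken from the planted ledger."""
    return [TFRole(r["tf_id"], r["role"], evidence="planted") for r in truth.regulons]


def run_all(
    sim_config: synthdata.SimulationConfig,
    outdir: str | Path,
    config: dict | None = None,
    write_inputs: bool = False,
) -> dict:
    """Run the full pipeline on a generated study; returns the summary dict."""
    cfg = config or load_config()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    echo_config({**cfg, "simulate": {"seed": sim_config.seed}}, out)
    summary: dict = {"seed": sim_config.seed}

    study = synthdata.simulate_all(sim_config)
    truth: synthdata.TruthLedger = study["truth"]
    if write_inputs:
        synthdata.write_study(study, out / "inputs")

    # --- bulk DE on two replicate comparisons, then concordance intersection
    de_cfg = cfg["de"]
    bulk_a = study["bulk"]
    bulk_b, _ = synthdata.simulate_bulk(sim_config, rep=1)
    de_a = diffexpr.run_de(bulk_a, alpha=de_cfg["alpha"], lfc_min=de_cfg["lfc_min"],
                           moderation=de_cfg["moderation"])
    de_a = diffexpr.abundance_filter(de_a, study["tpm"], min_median=de_cfg["min_median"])
    de_b = diffexpr.run_de(bulk_b, alpha=de_cfg["alpha"], lfc_min=de_cfg["lfc_min"],
                           moderation=de_cfg["moderation"])
    de_a.write(out / "de_a.tsv")
    de_b.write(out / "de_b.tsv")
    inter = diffexpr.intersect_concordant(de_a, de_b)
    summary["n_significant_a"] = len(de_a.significant())
    summary["n_shared"] = len(inter.shared_genes)
    summary["concordance_fraction"] = inter.concordance_fraction
    (out / "intersection.json").write_text(json.dumps({
        "shared": sorted(inter.shared_genes),
        "concordant": sorted(inter.concordant_genes),
        "discordant": sorted(inter.discordant_genes),
        "concordance_fraction": inter.concordance_fraction,
    }, indent=1, sort_keys=True))

    # the intersected, concordant gene sets drive the downstream stages
    concordant_up = inter.concordant_genes & de_a.up
    concordant_down = inter.concordant_genes & de_a.down
    genesets = {"aged": concordant_up, "young": concordant_down}

    # --- dual-window motif enrichment over the young-enriched gene set
    m_cfg = cfg["motifs"]
    gs_cond = cfg["regulons"]["geneset_condition"]
    edges = motifenrich.scan_two_windows(
        study["db_short"], study["db_long"], genesets[gs_cond], study["annotation"],
        max_rank_fraction=m_cfg["max_rank_fraction"], nes_min=m_cfg["nes_min"],
    )
    edges.to_csv(out / "candidate_edges.tsv", sep="\t", index=False)

    # --- signed regulons
    roles = roles_from_truth(truth)
    regulons = regulon.build_regulons(
        edges, de_a, roles, gs_cond, min_targets=cfg["regulons"]["min_targets"]
    )
    (out / "regulons.json").write_text(
        json.dumps(regulon.regulons_to_json(regulons), indent=1, sort_keys=True)
    )
    summary["n_regulons"] = len(regulons)
    summary["regulon_tfs"] = sorted(r.tf_id for r in regulons)

    # --- single-cell: filter, AUCell, overexpression validation
    sc_cfg = cfg["sc"]
    cells = diffexpr.sc_filter_cells(
        study["cells"], max_mito_pct=sc_cfg["max_mito_pct"],
        min_genes=sc_cfg["min_genes"], mito_prefix=sc_cfg["mito_prefix"],
    )
    summary["n_cells_kept"] = len(cells.sample_ids)
    summary["n_cells_removed"] = len(study["cells"].sample_ids) - len(cells.sample_ids)
    rankings = regulon.aucell_rank_cells(cells, seed=sim_config.seed)
    oe_tf = next((r["tf_id"] for r in truth.regulons if r["role"] == "repressor"), None)
    scored = next((r for r in regulons if r.tf_id == oe_tf), None)
    if scored is not None:
        act = regulon.aucell_score(rankings, scored,
                                   max_rank_fraction=m_cfg["max_rank_fraction"],
                                   groups=cells.conditions())
        act.scores.to_frame("auc").assign(group=act.groups).to_csv(
            out / "aucell_scores.tsv", sep="\t", index_label="cell_id")
        gtest = regulon.compare_regulon_activity(act, "tf_active", "control")
        summary["aucell_test"] = gtest
        (out / "aucell_group_test.json").write_text(json.dumps(gtest, indent=1, sort_keys=True))

        sc_result = diffexpr.sc_de(cells, ("control", "tf_active"),
                                   alpha=sc_cfg["alpha"], lfc_min=sc_cfg["lfc_min"],
                                   min_pct=sc_cfg["min_pct"])
        sc_result.write(out / "sc_de.tsv")
        repressed, activated = sc_result.down, sc_result.up
        if repressed and activated:
            fisher = regulon.target_enrichment_fisher(scored.targets, repressed, activated)
            summary["oe_fisher"] = fisher
            (out / "oe_fisher.json").write_text(json.dumps(fisher, indent=1, sort_keys=True))
        upset = regulon.compare_target_sets(truth.targets_of(oe_tf), scored.targets)
        summary["target_set_counts"] = upset["counts"]

    # --- miRNA: DE, consensus targeting, summary, cross-network
    mi_cfg = cfg["mirna"]
    mirna_result = mirna.mirna_de(study["mirna"], alpha=mi_cfg["alpha"])
    mirna_result.write(out / "mirna_de.tsv")
    consensus = mirna.consensus_for_de(mirna_result, study["target_dbs"],
                                       min_src=mi_cfg["min_src"], method=mi_cfg["method"])
    cons_rows = [
        {"mirna_id": m, "gene": row.gene, "n_sources": row.n_sources,
         "aggregate_rank": row.aggregate_rank}
        for m, ct in consensus.items() for row in ct.table.itertuples(index=False)
    ]
    pd.DataFrame(cons_rows, columns=["mirna_id", "gene", "n_sources", "aggregate_rank"]).to_csv(
        out / "consensus_targets.tsv", sep="\t", index=False)
    msum = mirna.target_summary(mirna_result, consensus, de_a)
    summary["mirna_summary"] = msum
    summary["n_de_mirnas"] = len(mirna_result.significant())
    mir_net, per_tf = mirna.build_mir_networks(
        mirna_result, de_a, consensus, study["tf_mir"], de_a, roles=roles)
    write_network(mir_net, out / "mir_network.json", "json")
    summary["tf_mirna_counts"] = per_tf.to_dict()

    # --- functional-term network
    t_cfg = cfg["termnet"]
    terms_df = study["terms"]
    term_sets = {t: set(g["gene_id"]) for t, g in terms_df.groupby("term_id")}
    expected = {
        t: dict(zip(g["gene_id"], g["expected_direction"]))
        for t, g in terms_df.groupby("term_id")
    }
    universe = set(truth.gene_ids)
    de_set = de_a.significant() & universe
    results = termnet.term_enrichment(term_sets, de_set, universe,
                                      term_alpha=t_cfg["term_alpha"],
                                      expected_directions=expected)
    de_dirs = {g: de_a.direction_of(g) for g in de_set}
    for r in results:
        r.z = termnet.activation_z(r, de_dirs)
    retained = [r for r in results if r.retained]
    pruned = termnet.prune_redundant(retained, jaccard_max=t_cfg["jaccard_max"])
    pd.DataFrame([
        {"term_id": r.term_id, "n_genes": len(r.annotated_genes),
         "n_overlap": len(r.overlap_de), "p": r.p, "q": r.q,
         "z": r.z if r.z is not None else "NA",
         "retained": r.retained, "pruned_in": r in pruned}
        for r in results
    ]).to_csv(out / "term_results.tsv", sep="\t", index=False)
    summary["n_terms_retained"] = len(retained)
    summary["n_terms_pruned"] = len(pruned)
    if pruned:
        term_net = termnet.build_term_network(pruned, de_a)
        modules, modularity = termnet.detect_modules(term_net, seed=sim_config.seed)
        write_network(term_net, out / "term_network.json", "json")
        summary["n_modules"] = len({m for m in modules.values() if m != 0})
        summary["modularity"] = modularity

    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    log.info("run_all complete: %s", out / "summary.json")
    return summary
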