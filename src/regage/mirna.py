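"""miRNA differential expression and multi-database consensus targeting.

Array-style log-intensities are tested with the same moderated-t machinery as
the bulk stage (no count transform, no fold-change floor; significance at
adjusted p < 0.01). Predicted targets are aggregated across several
independent prediction databases: a gene counts as a consensus target of a
miRNA when at least ``min_src`` databases list it, with its per-database
ranks combined by geometric mean ("geom"). Because miRNAs repress their
targets, network edges pair each differentially expressed miRNA with target
genes enriched in the OPPOSITE condition, and curated TF->miRNA edges are
kept only between entities that are both differentially expressed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, RegulatoryNetwork
from .diffexpr import DEResult, fit_gene_models, moderate_variances, test_de
from .regulon import TFRole

log = logging.getLogger("regage.mirna")


@dataclass
class ConsensusTargets:
    mirna_id: str
    table: pd.DataFrame  # columns gene, n_sources, aggregate_rank, source_ranks

    @property
    def genes(self) -> set[str]:
        return set(self.table["gene"])


def mirna_de(
    intensities: ExpressionMatrix,
    conditions: tuple[str, str] = ("young", "aged"),
    alpha: float = 0.01,
) -> DEResult:
    """Moderated-t differential expression on log-intensities.

    Only the adjusted-p criterion applies (lfc_min = 0).
    """
    if intensities.unit != "log_intensity":
        raise ValueError("mirna_de expects unit='log_intensity'")
    cond = intensities.conditions()
    for c in conditions:
        if (cond == c).sum() < 2:
            raise ValueError(f"need >= 2 samples in condition {c!r}")
    models = fit_gene_models(intensities, conditions)
    fit = moderate_variances(models["s_sq"].to_numpy(), models["df"].to_numpy())
    return test_de(models, fit, alpha=alpha, lfc_min=0.0)


def consensus_targets(
    mirna_id: str,
    dbs: list[dict[str, list[str]]],
    min_src: int = 2,
    method: str = "geom",
) -> ConsensusTargets:
    """Aggregate one miRNA's predicted targets across databases.

    A gene is kept iff it appears in >= ``min_src`` databases; its aggregate
    rank is the geometric mean of its ranks over the databases that contain
    it (no padding for absent sources). Rows are sorted by aggregate rank
    ascending, ties broken lexicographically by gene id.
    """
    if not (1 <= min_src <= len(dbs)):
        raise ValueError(f"min_src must lie in 1..{len(dbs)}")
    if method != "geom":
        raise ValueError("only the 'geom' aggregation method is implemented")
    source_ranks: dict[str, dict[int, int]] = {}
    n_present = 0
    for i, db in enumerate(dbs):
        targets = db.get(mirna_id)
        if targets is None:
            continue
        n_present += 1
        for rank, gene in enumerate(targets, start=1):
            source_ranks.setdefault(gene, {})[i] = rank
    if n_present == 0:
        log.warning("consensus_targets: miRNA %s absent from all databases", mirna_id)
    rows = []
    for gene, ranks in source_ranks.items():
        if len(ranks) < min_src:
            continue
        agg = float(np.exp(np.mean(np.log(list(ranks.values())))))
        rows.append({"gene": gene, "n_sources": len(ranks), "aggregate_rank": agg,
                     "source_ranks": dict(sorted(ranks.items()))})
    # round the sort key so numerically-equal geometric means tie exactly
    rows.sort(key=lambda r: (round(r["aggregate_rank"], 9), r["gene"]))
    table = pd.DataFrame(rows, columns=["gene", "n_sources", "aggregate_rank", "source_ranks"])
    return ConsensusTargets(mirna_id, table)


def consensus_for_de(
    de: DEResult, dbs: list[dict[str, list[str]]], min_src: int = 2, method: str = "geom"
) -> dict[str, ConsensusTargets]:
    """Consensus target sets for every significantly DE miRNA."""
    return {m: consensus_targets(m, dbs, min_src, method) for m in sorted(de.significant())}


def _enriched_in(de: DEResult, condition: str) -> set[str]:
    # aged-vs-young convention: "up" = aged-enriched, "down" = young-enriched
    return de.up if condition == "aged" else de.down


def target_summary(
    mirna_result: DEResult,
    consensus: dict[str, ConsensusTargets],
    gene_de: DEResult,
) -> dict[str, dict]:
    """Per-condition summary of opposite-condition targeting.

    For miRNAs enriched in condition c: per-miRNA count of consensus targets
    among genes enriched in the other condition (mean and sample sd), and
    the coverage fraction of the other condition's genes reached by >= 1
    such miRNA (union semantics).
    """
    out: dict[str, dict] = {}
    for cond, other in (("young", "aged"), ("aged", "young")):
        mirnas = sorted(_enriched_in(mirna_result, cond))
        if not mirnas:
            log.warning("target_summary: no DE miRNAs enriched in %s; summary omitted", cond)
            continue
        opposite_genes = _enriched_in(gene_de, other)
        counts, union = [], set()
        for m in mirnas:
            hits = consensus[m].genes & opposite_genes if m in consensus else set()
            counts.append(len(hits))
            union |= hits
        counts_arr = np.array(counts, dtype=float)
        sd_flag = len(counts) < 2
        out[cond] = {
            "n_mirnas": len(mirnas),
            "mean_targets": float(counts_arr.mean()),
            "sd_targets": 0.0 if sd_flag else float(counts_arr.std(ddof=1)),
            "sd_undefined": sd_flag,
            "coverage_fraction": (len(union) / len(opposite_genes)) if opposite_genes else 0.0,
            "covered_condition": other,
        }
    return out


def build_mir_networks(
    mirna_result: DEResult,
    gene_de: DEResult,
    consensus: dict[str, ConsensusTargets],
    tf_mir_table: pd.DataFrame,
    tf_de: DEResult,
    roles: list[TFRole] | None = None,
) -> tuple[RegulatoryNetwork, pd.Series]:
    """Assemble the miRNA/target/TF network.

    miRNA->gene "targets" edges require the miRNA and gene to be DE in
    opposite conditions; curated TF->miRNA edges are kept only when both
    endpoints are significantly DE, signed by the TF's role (defaulting to
    "targets" when no role is known). Returns the network and the per-TF
    count of unique DE miRNAs targeted (the ranking statistic).
    """
    net = RegulatoryNetwork()
    role_map = {r.tf_id: r.role for r in (roles or [])}

    for cond, other in (("young", "aged"), ("aged", "young")):
        for m in sorted(_enriched_in(mirna_result, cond)):
            if m not in consensus:
                continue
            targets = consensus[m].genes & _enriched_in(gene_de, other)
            if not targets:
                continue
            net.add_node(m, "mirna", "up" if cond == "aged" else "down")
            for g in sorted(targets):
                net.add_node(g, "gene", gene_de.direction_of(g))
                net.add_edge(m, g, "targets", "mirna_consensus")

    de_mirnas = mirna_result.significant()
    tf_counts: dict[str, set[str]] = {}
    for row in tf_mir_table.itertuples(index=False):
        tf, m = str(row.tf_id), str(row.mirna_id)
        if tf_de.direction_of(tf) == "ns" or m not in de_mirnas:
            continue
        role = role_map.get(tf)
        sign = {"activator": "activates", "repressor": "represses"}.get(role, "targets")
        net.add_node(tf, "tf", tf_de.direction_of(tf))
        if m not in net.nodes:
            net.add_node(m, "mirna",
                         "up" if m in mirna_result.up else "down")
        net.add_edge(tf, m, sign, "curated_tf_mirna")
        tf_counts.setdefault(tf, set()).add(m)

    per_tf = pd.Series({tf: len(ms) for tf, ms in tf_counts.items()},
                       dtype=int).sort_values(ascending=False)
    log.info("build_mir_networks: %d nodes, %d edges; %d TF(s) with curated edges",
             len(net.nodes), len(net.edges), len(per_tf))
    return net, per_tf
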