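"""Signed regulon construction and per-cell activity scoring.

A regulon is a transcription factor with its inferred target set, signed by
the factor's literature role. The admission rule mirrors the enrichment
geometry of repression: a repressor enriched in one condition is paired with
the gene set of the OTHER condition (its targets are de-repressed where the
factor is absent), while an activator is paired with its own condition's
gene set. Only TFs that are themselves significantly differentially
expressed survive.

Activity is scored per cell with the same recovery-AUC kernel used for motif
enrichment (AUCell): genes are ranked within each cell by decreasing
expression with seeded random tie-breaking, and the regulon's target set is
scored in the top fraction of that ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionMatrix
from .diffexpr import DEResult

log = logging.getLogger("regage.regulon")

CONDITIONS = ("young", "aged")


@dataclass
class TFRole:
    tf_id: str
    role: str  # activator | repressor
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.role not in ("activator", "repressor"):
            raise ValueError(f"role must be activator or repressor, got {self.role!r}")


@dataclass
class Regulon:
    tf_id: str
    role: str
    tf_condition: str
    geneset_condition: str
    targets: set[str]
    edge_sign: str  # activates | represses
    window_support: dict[str, str] = field(default_factory=dict)  # gene -> windows

    def __post_init__(self) -> None:
        if self.role == "activator":
            assert self.tf_condition == self.geneset_condition and self.edge_sign == "activates"
        else:
            assert self.tf_condition != self.geneset_condition and self.edge_sign == "represses"


@dataclass
class RegulonActivity:
    regulon_id: str
    scores: pd.Series  # per-cell AUC
    groups: pd.Series  # per-cell group label


def _other(condition: str) -> str:
    return CONDITIONS[1] if condition == CONDITIONS[0] else CONDITIONS[0]


def _tf_condition(direction: str) -> str:
    # DE directions are aged-vs-young: "up" = aged-enriched, "down" = young-enriched
    return "aged" if direction == "up" else "young"


def build_regulons(
    candidate_edges: pd.DataFrame,
    de: DEResult,
    roles: list[TFRole],
    geneset_condition: str,
    min_targets: int = 5,
) -> list[Regulon]:
    """Filter candidate TF->gene edges into signed, age-labeled regulons.

    An edge survives iff its TF is significantly DE and the role/direction
    rule holds: activators must be enriched in the gene set's condition,
    repressors in the other condition. Targets are restricted to the gene
    set by construction of the candidate edges; window support is carried
    through. Regulons below ``min_targets`` are dropped with a warning.
    """
    if geneset_condition not in CONDITIONS:
        raise ValueError(f"geneset_condition must be one of {CONDITIONS}")
    role_map = {r.tf_id: r.role for r in roles}
    regulons: list[Regulon] = []
    n_no_role = 0
    for tf, grp in candidate_edges.groupby("tf", sort=True):
        if tf not in role_map:
            n_no_role += 1
            continue
        direction = de.direction_of(tf)
        if direction == "ns":
            log.info("build_regulons: TF %s not significantly DE; dropped", tf)
            continue
        role = role_map[tf]
        tf_cond = _tf_condition(direction)
        if role == "activator" and tf_cond != geneset_condition:
            continue
        if role == "repressor" and tf_cond != _other(geneset_condition):
            continue
        targets = set(grp["gene"])
        targets.discard(tf)
        if len(targets) < min_targets:
            log.warning("build_regulons: regulon %s has %d target(s) < %d; dropped",
                        tf, len(targets), min_targets)
            continue
        support = dict(zip(grp["gene"], grp["windows"])) if "windows" in grp else {}
        regulons.append(
            Regulon(
                tf_id=tf,
                role=role,
                tf_condition=tf_cond,
                geneset_condition=geneset_condition,
                targets=targets,
                edge_sign="activates" if role == "activator" else "represses",
                window_support={g: support.get(g, "") for g in targets},
            )
        )
    if n_no_role:
        log.info("build_regulons: %d TF(s) without a role entry dropped", n_no_role)
    log.info("build_regulons: %d regulon(s) emitted for %s gene set",
             len(regulons), geneset_condition)
    return regulons


# ---------------------------------------------------------------------------
# AUCell scoring
# ---------------------------------------------------------------------------


def aucell_rank_cells(
    cells: ExpressionMatrix, seed: int, deterministic_ties: bool = False
) -> pd.DataFrame:
    """Rank genes within each cell by decreasing expression (rank 1 = highest).

    Ties — including the all-zero tail — are broken by a seeded random
    permutation per cell, or lexicographically when ``deterministic_ties``.
    """
    arr = cells.values.to_numpy(float)
    n_genes, n_cells = arr.shape
    rng = np.random.default_rng(seed)
    ranks = np.empty((n_genes, n_cells), dtype=np.int32)
    gene_index = np.arange(n_genes)
    for j in range(n_cells):
        tiebreak = gene_index if deterministic_ties else rng.permutation(n_genes)
        order = np.lexsort((tiebreak, -arr[:, j]))
        ranks[order, j] = np.arange(1, n_genes + 1)
        if arr[:, j].max() == 0:
            log.warning("aucell_rank_cells: cell %s has no counts; ranking is random",
                        cells.sample_ids[j])
    return pd.DataFrame(ranks, index=cells.gene_ids, columns=cells.sample_ids)


def aucell_score(
    rankings: pd.DataFrame,
    regulon: Regulon,
    max_rank_fraction: float = 0.05,
    groups: pd.Series | None = None,
) -> RegulonActivity:
    """Per-cell recovery AUC of the regulon's targets in the cell ranking.

    Identical formula to the motif-enrichment recovery AUC (shared kernel).
    """
    targets = [g for g in regulon.targets if g in rankings.index]
    if not targets:
        raise ValueError(f"regulon {regulon.tf_id} has no targets among ranked genes")
    g = rankings.shape[0]
    max_rank = max(1, int(np.ceil(max_rank_fraction * g)))
    ranks = rankings.loc[targets].to_numpy()  # k x cells
    k = len(targets)
    hits = np.where(ranks <= max_rank, max_rank - ranks + 1, 0)
    raw = hits.sum(axis=0).astype(float)
    kk = min(k, max_rank)
    max_area = kk * (kk + 1) / 2 + max(0, max_rank - k) * k
    scores = pd.Series(raw / max_area, index=rankings.columns, name=regulon.tf_id)
    if groups is None:
        groups = pd.Series("all", index=rankings.columns)
    return RegulonActivity(regulon.tf_id, scores, groups.loc[scores.index])


def compare_regulon_activity(
    act: RegulonActivity, group_a: str, group_b: str
) -> dict:
    """Two-sided rank-sum comparison of per-cell activity between two groups.

    Exact when both groups have <= 10 tie-free cells, otherwise the normal
    approximation with continuity correction. Degenerate input (all scores
    identical) reports p = 1 with a warning.
    """
    a = act.scores[act.groups == group_a].to_numpy()
    b = act.scores[act.groups == group_b].to_numpy()
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs >= 3 cells")
    if np.all(np.concatenate([a, b]) == a[0]):
        log.warning("compare_regulon_activity: all scores identical; p = 1")
        return {"statistic": len(a) * len(b) / 2.0, "p": 1.0,
                "median_a": float(np.median(a)), "median_b": float(np.median(b))}
    method = "exact" if max(len(a), len(b)) <= 10 else "asymptotic"
    if method == "exact" and len(np.unique(np.concatenate([a, b]))) < len(a) + len(b):
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
    }


# ---------------------------------------------------------------------------
# Overexpression validation statistics
# ---------------------------------------------------------------------------


def target_enrichment_fisher(
    predicted_targets: set[str],
    repressed_set: set[str],
    activated_set: set[str],
    alternative: str = "greater",
) -> dict:
    """One-sided Fisher exact test: are predicted targets enriched among
    repressed rather than activated genes?

    The 2x2 table crosses target membership with repressed/activated status
    over the union universe; p is the hypergeometric upper tail. The odds
    ratio uses the Haldane 0.5 correction when any cell is zero.
    """
    if repressed_set & activated_set:
        raise ValueError("repressed and activated sets must be disjoint")
    if not repressed_set or not activated_set:
        raise ValueError("repressed and activated sets must be nonempty")
    a = len(predicted_targets & repressed_set)
    b = len(predicted_targets & activated_set)
    c = len(repressed_set) - a
    d = len(activated_set) - b
    n_total = a + b + c + d
    if alternative == "greater":
        p = float(stats.hypergeom.sf(a - 1, n_total, a + b, a + c))
    elif alternative == "two-sided":
        p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    else:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    if min(a, b, c, d) == 0:
        odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        odds = a * d / (b * c)
    return {"odds_ratio": float(odds), "p_one_sided": p,
            "table": [[a, b], [c, d]]}


def compare_target_sets(
    in_vivo_targets: set[str],
    oe_targets: set[str],
) -> dict:
    """Partition two target sets into shared / in-vivo-only / OE-only, with
    counts suitable for an upset-style plot."""
    shared = in_vivo_targets & oe_targets
    return {
        "shared": shared,
        "in_vivo_only": in_vivo_targets - shared,
        "oe_only": oe_targets - shared,
        "counts": {
            "shared": len(shared),
            "in_vivo_only": len(in_vivo_targets - shared),
            "oe_only": len(oe_targets - shared),
        },
    }


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def regulons_to_json(regulons: list[Regulon]) -> list[dict]:
    return [
        {
            "tf_id": r.tf_id,
            "role": r.role,
            "tf_condition": r.tf_condition,
            "geneset_condition": r.geneset_condition,
            "edge_sign": r.edge_sign,
            "targets": sorted(r.targets),
            "window_support": {g: r.window_support.get(g, "") for g in sorted(r.targets)},
        }
        for r in regulons
    ]


def regulons_from_json(payload: list[dict]) -> list[Regulon]:
    return [
        Regulon(
            tf_id=d["tf_id"],
            role=d["role"],
            tf_condition=d["tf_condition"],
            geneset_condition=d["geneset_condition"],
            targets=set(d["targets"]),
            edge_sign=d["edge_sign"],
            window_support=d.get("window_support", {}),
        )
        for d in payload
    ]
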