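"""Ranking-based motif enrichment over whole-genome promoter rankings.

For each motif the recovery curve rc(x) counts how many query-set genes sit
within that motif's top-x ranked genes. Its area up to ``max_rank``
(normalized by the ideal curve of a same-sized set, so a saturated motif
scores exactly 1) gives the AUC, which is standardized against the AUC
distribution of every motif in the same database to yield the normalized
enrichment score (NES). Motifs with NES above the significance floor
(default 3) are annotated to transcription factors; targets are called by
the point of maximal deviation of the recovery curve above the database
mean + 2 sd curve (the leading edge). Enrichment is run independently in a
proximal and a distal promoter window and the TF->gene edges merged by
union.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import MotifAnnotation, RankingDatabase

log = logging.getLogger("regage.motifenrich")


@dataclass
class EnrichedMotif:
    motif_id: str
    window_label: str
    auc: float
    nes: float
    significant: bool
    leading_edge_targets: set[str] = field(default_factory=set)
    annotated_tfs: set[str] = field(default_factory=set)


def recovery_auc(rank_row: pd.Series | dict, geneset: set[str], max_rank: int) -> float:
    """Area under the recovery curve of ``geneset`` in one motif's ranking.

    The raw area sum_{x=1..max_rank} rc(x) collapses to
    sum over hits (max_rank - rank + 1); it is divided by the area of the
    ideal curve for a set of size k = |geneset ∩ ranked genes|:
    sum_{x=1..min(k,max_rank)} x + max(0, max_rank - k) * k.
    """
    if isinstance(rank_row, dict):
        rank_row = pd.Series(rank_row)
    g = len(rank_row)
    if not (1 <= max_rank <= g):
        raise ValueError(f"max_rank must lie in 1..{g}")
    present = [gene for gene in geneset if gene in rank_row.index]
    k = len(present)
    if k == 0:
        raise ValueError("geneset has empty intersection with database genes")
    ranks = rank_row.loc[present].to_numpy()
    hits = ranks[ranks <= max_rank]
    raw = float((max_rank - hits + 1).sum())
    kk = min(k, max_rank)
    max_area = kk * (kk + 1) / 2 + max(0, max_rank - k) * k
    return raw / max_area


def _aucs_for_db(db: RankingDatabase, geneset: set[str], max_rank: int) -> np.ndarray:
    """Vectorized recovery AUC for every motif in the database."""
    cols = [g for g in geneset if g in db.ranks.columns]
    if not cols:
        raise ValueError("geneset has empty intersection with database genes")
    ranks = db.ranks[cols].to_numpy()  # motifs x k
    k = len(cols)
    hits = np.where(ranks <= max_rank, max_rank - ranks + 1, 0)
    raw = hits.sum(axis=1).astype(float)
    kk = min(k, max_rank)
    max_area = kk * (kk + 1) / 2 + max(0, max_rank - k) * k
    return raw / max_area


def enrich_motifs(
    db: RankingDatabase,
    geneset: set[str],
    max_rank_fraction: float = 0.05,
    nes_min: float = 3.0,
) -> list[EnrichedMotif]:
    """Score every motif in the database; NES standardizes AUC across motifs.

    NES_i = (AUC_i - mean(AUC)) / sd(AUC) with the sample (n-1) standard
    deviation. A degenerate database with zero AUC spread yields NES = 0 for
    all motifs (nothing can be significant) with a warning.
    """
    g = db.ranks.shape[1]
    max_rank = max(1, int(np.ceil(max_rank_fraction * g)))
    aucs = _aucs_for_db(db, geneset, max_rank)
    mean, sd = aucs.mean(), aucs.std(ddof=1) if len(aucs) > 1 else 0.0
    if sd == 0:
        log.warning("enrich_motifs[%s]: zero AUC spread; all NES set to 0", db.window_label)
        nes = np.zeros(len(aucs))
    else:
        nes = (aucs - mean) / sd
    out = [
        EnrichedMotif(
            motif_id=m,
            window_label=db.window_label,
            auc=float(a),
            nes=float(z),
            significant=bool(z > nes_min),
        )
        for m, a, z in zip(db.motif_ids, aucs, nes)
    ]
    n_sig = sum(e.significant for e in out)
    log.info("enrich_motifs[%s]: %d/%d motifs significant at NES>%g (max_rank=%d)",
             db.window_label, n_sig, len(out), nes_min, max_rank)
    return out


def _recovery_curves(db: RankingDatabase, geneset: set[str], max_rank: int) -> np.ndarray:
    """rc(x) for x = 1..max_rank for every motif (motifs x max_rank)."""
    cols = [g for g in geneset if g in db.ranks.columns]
    ranks = db.ranks[cols].to_numpy()
    n_motifs = ranks.shape[0]
    rc = np.zeros((n_motifs, max_rank + 1), dtype=np.int32)
    within = ranks <= max_rank
    for i in range(n_motifs):
        hit_ranks = ranks[i][within[i]]
        np.add.at(rc[i], hit_ranks, 1)
    return np.cumsum(rc, axis=1)[:, 1:]


def leading_edge_rank(
    db: RankingDatabase,
    motif_id: str,
    geneset: set[str],
    max_rank: int,
) -> int | None:
    """Rank of maximal deviation of the motif's recovery curve above the
    database mean + 2 sd curve, or None when the curve never exceeds it.

    Argmax ties break to the smallest rank (the smaller, more precise
    target set).
    """
    if motif_id not in db.ranks.index:
        raise KeyError(f"motif {motif_id!r} not in database {db.window_label}")
    rc = _recovery_curves(db, geneset, max_rank)
    i = db.motif_ids.index(motif_id)
    mean = rc.mean(axis=0)
    sd = rc.std(axis=0, ddof=1) if rc.shape[0] > 1 else np.zeros(rc.shape[1])
    diff = rc[i] - (mean + 2.0 * sd)
    if diff.max() <= 0:
        return None
    return int(np.argmax(diff)) + 1  # first occurrence = smallest rank


def leading_edge(
    db: RankingDatabase,
    motif_id: str,
    geneset: set[str],
    max_rank: int,
) -> set[str]:
    """Query genes ranked at or above the motif's leading-edge rank; empty
    when the recovery curve never exceeds the database threshold curve."""
    rank_at_max = leading_edge_rank(db, motif_id, geneset, max_rank)
    if rank_at_max is None:
        return set()
    row = db.ranks.loc[motif_id]
    return {g for g in geneset if g in row.index and row[g] <= rank_at_max}


def annotate_tfs(
    motifs: list[EnrichedMotif],
    ann: MotifAnnotation,
) -> dict[str, dict]:
    """Aggregate significant motifs to the TF level.

    Returns tf_id -> {windows, best_nes, targets (union of leading edges)}.
    Motifs without an annotation are dropped with a logged count; a motif
    annotated to several TFs contributes to each.
    """
    out: dict[str, dict] = {}
    dropped = 0
    for m in motifs:
        tfs = ann.tfs_for(m.motif_id)
        if not tfs:
            dropped += 1
            continue
        for tf in tfs:
            rec = out.setdefault(tf, {"windows": set(), "best_nes": -np.inf, "targets": set(),
                                      "motifs": set()})
            rec["windows"].add(m.window_label)
            rec["best_nes"] = max(rec["best_nes"], m.nes)
            rec["targets"] |= m.leading_edge_targets
            rec["motifs"].add(m.motif_id)
    if dropped:
        log.info("annotate_tfs: %d significant motif(s) without annotation dropped", dropped)
    return out


def scan_two_windows(
    db_short: RankingDatabase,
    db_long: RankingDatabase,
    geneset: set[str],
    ann: MotifAnnotation,
    max_rank_fraction: float = 0.05,
    nes_min: float = 3.0,
) -> pd.DataFrame:
    """Enrich + annotate each promoter window independently, then union the
    TF->gene edges, tagging each with the window(s) supporting it.

    Returns a table with columns tf, gene, windows (comma-joined sorted
    labels), best_nes.
    """
    genes_s, genes_l = set(db_short.gene_ids), set(db_long.gene_ids)
    if genes_s != genes_l:
        asym = sorted((genes_s ^ genes_l))[:10]
        raise ValueError(f"gene universes differ between windows; e.g. {asym}")

    edges: dict[tuple[str, str], dict] = {}
    for db in (db_short, db_long):
        g = db.ranks.shape[1]
        max_rank = max(1, int(np.ceil(max_rank_fraction * g)))
        enriched = [e for e in enrich_motifs(db, geneset, max_rank_fraction, nes_min)
                    if e.significant]
        for e in enriched:
            e.leading_edge_targets = leading_edge(db, e.motif_id, geneset, max_rank)
        tf_map = annotate_tfs(enriched, ann)
        for tf, rec in tf_map.items():
            for gene in rec["targets"]:
                key = (tf, gene)
                entry = edges.setdefault(key, {"windows": set(), "best_nes": -np.inf})
                entry["windows"].add(db.window_label)
                entry["best_nes"] = max(entry["best_nes"], rec["best_nes"])

    rows = [
        {"tf": tf, "gene": gene,
         "windows": ",".join(sorted(v["windows"])), "best_nes": v["best_nes"]}
        for (tf, gene), v in sorted(edges.items())
    ]
    df = pd.DataFrame(rows, columns=["tf", "gene", "windows", "best_nes"])
    log.info("scan_two_windows: %d merged TF->gene edges over %d TFs",
             len(df), df["tf"].nunique() if len(df) else 0)
    return df
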