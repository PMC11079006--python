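"""Synthetic data generation with a planted ground-truth ledger.

Every input the pipeline consumes is emulated here: a bulk two-condition
(young vs aged) negative-binomial count matrix with batch effects and
planted regulon targets; two promoter-window motif ranking databases whose
planted motifs rank their regulon's targets near the top; a single-cell
overexpression experiment (control vs tf_active) with mitochondrial genes,
depth variation and deliberate low-quality cells; miRNA array
log-intensities with planted condition shifts and five partially redundant
target databases; a curated TF->miRNA table; and a term->gene annotation
table with enriched, decoy and near-duplicate terms.

All generation is a pure function of (config, seed): each stage derives its
generator from the config seed and a fixed stage offset, so stages can be
re-run independently and reproduce byte-identically.

The generator's defaults define the study conditions used throughout the
test suite: 2,000 genes, four aged repressors with 50 targets each at a
2.0 log2 effect, 8 young vs 3 aged samples, 200-motif databases per window.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    ExpressionMatrix,
    GeneSetCollection,
    MotifAnnotation,
    RankingDatabase,
    write_expression,
    write_gmt,
    write_meta,
    write_motif_annotation,
    write_ranking_db,
    write_target_db,
)

log = logging.getLogger("regage.synthdata")

# stage offsets for child generators (pure function of config.seed)
_STAGE = {"bulk": 1, "rankdb": 2, "cells": 3, "mirna": 4, "terms": 5}


@dataclass
class SimulationConfig:
    n_genes: int = 2000
    n_samples_per_condition: tuple[int, int] = (8, 3)  # (young, aged)
    n_batches: int = 2
    nb_dispersion: float = 0.05
    sc_nb_dispersion: float = 0.3
    baseline_mean_log2_range: tuple[float, float] = (5.0, 9.0)
    n_regulons: int = 4
    regulon_roles: list[dict] = field(
        default_factory=lambda: [{"role": "repressor", "condition": "aged"}] * 4
    )
    targets_per_regulon: int = 50
    regulon_effect_log2: float = 2.0
    motif_db_size: int = 200
    planted_rank_quantile: float = 0.05
    planted_target_fraction: float = 0.9
    n_cells_per_group: int = 200
    sc_max_mito_pct: float = 15.0  # quality floor the low-quality cells violate
    sc_min_genes: int = 500
    n_mirnas: int = 60
    mirna_effect_log2: float = 1.5
    n_target_dbs: int = 5
    db_recall: float = 0.7
    decoy_targets_per_db: int = 20
    targets_per_mirna: int = 40
    n_terms: int = 50
    term_size_range: tuple[int, int] = (20, 60)
    n_background_de_genes: int = 100  # regulon-independent DE genes, split 50/50
    n_indirect_response_genes: int = 100  # mildly induced in tf_active cells
    n_mirna_samples_per_condition: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [self.n_genes, self.n_batches, self.targets_per_regulon,
                  self.motif_db_size, self.n_cells_per_group, self.n_mirnas,
                  self.n_target_dbs, self.n_terms]
        if any(c <= 0 for c in counts):
            raise ValueError("all size parameters must be positive")
        if not (0 < self.planted_rank_quantile <= 1):
            raise ValueError("planted_rank_quantile must lie in (0, 1]")
        if not (0 < self.planted_target_fraction <= 1):
            raise ValueError("planted_target_fraction must lie in (0, 1]")
        if not (0 <= self.db_recall <= 1):
            raise ValueError("db_recall must lie in [0, 1]")
        if self.n_target_dbs < 2:
            raise ValueError("n_target_dbs must be >= 2")
        if self.n_regulons != len(self.regulon_roles):
            raise ValueError("regulon_roles must have n_regulons entries")
        needed = self.n_regulons * (self.targets_per_regulon + 1) + self.n_background_de_genes
        if needed > self.n_genes:
            raise ValueError(
                f"planted genes ({needed}) exceed n_genes ({self.n_genes})"
            )


@dataclass
class TruthLedger:
    """Everything planted, for downstream oracle tests."""

    regulons: list[dict] = field(default_factory=list)
    de_genes: dict[str, dict] = field(default_factory=dict)
    mirna_truth: dict[str, dict] = field(default_factory=dict)
    tf_mirna_edges: list[dict] = field(default_factory=list)
    term_truth: dict[str, dict] = field(default_factory=dict)
    low_quality_cells: dict[str, str] = field(default_factory=dict)  # cell -> defect kind
    oe_indirect_genes: list[str] = field(default_factory=list)
    duplicate_term_pairs: list[list[str]] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["regulons"] = [
            {**r, "true_targets": sorted(r["true_targets"])} for r in payload["regulons"]
        ]
        payload["mirna_truth"] = {
            m: {**v, "true_targets": sorted(v["true_targets"])}
            for m, v in payload["mirna_truth"].items()
        }
        payload["term_truth"] = {
            t: {**v, "genes": sorted(v["genes"])} for t, v in payload["term_truth"].items()
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthLedger":
        payload = json.loads(Path(path).read_text())
        led = cls(**payload)
        for r in led.regulons:
            r["true_targets"] = set(r["true_targets"])
        for v in led.mirna_truth.values():
            v["true_targets"] = set(v["true_targets"])
        for v in led.term_truth.values():
            v["genes"] = set(v["genes"])
        return led

    def targets_of(self, tf_id: str) -> set[str]:
        for r in self.regulons:
            if r["tf_id"] == tf_id:
                return set(r["true_targets"])
        raise KeyError(tf_id)


def _gene_ids(config: SimulationConfig) -> tuple[list[str], list[str]]:
    """(all gene ids, TF gene ids). TFs are ordinary genes with TF names."""
    tfs = [f"TF{i + 1:02d}" for i in range(config.n_regulons)]
    others = [f"G{i + 1:05d}" for i in range(config.n_genes - config.n_regulons)]
    return tfs + others, tfs


def _effect_sign(role: str, condition: str) -> float:
    """Aged-vs-young sign of the planted target effect.

    A repressor active in `aged` lowers its targets in aged samples
    (negative aged-vs-young log2FC); an activator raises them.
    """
    cond_sign = +1.0 if condition == "aged" else -1.0
    role_sign = +1.0 if role == "activator" else -1.0
    return cond_sign * role_sign


# ---------------------------------------------------------------------------
# Bulk counts
# ---------------------------------------------------------------------------


def simulate_bulk(
    config: SimulationConfig, rep: int = 0
) -> tuple[ExpressionMatrix, TruthLedger]:
    """Negative-binomial bulk counts with planted regulon and background effects.

    Per gene g and sample s the mean is mu = 2^(b_g + beta_g * [aged] +
    gamma_batch(s)) with shared dispersion; beta is +/- the regulon effect for
    planted targets (sign per the repressor/activator rule), the TF gene
    itself is raised in its own condition, and batches are balanced across
    conditions.

    ``rep`` re-draws only the count noise (baselines, batch offsets and the
    planted structure are shared), giving independent replicate experiments
    over the same ground truth — the substrate for the concordance
    intersection of two comparisons.
    """
    rng = np.random.default_rng([config.seed, _STAGE["bulk"], 0])
    noise_rng = np.random.default_rng([config.seed, _STAGE["bulk"], 1 + rep])
    genes, tfs = _gene_ids(config)
    n_young, n_aged = config.n_samples_per_condition
    samples = [f"Y{i + 1:02d}" for i in range(n_young)] + [f"A{i + 1:02d}" for i in range(n_aged)]
    condition = ["young"] * n_young + ["aged"] * n_aged
    # balanced batch assignment within each condition
    batch = [f"b{(i % config.n_batches) + 1}" for i in range(n_young)] + [
        f"b{(i % config.n_batches) + 1}" for i in range(n_aged)
    ]
    meta = pd.DataFrame({"condition": condition, "batch": batch}, index=samples)

    baseline = rng.uniform(*config.baseline_mean_log2_range, size=config.n_genes)
    gamma = {f"b{i + 1}": g for i, g in enumerate(rng.normal(0.0, 0.25, config.n_batches))}

    beta = np.zeros(config.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    ledger = TruthLedger(gene_ids=genes)

    non_tf = [g for g in genes if g not in tfs]
    pool = list(rng.permutation(non_tf))
    for tf, spec_role in zip(tfs, config.regulon_roles):
        role, cond = spec_role["role"], spec_role["condition"]
        targets = set(pool[: config.targets_per_regulon])
        del pool[: config.targets_per_regulon]
        sign = _effect_sign(role, cond)
        for g in targets:
            beta[gene_index[g]] = sign * config.regulon_effect_log2
            ledger.de_genes[g] = {
                "true_log2fc": sign * config.regulon_effect_log2,
                "condition": "aged" if sign > 0 else "young",
            }
        tf_sign = +1.0 if cond == "aged" else -1.0
        beta[gene_index[tf]] = tf_sign * config.regulon_effect_log2
        ledger.de_genes[tf] = {
            "true_log2fc": tf_sign * config.regulon_effect_log2,
            "condition": cond,
        }
        ledger.regulons.append(
            {"tf_id": tf, "role": role, "condition": cond, "true_targets": targets}
        )

    n_bg = config.n_background_de_genes
    bg = pool[:n_bg]
    del pool[:n_bg]
    for i, g in enumerate(bg):
        sign = +1.0 if i < n_bg // 2 else -1.0
        beta[gene_index[g]] = sign * config.regulon_effect_log2
        ledger.de_genes[g] = {
            "true_log2fc": sign * config.regulon_effect_log2,
            "condition": "aged" if sign > 0 else "young",
        }

    aged_ind = np.array([1.0 if c == "aged" else 0.0 for c in condition])
    gamma_s = np.array([gamma[b] for b in batch])
    log2_mu = baseline[:, None] + beta[:, None] * aged_ind[None, :] + gamma_s[None, :]
    mu = np.exp2(log2_mu)
    r = 1.0 / config.nb_dispersion  # NB size; var = mu + dispersion * mu^2
    counts = noise_rng.negative_binomial(r, r / (r + mu))

    # sign-consistency self-check: the batch-adjusted aged-vs-young contrast of
    # the sampling means (exactly beta) moves the way the ledger records
    for g, rec in ledger.de_genes.items():
        i = gene_index[g]
        contrast = (log2_mu[i] - gamma_s)[aged_ind == 1].mean() - (
            log2_mu[i] - gamma_s
        )[aged_ind == 0].mean()
        assert np.isclose(contrast, rec["true_log2fc"]), "planted sign inconsistency"

    mat = ExpressionMatrix(pd.DataFrame(counts, index=genes, columns=samples), meta, "count")
    log.info("simulate_bulk: %d genes x %d samples, %d planted DE genes",
             config.n_genes, len(samples), len(ledger.de_genes))
    return mat, ledger


def to_tpm(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Per-sample abundance normalized to one million (unit-length genes)."""
    arr = mat.values.to_numpy(float)
    tpm = arr / arr.sum(axis=0, keepdims=True) * 1e6
    return ExpressionMatrix(
        pd.DataFrame(tpm, index=mat.gene_ids, columns=mat.sample_ids),
        mat.sample_meta, "tpm",
    )


# ---------------------------------------------------------------------------
# Ranking databases
# ---------------------------------------------------------------------------

WINDOW_SHORT = "500bp_up_100bp_down"
WINDOW_LONG = "10kb_up_10kb_down"


def simulate_ranking_db(
    truth: TruthLedger, config: SimulationConfig
) -> tuple[RankingDatabase, RankingDatabase, MotifAnnotation]:
    """Two independently generated promoter-window ranking databases.

    Each planted regulon gets one annotated motif per window whose row places
    planted_target_fraction of the true targets uniformly within the top
    planted_rank_quantile of ranks; the remaining motifs are random decoys.
    """
    rng = np.random.default_rng([config.seed, _STAGE["rankdb"]])
    genes = truth.gene_ids
    g = len(genes)
    n_top = int(np.floor(config.planted_rank_quantile * g))
    tfs = {}
    ann_conf = {}

    dbs = []
    for window in (WINDOW_SHORT, WINDOW_LONG):
        rows = {}
        for reg in truth.regulons:
            motif = f"m_{reg['tf_id']}_{window}"
            targets = sorted(reg["true_targets"])
            n_planted = int(round(config.planted_target_fraction * len(targets)))
            if n_planted > n_top:
                raise ValueError(
                    f"{n_planted} planted targets exceed top-quantile capacity {n_top}"
                )
            planted = list(rng.choice(targets, size=n_planted, replace=False))
            top_ranks = 1 + rng.choice(n_top, size=n_planted, replace=False)
            rank_row = np.empty(g, dtype=np.int64)
            gene_pos = {gid: i for i, gid in enumerate(genes)}
            remaining_ranks = np.setdiff1d(np.arange(1, g + 1), top_ranks)
            rng.shuffle(remaining_ranks)
            others = [gid for gid in genes if gid not in set(planted)]
            for gid, rk in zip(planted, top_ranks):
                rank_row[gene_pos[gid]] = rk
            for gid, rk in zip(others, remaining_ranks):
                rank_row[gene_pos[gid]] = rk
            rows[motif] = rank_row
            tfs[motif] = {reg["tf_id"]}
            ann_conf[motif] = "high"
        for d in range(config.motif_db_size - len(truth.regulons)):
            rows[f"decoy_{window}_{d + 1:04d}"] = 1 + rng.permutation(g)
        df = pd.DataFrame(rows, index=genes).T
        df.columns = genes
        dbs.append(RankingDatabase(window, df))
    ann = MotifAnnotation(tfs, ann_conf)
    return dbs[0], dbs[1], ann


# ---------------------------------------------------------------------------
# Single-cell overexpression experiment
# ---------------------------------------------------------------------------

N_MITO_GENES = 10
CELL_DEPTH = 8000.0
LOWQ_FRACTION = 0.05


def simulate_cells(
    truth: TruthLedger, config: SimulationConfig, tf_id: str | None = None
) -> tuple[ExpressionMatrix, TruthLedger]:
    """Control vs tf_active single-cell counts for one repressor regulon.

    In tf_active cells the chosen repressor's true targets are scaled by
    2^(-effect) (2^(+effect) for an activator), and a disjoint set of
    indirect-response genes is mildly induced (2^(effect/4)) — the secondary
    transcriptional response to transgene induction, which gives the
    overexpression contrast a nonempty upregulated side. Mitochondrial genes
    ("MT-" prefix) and per-cell depth variation are included; a 5% tail of
    deliberate low-quality cells (very high mitochondrial fraction or very
    low depth) is appended and recorded in the ledger.
    """
    repressors = [r for r in truth.regulons if r["role"] == "repressor"]
    if tf_id is None:
        if not repressors:
            raise ValueError("simulate_cells requires at least one repressor regulon")
        reg = repressors[0]
    else:
        reg = next(r for r in truth.regulons if r["tf_id"] == tf_id)
    rng = np.random.default_rng([config.seed, _STAGE["cells"]])

    genes = list(truth.gene_ids) + [f"MT-{i + 1}" for i in range(N_MITO_GENES)]
    n_genes = len(genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    baseline = np.exp2(rng.uniform(*config.baseline_mean_log2_range, size=n_genes))
    # mitochondrial genes carry ~5% of a healthy cell's counts
    mito_idx = np.array([i for i, g in enumerate(genes) if g.startswith("MT-")])
    non_mito_total = baseline.sum() - baseline[mito_idx].sum()
    baseline[mito_idx] = 0.05 / 0.95 * non_mito_total / N_MITO_GENES

    effect = config.regulon_effect_log2
    scale = 2.0 ** (-effect if reg["role"] == "repressor" else effect)
    indirect_scale = 2.0 ** (effect / 4.0)
    target_idx = np.array([gene_index[g] for g in sorted(reg["true_targets"])])
    tf_idx = gene_index[reg["tf_id"]]
    excluded = set(reg["true_targets"]) | {reg["tf_id"]} | set(truth.de_genes)
    indirect_pool = [g for g in truth.gene_ids if g not in excluded]
    indirect = sorted(rng.choice(indirect_pool,
                                 size=min(config.n_indirect_response_genes,
                                          len(indirect_pool)),
                                 replace=False))
    indirect_idx = np.array([gene_index[g] for g in indirect], dtype=int)

    n_per = config.n_cells_per_group
    n_lowq = max(2, int(np.ceil(LOWQ_FRACTION * 2 * n_per)))
    n_lowq_mito = n_lowq // 2
    n_lowq_depth = n_lowq - n_lowq_mito

    groups = ["control"] * n_per + ["tf_active"] * n_per
    lowq_kinds = ["high_mito"] * n_lowq_mito + ["low_depth"] * n_lowq_depth
    groups += ["control" if i % 2 == 0 else "tf_active" for i in range(n_lowq)]
    cells = [f"C{i + 1:04d}" for i in range(len(groups))]

    r = 1.0 / config.sc_nb_dispersion
    depth_factor = rng.lognormal(0.0, 0.3, size=len(cells))
    counts = np.zeros((n_genes, len(cells)), dtype=np.int64)
    ledger = dataclasses.replace(
        truth,
        low_quality_cells={},
        oe_indirect_genes=indirect,
    )
    for j, cell in enumerate(cells):
        means = baseline.copy()
        if groups[j] == "tf_active":
            means[target_idx] *= scale
            if len(indirect_idx):
                means[indirect_idx] *= indirect_scale
            means[tf_idx] *= 2.0**effect  # transgene induction
        kind = None
        if j >= 2 * n_per:
            kind = lowq_kinds[j - 2 * n_per]
            if kind == "high_mito":
                means[mito_idx] *= 25.0  # ~55-60% mitochondrial
            else:
                # total counts well below the detected-genes floor, so the
                # cell cannot reach min_genes detected genes
                depth_factor[j] = config.sc_min_genes / 3.0 / CELL_DEPTH
            ledger.low_quality_cells[cell] = kind
        means = means / means.sum() * CELL_DEPTH * depth_factor[j]
        counts[:, j] = rng.negative_binomial(r, r / (r + means))

    meta = pd.DataFrame({"condition": groups, "batch": "b1"}, index=cells)
    mat = ExpressionMatrix(pd.DataFrame(counts, index=genes, columns=cells), meta, "count")

    # generation-time check: planted-good cells clear the quality filters with
    # margin and deliberate low-quality cells violate them strictly
    arr = counts.astype(float)
    mito_pct = 100.0 * arr[mito_idx].sum(axis=0) / np.maximum(arr.sum(axis=0), 1)
    detected = (arr > 0).sum(axis=0)
    mito_max, genes_min = config.sc_max_mito_pct, config.sc_min_genes
    for j, cell in enumerate(cells):
        if cell in ledger.low_quality_cells:
            assert mito_pct[j] > mito_max or detected[j] < genes_min, \
                "low-quality cell passes filters"
        else:
            assert mito_pct[j] <= mito_max and detected[j] >= genes_min, \
                "good cell fails filters"

    log.info("simulate_cells: %d genes x %d cells (%d low-quality) for regulon %s",
             n_genes, len(cells), n_lowq, reg["tf_id"])
    return mat, ledger


# ---------------------------------------------------------------------------
# miRNA arrays, target databases, curated TF->miRNA table
# ---------------------------------------------------------------------------


def simulate_mirna(
    truth: TruthLedger, config: SimulationConfig
) -> tuple[ExpressionMatrix, list[dict[str, list[str]]], pd.DataFrame, TruthLedger]:
    """Gaussian log-intensities with planted shifts, plus target databases.

    Two thirds of the miRNAs are differentially expressed (half per
    condition) with a +/- mirna_effect_log2 shift. Each true target of a DE
    miRNA enters each of the n_target_dbs databases independently with
    probability db_recall, placed uniformly within the top half of that
    database's list; every database adds decoy targets. The curated
    TF->miRNA table mixes planted edges between DE entities with decoys
    touching non-DE entities.
    """
    if config.n_mirnas < 2:
        raise ValueError("n_mirnas must be >= 2")
    rng = np.random.default_rng([config.seed, _STAGE["mirna"]])
    mirnas = [f"mir{i + 1:03d}" for i in range(config.n_mirnas)]
    n_de = (config.n_mirnas * 2 // 3) // 2 * 2
    de_mirnas = mirnas[:n_de]
    half = n_de // 2

    n_per = config.n_mirna_samples_per_condition
    samples = [f"My{i + 1}" for i in range(n_per)] + [f"Ma{i + 1}" for i in range(n_per)]
    meta = pd.DataFrame(
        {"condition": ["young"] * n_per + ["aged"] * n_per, "batch": "b1"}, index=samples
    )
    baseline = rng.uniform(5.0, 9.0, size=config.n_mirnas)
    shift = np.zeros(config.n_mirnas)
    shift[:half] = config.mirna_effect_log2       # aged-enriched
    shift[half:n_de] = -config.mirna_effect_log2  # young-enriched
    aged_ind = np.array([0.0] * n_per + [1.0] * n_per)
    mu = baseline[:, None] + shift[:, None] * aged_ind[None, :]
    intensities = mu + rng.normal(0.0, 0.25, size=mu.shape)
    mat = ExpressionMatrix(
        pd.DataFrame(intensities, index=mirnas, columns=samples), meta, "log_intensity"
    )

    ledger = dataclasses.replace(truth, mirna_truth={}, tf_mirna_edges=[])
    aged_genes = sorted(g for g, v in truth.de_genes.items() if v["condition"] == "aged")
    young_genes = sorted(g for g, v in truth.de_genes.items() if v["condition"] == "young")
    all_genes = truth.gene_ids
    for i, m in enumerate(de_mirnas):
        cond = "aged" if i < half else "young"
        pool = young_genes if cond == "aged" else aged_genes
        k = min(config.targets_per_mirna, len(pool))
        targets = set(rng.choice(pool, size=k, replace=False))
        ledger.mirna_truth[m] = {"condition": cond, "true_targets": targets}

    dbs: list[dict[str, list[str]]] = []
    for _ in range(config.n_target_dbs):
        db: dict[str, list[str]] = {}
        for m in mirnas:
            true_t = sorted(ledger.mirna_truth.get(m, {}).get("true_targets", set()))
            included = [g for g in true_t if rng.random() < config.db_recall]
            decoy_pool = [g for g in all_genes if g not in set(true_t)]
            decoys = list(rng.choice(decoy_pool, size=config.decoy_targets_per_db,
                                     replace=False))
            total = len(included) + len(decoys)
            ordered: list[str | None] = [None] * total
            top_half = max(len(included), int(np.ceil(total / 2)))
            pos = rng.choice(top_half, size=len(included), replace=False)
            for g, p in zip(included, pos):
                ordered[p] = g
            it = iter(decoys)
            for idx in range(total):
                if ordered[idx] is None:
                    ordered[idx] = next(it)
            db[m] = ordered  # type: ignore[assignment]
        dbs.append(db)

    rows = []
    tf_conditions = {r["tf_id"]: r["condition"] for r in truth.regulons}
    tf_roles = {r["tf_id"]: r["role"] for r in truth.regulons}
    for tf in sorted(tf_conditions):
        picks = rng.choice(de_mirnas, size=min(5, len(de_mirnas)), replace=False)
        for m in picks:
            sign = "represses" if tf_roles[tf] == "repressor" else "activates"
            rows.append({"tf_id": tf, "mirna_id": m, "evidence": "planted"})
            ledger.tf_mirna_edges.append({"tf_id": tf, "mirna_id": m, "sign": sign})
    # decoys touching non-DE entities (non-DE miRNAs, non-DE genes as "TFs")
    non_de_mirnas = mirnas[n_de:]
    non_de_genes = [g for g in all_genes if g not in truth.de_genes][:10]
    for tf, m in zip(non_de_genes, non_de_mirnas):
        rows.append({"tf_id": tf, "mirna_id": m, "evidence": "decoy"})
    tf_mir = pd.DataFrame(rows, columns=["tf_id", "mirna_id", "evidence"])
    return mat, dbs, tf_mir, ledger


# ---------------------------------------------------------------------------
# Functional terms
# ---------------------------------------------------------------------------

TRUE_TERM_DE_FRACTION = 0.8
N_DUPLICATE_PAIRS = 3


def simulate_terms(
    truth: TruthLedger, config: SimulationConfig
) -> tuple[pd.DataFrame, TruthLedger]:
    """Term->gene annotations with planted enriched, decoy and duplicate terms.

    True terms draw >= 70% (here 80%) of their genes from planted DE genes of
    one condition with a consistent expected direction; decoy terms sample
    genes uniformly. Near-duplicate copies (Jaccard > 0.8) of the first few
    true terms are injected to exercise redundancy pruning.
    """
    if config.n_terms < 2:
        raise ValueError("n_terms must be >= 2")
    lo, hi = config.term_size_range
    if hi > config.n_genes:
        raise ValueError("term_size_range exceeds n_genes")
    rng = np.random.default_rng([config.seed, _STAGE["terms"]])
    ledger = dataclasses.replace(truth, term_truth={}, duplicate_term_pairs=[])

    genes = truth.gene_ids
    de_by_cond = {
        c: sorted(g for g, v in truth.de_genes.items() if v["condition"] == c)
        for c in ("young", "aged")
    }
    non_de = [g for g in genes if g not in truth.de_genes]
    n_true = max(4, config.n_terms // 5)
    rows = []

    def add_term(term_id, members, directions, kind, condition=None):
        ledger.term_truth[term_id] = {"genes": set(members), "kind": kind,
                                      "condition": condition}
        for g in members:
            rows.append({"term_id": term_id, "gene_id": g,
                         "expected_direction": directions[g]})

    true_ids = []
    for i in range(n_true):
        cond = "young" if i % 2 == 0 else "aged"
        size = int(rng.integers(lo, hi + 1))
        n_de_genes = min(int(np.ceil(TRUE_TERM_DE_FRACTION * size)), len(de_by_cond[cond]))
        members = list(rng.choice(de_by_cond[cond], size=n_de_genes, replace=False))
        members += list(rng.choice(non_de, size=size - n_de_genes, replace=False))
        expected = "down" if cond == "young" else "up"  # aged-vs-young sign
        add_term(f"term_true_{i + 1:02d}", members, {g: expected for g in members},
                 "true", cond)
        true_ids.append((f"term_true_{i + 1:02d}", members, expected, cond))

    for i in range(min(N_DUPLICATE_PAIRS, n_true)):
        base_id, members, expected, cond = true_ids[i]
        n_swap = max(1, len(members) // 12)  # Jaccard stays > 0.8
        keep = list(members[:-n_swap])
        pool = [g for g in non_de if g not in set(members)]
        dup = keep + list(rng.choice(pool, size=n_swap, replace=False))
        dup_id = f"{base_id}_dup"
        add_term(dup_id, dup, {g: expected for g in dup}, "duplicate", cond)
        ledger.duplicate_term_pairs.append([base_id, dup_id])

    n_decoys = config.n_terms - n_true - min(N_DUPLICATE_PAIRS, n_true)
    for i in range(n_decoys):
        size = int(rng.integers(lo, hi + 1))
        members = list(rng.choice(genes, size=size, replace=False))
        dirs = {g: ("up" if rng.random() < 0.5 else "down") for g in members}
        add_term(f"term_decoy_{i + 1:02d}", members, dirs, "decoy")

    table = pd.DataFrame(rows, columns=["term_id", "gene_id", "expected_direction"])
    return table, ledger


# ---------------------------------------------------------------------------
# Whole-study generation
# ---------------------------------------------------------------------------


def simulate_all(config: SimulationConfig) -> dict:
    """Generate every pipeline input; returns a dict of in-memory objects."""
    bulk, ledger = simulate_bulk(config)
    db_short, db_long, ann = simulate_ranking_db(ledger, config)
    cells, ledger = simulate_cells(ledger, config)
    mirna_mat, target_dbs, tf_mir, ledger = simulate_mirna(ledger, config)
    terms, ledger = simulate_terms(ledger, config)
    return {
        "config": config,
        "bulk": bulk,
        "tpm": to_tpm(bulk),
        "db_short": db_short,
        "db_long": db_long,
        "annotation": ann,
        "cells": cells,
        "mirna": mirna_mat,
        "target_dbs": target_dbs,
        "tf_mir": tf_mir,
        "terms": terms,
        "truth": ledger,
    }


def write_study(study: dict, outdir: str | Path) -> None:
    """Write a generated study to disk in the pipeline's input formats."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression(study["bulk"], out / "bulk.tsv")
    write_meta(study["bulk"], out / "meta.tsv")
    write_expression(study["tpm"], out / "tpm.tsv")
    write_expression(study["cells"], out / "cells.mtx", format="mtx_triplet")
    write_meta(study["cells"], out / "cells_meta.tsv")
    write_ranking_db(study["db_short"], out / "rankdb_500bp.tsv")
    write_ranking_db(study["db_long"], out / "rankdb_10kb.tsv")
    write_motif_annotation(study["annotation"], out / "motif_annotation.tsv")
    write_expression(study["mirna"], out / "mirna_intensity.tsv")
    write_meta(study["mirna"], out / "mirna_meta.tsv")
    for i, db in enumerate(study["target_dbs"], start=1):
        write_target_db(db, out / f"target_db_{i}.tsv")
    study["tf_mir"].to_csv(out / "tf_mirna.tsv", sep="\t", index=False)
    study["terms"].to_csv(out / "terms.tsv", sep="\t", index=False)
    study["truth"].to_json(out / "truth.json")
    truth = study["truth"]
    sets = GeneSetCollection()
    de = truth.de_genes
    sets.sets["aged_enriched"] = {g for g, v in de.items() if v["condition"] == "aged"}
    sets.sets["young_enriched"] = {g for g, v in de.items() if v["condition"] == "young"}
    sets.conditions = {"aged_enriched": "aged", "young_enriched": "young"}
    write_gmt(sets, out / "genesets.gmt")
    cfg = dataclasses.asdict(study["config"])
    (out / "sim-config.json").write_text(json.dumps(cfg, indent=1, sort_keys=True))
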