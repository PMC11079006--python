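"""Data model, file I/O, configuration and logging for the regulatory-aging pipeline.

The pipeline contrasts a "young" and an "aged" condition throughout; effect
signs are always reported aged-vs-young. Gene, motif, miRNA and term
identifiers are opaque strings: no species or identifier-scheme assumption is
made anywhere.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("regage")

VALID_UNITS = ("count", "tpm", "log_intensity")
EDGE_SIGNS = ("activates", "represses", "targets", "annotates")
NODE_KINDS = ("tf", "gene", "mirna", "term")


def setup_logging(level: str = "INFO") -> None:
    """Configure the package logger once; idempotent."""
    root = logging.getLogger("regage")
    root.setLevel(getattr(logging, level.upper()))
    if not root.handlers:
        h = logging.StreamHandler()
        h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
        root.addHandler(h)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples (or cells) abundance table with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, columns are sample (or cell) ids.
    sample_meta
        DataFrame indexed by sample id with at least a ``condition`` column;
        a ``batch`` column is optional for unbatched designs.
    unit
        One of ``count`` (non-negative integers), ``tpm`` or ``log_intensity``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    unit: str = "count"

    def __post_init__(self) -> None:
        self.validate()

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def validate(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        if self.unit != "log_intensity" and (self.values.to_numpy() < 0).any():
            raise ValueError(f"negative values not allowed for unit={self.unit}")
        if self.unit == "count":
            arr = self.values.to_numpy()
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers when unit=count")
        missing = [s for s in self.values.columns if s not in self.sample_meta.index]
        if missing:
            raise ValueError(f"metadata missing for sample(s): {missing[:5]}")
        if "condition" not in self.sample_meta.columns:
            raise ValueError("sample metadata must contain a 'condition' column")

    def conditions(self) -> pd.Series:
        """Condition label per sample, in column order."""
        return self.sample_meta.loc[self.sample_ids, "condition"]

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        return ExpressionMatrix(self.values[ids], self.sample_meta.loc[ids], self.unit)


@dataclass
class GeneSetCollection:
    """Named gene sets, optionally tagged with the condition they represent."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    conditions: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class RankingDatabase:
    """Motifs x genes whole-genome ranking table for one promoter window.

    Each motif row is a permutation of 1..G (rank 1 = best-scoring gene for
    that motif); the invariant is enforced at construction.
    """

    window_label: str
    ranks: pd.DataFrame  # motifs x genes, integer

    def __post_init__(self) -> None:
        g = self.ranks.shape[1]
        expected = np.arange(1, g + 1)
        arr = self.ranks.to_numpy()
        for i, motif in enumerate(self.ranks.index):
            row = np.sort(arr[i])
            if not np.array_equal(row, expected):
                vals, counts = np.unique(arr[i], return_counts=True)
                dups = vals[counts > 1]
                if len(dups):
                    raise ValueError(f"rank {int(dups[0])} duplicated in motif {motif}")
                raise ValueError(f"motif {motif} row is not a permutation of 1..{g}")

    @property
    def motif_ids(self) -> list[str]:
        return list(self.ranks.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.ranks.columns)


@dataclass
class MotifAnnotation:
    """Motif -> transcription-factor annotation with an ordinal confidence tier."""

    tfs: dict[str, set[str]]
    confidence: dict[str, str] = field(default_factory=dict)

    def tfs_for(self, motif_id: str) -> set[str]:
        return self.tfs.get(motif_id, set())


@dataclass
class RegulatoryNetwork:
    """Typed multi-layer network: TF->gene, miRNA->gene, TF->miRNA, term->gene.

    nodes: id -> {"kind": tf|gene|mirna|term, "direction": up|down|none, ...}
    edges: list of {"source", "target", "sign", "provenance"}
    modules: optional node -> module id mapping.
    """

    nodes: dict[str, dict] = field(default_factory=dict)
    edges: list[dict] = field(default_factory=list)
    modules: dict[str, int] = field(default_factory=dict)

    def add_node(self, node_id: str, kind: str, direction: str = "none", **attrs) -> None:
        if kind not in NODE_KINDS:
            raise ValueError(f"unknown node kind {kind!r}")
        existing = self.nodes.get(node_id, {})
        existing.update({"kind": kind, "direction": direction, **attrs})
        self.nodes[node_id] = existing

    def add_edge(self, source: str, target: str, sign: str, provenance: str) -> None:
        if sign not in EDGE_SIGNS:
            raise ValueError(f"unknown edge sign {sign!r}; expected one of {EDGE_SIGNS}")
        if source not in self.nodes or target not in self.nodes:
            raise ValueError(f"edge endpoints must be added as nodes first: {source}->{target}")
        self.edges.append(
            {"source": source, "target": target, "sign": sign, "provenance": provenance}
        )

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for nid, attrs in self.nodes.items():
            g.add_node(nid, **attrs)
        for e in self.edges:
            g.add_edge(e["source"], e["target"], sign=e["sign"], provenance=e["provenance"])
        for nid, m in self.modules.items():
            g.nodes[nid]["module"] = m
        return g


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_meta(meta_path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    first = meta.columns[0]
    return meta.set_index(first)


def read_expression(
    path: str | Path,
    format: str = "tsv",
    meta_path: str | Path | None = None,
    unit: str = "count",
) -> ExpressionMatrix:
    """Read a genes x samples expression table plus its sample metadata.

    ``tsv``: dense table, first column gene ids, header sample ids.
    ``mtx_triplet``: MatrixMarket coordinate file; gene and sample ids are read
    from sibling ``<stem>.genes.txt`` and ``<stem>.samples.txt`` files.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.shape[0] == 0:
            raise ValueError(f"no genes parsed from {path}")
        bad = df.columns[~df.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
        if len(bad):
            col = bad[0]
            row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ValueError(f"non-numeric cell at gene {row!r}, sample {col!r}")
        df = df.astype(float)
    elif format == "mtx_triplet":
        from scipy.io import mmread

        mat = mmread(path).toarray()
        stem = path.with_suffix("")
        genes = Path(f"{stem}.genes.txt").read_text().split()
        samples = Path(f"{stem}.samples.txt").read_text().split()
        df = pd.DataFrame(mat, index=genes, columns=samples)
        if df.shape[0] == 0:
            raise ValueError(f"no genes parsed from {path}")
    else:
        raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'mtx_triplet'")

    if meta_path is None:
        raise ValueError("meta_path is required")
    meta = _read_meta(meta_path)
    missing = [s for s in df.columns if s not in meta.index]
    if missing:
        raise ValueError(f"metadata missing for sample(s): {missing}")
    mat = ExpressionMatrix(df, meta.loc[list(df.columns)], unit=unit)
    log.info("read_expression: %d genes x %d samples from %s", df.shape[0], df.shape[1], path)
    return mat


def write_expression(mat: ExpressionMatrix, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        out = mat.values.copy()
        if mat.unit == "count":
            out = out.astype(int)
        out.to_csv(path, sep="\t", index_label="gene_id")
    elif format == "mtx_triplet":
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        mmwrite(str(path), csr_matrix(mat.values.to_numpy()))
        stem = path.with_suffix("")
        Path(f"{stem}.genes.txt").write_text("\n".join(mat.gene_ids) + "\n")
        Path(f"{stem}.samples.txt").write_text("\n".join(mat.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'mtx_triplet'")


def write_meta(mat: ExpressionMatrix, path: str | Path) -> None:
    mat.sample_meta.to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line — name, description, genes (tab-separated).

    Duplicate genes within a line are deduplicated with a logged warning; the
    description field is kept as the set's condition tag when non-empty.
    """
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: expected >=3 tab-separated fields")
            name, desc, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"GMT line {lineno}: gene set {name!r} has no genes")
            uniq = set(genes)
            if len(uniq) < len(genes):
                log.warning("GMT line %d: %d duplicate gene(s) removed from %s",
                            lineno, len(genes) - len(uniq), name)
            if name in coll.sets:
                raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
            coll.sets[name] = uniq
            if desc:
                coll.conditions[name] = desc
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in coll.names():
            desc = coll.conditions.get(name, ".")
            genes = sorted(coll.sets[name])
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_ranking_db(path: str | Path, window_label: str) -> RankingDatabase:
    """Read a motifs x genes rank table (TSV, first column motif ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0).astype(int)
    return RankingDatabase(window_label, df)


def write_ranking_db(db: RankingDatabase, path: str | Path) -> None:
    db.ranks.to_csv(path, sep="\t", index_label="motif_id")


def read_motif_annotation(path: str | Path) -> MotifAnnotation:
    """Two/three column TSV: motif_id, tf_id[, confidence]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    tfs: dict[str, set[str]] = {}
    conf: dict[str, str] = {}
    for row in df.itertuples(index=False):
        tfs.setdefault(row.motif_id, set()).add(row.tf_id)
        if hasattr(row, "confidence"):
            conf[row.motif_id] = row.confidence
    return MotifAnnotation(tfs, conf)


def write_motif_annotation(ann: MotifAnnotation, path: str | Path) -> None:
    rows = []
    for motif, tf_set in ann.tfs.items():
        for tf in sorted(tf_set):
            rows.append({"motif_id": motif, "tf_id": tf,
                         "confidence": ann.confidence.get(motif, "high")})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_network(net: RegulatoryNetwork, path: str | Path, format: str = "json") -> None:
    """Serialize a RegulatoryNetwork as graphml, edge_tsv or json.

    The json form is lossless (nodes, edges and modules round-trip exactly);
    edge_tsv carries edges only; graphml is for external graph tooling.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net.to_networkx(), path)
    elif format == "edge_tsv":
        df = pd.DataFrame(net.edges, columns=["source", "target", "sign", "provenance"])
        df.to_csv(path, sep="\t", index=False)
    elif format == "json":
        payload = {
            "nodes": net.nodes,
            "edges": net.edges,
            "modules": net.modules,
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    else:
        raise ValueError(f"unknown format {format!r}; supported: graphml, edge_tsv, json")


def read_network_json(path: str | Path) -> RegulatoryNetwork:
    payload = json.loads(Path(path).read_text())
    return RegulatoryNetwork(
        nodes=payload["nodes"],
        edges=payload["edges"],
        modules={k: int(v) for k, v in payload.get("modules", {}).items()},
    )


def read_target_dbs(paths: Iterable[str | Path]) -> list[dict[str, list[str]]]:
    """Read miRNA target databases: TSV columns mirna_id, gene_id, rank.

    Each database maps mirna -> ordered target list (rank 1 first).
    """
    dbs = []
    for p in paths:
        df = pd.read_csv(p, sep="\t", dtype={"mirna_id": str, "gene_id": str, "rank": int})
        db: dict[str, list[str]] = {}
        for mirna, grp in df.groupby("mirna_id", sort=False):
            ordered = grp.sort_values("rank")["gene_id"].tolist()
            if len(ordered) != len(set(ordered)):
                raise ValueError(f"duplicate target for miRNA {mirna} in {p}")
            db[str(mirna)] = ordered
        dbs.append(db)
    return dbs


def write_target_db(db: Mapping[str, list[str]], path: str | Path) -> None:
    rows = [
        {"mirna_id": m, "gene_id": g, "rank": i + 1}
        for m, targets in db.items()
        for i, g in enumerate(targets)
    ]
    pd.DataFrame(rows, columns=["mirna_id", "gene_id", "rank"]).to_csv(path, sep="\t", index=False)


def read_tf_mir_table(path: str | Path) -> pd.DataFrame:
    """Curated TF->miRNA edges: columns tf_id, mirna_id[, evidence]."""
    return pd.read_csv(path, sep="\t", dtype=str)


def read_terms_table(path: str | Path) -> pd.DataFrame:
    """Term->gene annotation: columns term_id, gene_id[, expected_direction]."""
    return pd.read_csv(path, sep="\t", dtype=str)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "de": {"alpha": 0.01, "lfc_min": 1.0, "min_median": 1.0, "moderation": True},
    "sc": {"max_mito_pct": 15.0, "min_genes": 500, "alpha": 0.05, "lfc_min": 0.25,
           "min_pct": 0.10, "mito_prefix": "MT-"},
    "motifs": {"max_rank_fraction": 0.05, "nes_min": 3.0},
    "regulons": {"min_targets": 5, "geneset_condition": "young"},
    "mirna": {"alpha": 0.01, "min_src": 2, "method": "geom"},
    "termnet": {"term_alpha": 0.001, "jaccard_max": 0.5},
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Layer a YAML config file and explicit overrides over package defaults.

    Overrides use ``{"section": {"key": value}}`` nesting; None values in the
    overrides are ignored so absent CLI flags do not clobber file values.
    """
    import copy

    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for section, values in user.items():
            cfg.setdefault(section, {}).update(values or {})
    for section, values in (overrides or {}).items():
        cfg.setdefault(section, {}).update(
            {k: v for k, v in (values or {}).items() if v is not None}
        )
    return cfg


def echo_config(cfg: dict, outdir: str | Path) -> None:
    """Write the effective config into the output directory for provenance."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config-echo.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
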