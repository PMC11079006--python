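"""Functional-term enrichment, redundancy pruning and term-gene networks.

Term enrichment is a hypergeometric overlap test of each term's annotated
genes against the differentially expressed set within a stated universe,
BH-adjusted across terms and filtered at a strict threshold (default
q < 0.001). Each retained term gets a sign-consistency activation z-score,
(consistent - inconsistent)/sqrt(total), comparing observed DE directions to
the term's expected per-gene directions. Highly redundant terms are pruned
greedily by Jaccard similarity of their annotated gene sets, the surviving
terms joined to their contributing DE genes in a bipartite network, and
communities extracted with a seeded modularity heuristic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core_io import RegulatoryNetwork
from .diffexpr import DEResult, bh_adjust

log = logging.getLogger("regage.termnet")


@dataclass
class TermResult:
    term_id: str
    annotated_genes: set[str]
    overlap_de: set[str]
    p: float
    q: float = np.nan
    z: float | None = None
    retained: bool = False
    expected_directions: dict[str, str] = field(default_factory=dict)


def term_enrichment(
    terms: dict[str, set[str]],
    de_genes: set[str],
    universe: set[str],
    term_alpha: float = 0.001,
    expected_directions: dict[str, dict[str, str]] | None = None,
) -> list[TermResult]:
    """Hypergeometric upper-tail enrichment of DE genes in each term.

    Terms are intersected with the universe first; terms disjoint from the
    universe are skipped with a warning. ``retained`` marks q < term_alpha.
    """
    if not universe:
        raise ValueError("empty universe")
    extra = de_genes - universe
    if extra:
        raise ValueError(f"DE genes outside the universe, e.g. {sorted(extra)[:5]}")
    n_univ = len(universe)
    n_de = len(de_genes)
    results: list[TermResult] = []
    for term_id in sorted(terms):
        annotated = terms[term_id] & universe
        if not annotated:
            log.warning("term_enrichment: term %s disjoint from universe; skipped", term_id)
            continue
        overlap = annotated & de_genes
        # P(X >= |overlap|) with X ~ Hypergeom(N=universe, K=DE, n=|term|)
        p = float(stats.hypergeom.sf(len(overlap) - 1, n_univ, n_de, len(annotated)))
        results.append(
            TermResult(term_id, annotated, overlap, p,
                       expected_directions=(expected_directions or {}).get(term_id, {}))
        )
    if results:
        q = bh_adjust([r.p for r in results])
        for r, qv in zip(results, q):
            r.q = float(qv)
            r.retained = bool(qv < term_alpha)
    n_ret = sum(r.retained for r in results)
    log.info("term_enrichment: %d/%d terms retained at q<%g", n_ret, len(results), term_alpha)
    return results


def activation_z(
    result: TermResult,
    de_directions: dict[str, str],
) -> float | None:
    """Sign-consistency activation score over the term's DE overlap.

    z = (n_consistent - n_inconsistent)/sqrt(n_total), where a gene is
    consistent when its observed DE direction equals the term's expected
    direction for it. Genes without an expectation are excluded; with no
    usable gene the score is undefined (None).
    """
    consistent = inconsistent = 0
    for gene in result.overlap_de:
        expected = result.expected_directions.get(gene)
        observed = de_directions.get(gene)
        if expected is None or observed in (None, "ns"):
            continue
        if observed == expected:
            consistent += 1
        else:
            inconsistent += 1
    total = consistent + inconsistent
    if total == 0:
        return None
    return (consistent - inconsistent) / np.sqrt(total)


def jaccard(a: set, b: set) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def prune_redundant(results: list[TermResult], jaccard_max: float = 0.5) -> list[TermResult]:
    """Greedy redundancy pruning by annotated-gene Jaccard similarity.

    Results are swept in order of ascending p (ties: larger |z|, then
    lexicographic id); a term is accepted iff its Jaccard with every
    previously accepted term is <= ``jaccard_max``. Idempotent.
    """
    def sort_key(r: TermResult):
        zmag = abs(r.z) if r.z is not None else 0.0
        return (r.p, -zmag, r.term_id)

    accepted: list[TermResult] = []
    for r in sorted(results, key=sort_key):
        if all(jaccard(r.annotated_genes, a.annotated_genes) <= jaccard_max for a in accepted):
            accepted.append(r)
    log.info("prune_redundant: %d -> %d terms (jaccard_max=%g)",
             len(results), len(accepted), jaccard_max)
    return accepted


def build_term_network(retained: list[TermResult], de: DEResult) -> RegulatoryNetwork:
    """Bipartite term-gene network over each term's DE overlap genes."""
    if not retained:
        raise ValueError("no retained terms to build a network from")
    net = RegulatoryNetwork()
    for r in retained:
        net.add_node(r.term_id, "term", "none",
                     q=r.q, z=(r.z if r.z is not None else "NA"))
        for g in sorted(r.overlap_de):
            net.add_node(g, "gene", de.direction_of(g))
            net.add_edge(r.term_id, g, "annotates", "term_enrichment")
    return net


def detect_modules(
    net: RegulatoryNetwork, seed: int, method: str = "modularity"
) -> tuple[dict[str, int], float]:
    """Seeded modularity-based community detection.

    Operates on the largest connected component; isolated nodes are assigned
    module 0 and components other than the largest take modules after the
    main partition. Returns (node -> module, modularity of the partition on
    the full graph). The partition's modularity is never below the
    all-singleton partition's (which is <= 0).
    """
    if method != "modularity":
        raise ValueError("only the 'modularity' method is implemented")
    g = net.to_networkx().to_undirected()
    if g.number_of_edges() == 0:
        raise ValueError("cannot detect modules in an edgeless network")
    components = sorted(nx.connected_components(g), key=len, reverse=True)
    largest = components[0]
    sub = g.subgraph(largest)
    communities = nx.community.louvain_communities(sub, seed=seed)
    communities = sorted((sorted(c) for c in communities), key=lambda c: (-len(c), c[0]))
    assignment: dict[str, int] = {}
    for i, comm in enumerate(communities, start=1):
        for node in comm:
            assignment[node] = i
    next_module = len(communities) + 1
    for comp in components[1:]:
        if len(comp) == 1:
            assignment[next(iter(comp))] = 0  # isolate
        else:
            for node in sorted(comp):
                assignment[node] = next_module
            next_module += 1
    partition_sets: dict[int, set] = {}
    for node, m in assignment.items():
        partition_sets.setdefault(m, set()).add(node)
    modularity = nx.community.modularity(g, partition_sets.values())
    singleton = nx.community.modularity(g, [{n} for n in g.nodes])
    if modularity < singleton:
        log.warning("detect_modules: partition below singleton modularity; using singletons")
        assignment = {n: i for i, n in enumerate(sorted(g.nodes), start=1)}
        modularity = singleton
    log.info("detect_modules: %d module(s), modularity %.4f",
             len(set(assignment.values()) - {0}), modularity)
    net.modules = assignment
    return assignment, float(modularity)
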