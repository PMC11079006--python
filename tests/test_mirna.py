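import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_expr, small_config
from regage import diffexpr
from regage.diffexpr import DEResult
from regage.mirna import (
    build_mir_networks,
    consensus_for_de,
    consensus_targets,
    mirna_de,
    target_summary,
)
from regage.regulon import TFRole
from regage.synthdata import SimulationConfig, simulate_bulk, simulate_mirna


def de_with(directions: dict[str, str], alpha=0.01) -> DEResult:
    genes = sorted(directions)
    lfc = {"up": 2.0, "down": -2.0, "ns": 0.0}
    table = pd.DataFrame(
        {
            "log2fc": [lfc[directions[g]] for g in genes],
            "se": 0.1, "statistic": 5.0, "df_total": 10.0, "p": 0.001,
            "q": [0.001 if directions[g] != "ns" else 0.9 for g in genes],
            "direction": [directions[g] for g in genes],
        },
        index=genes,
    )
    return DEResult(table, alpha, 0.0)


class TestMirnaDE:
    def test_planted_shifts_recovered(self, small_study):
        truth = small_study["truth"]
        de = mirna_de(small_study["mirna"])
        true = set(truth.mirna_truth)
        sig = de.significant()
        assert len(sig & true) / len(true) >= 0.9
        for m, rec in truth.mirna_truth.items():
            if m in sig:
                want = "up" if rec["condition"] == "aged" else "down"
                assert de.direction_of(m) == want

    def test_null_false_positive_rate(self):
        rng = np.random.default_rng(0)
        fps = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            vals = rng.normal(7, 0.3, size=(40, 8))
            mat = make_expr(vals, ["young"] * 4 + ["aged"] * 4, unit="log_intensity")
            de = mirna_de(mat)
            fps.append(len(de.significant()) / 40)
        assert np.mean(fps) <= 0.03

    def test_constant_row_is_ns(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(7, 0.3, size=(10, 8))
        vals[0] = 5.0
        mat = make_expr(vals, ["young"] * 4 + ["aged"] * 4, unit="log_intensity")
        de = mirna_de(mat)
        assert de.direction_of("g1") == "ns"

    def test_wrong_unit_rejected(self):
        mat = make_expr([[1, 2, 3, 4]], ["young", "young", "aged", "aged"])
        with pytest.raises(ValueError, match="log_intensity"):
            mirna_de(mat)


class TestConsensusTargets:
    DBS = [
        {"mir1": ["gA", "gB"]},
        {"mir1": ["gC", "gB", "gD"]},
        {"mir1": ["gD"]},
    ]

    def test_single_source_gene_excluded(self):
        ct = consensus_targets("mir1", self.DBS, min_src=2)
        assert "gA" not in ct.genes and "gC" not in ct.genes
        assert ct.genes == {"gB", "gD"}

    def test_geometric_mean_of_ranks(self):
        # gB: ranks 2 and 2 -> 2.0; gD: ranks 3 and 1 -> sqrt(3)
        ct = consensus_targets("mir1", self.DBS, min_src=2)
        rows = ct.table.set_index("gene")
        assert rows.loc["gB", "aggregate_rank"] == pytest.approx(2.0)
        assert rows.loc["gD", "aggregate_rank"] == pytest.approx(np.sqrt(3))

    def test_hand_geometric_means(self):
        dbs = [{"m": ["x", "y"]}, {"m": ["z", "x", "w", "v", "u", "t", "s", "y"]},
               {"m": ["y"]}]
        ct = consensus_targets("m", dbs, min_src=2)
        rows = ct.table.set_index("gene")
        # x: ranks {1, 2} -> sqrt(2); y: ranks {2, 8, 1} -> cube root of 16
        assert rows.loc["x", "aggregate_rank"] == pytest.approx(np.sqrt(2))
        assert rows.loc["y", "aggregate_rank"] == pytest.approx(16 ** (1 / 3))

    def test_forced_examples(self):
        # ranks {2, 8} -> geometric mean 4.0
        dbs = [{"m": ["a", "g"]}, {"m": [f"p{i}" for i in range(7)] + ["g"]}]
        ct = consensus_targets("m", dbs, min_src=2)
        assert ct.table.set_index("gene").loc["g", "aggregate_rank"] == pytest.approx(4.0)

    def test_sorted_by_aggregate_rank_with_lexicographic_ties(self):
        dbs = [{"m": ["b", "a"]}, {"m": ["a", "b"]}]
        ct = consensus_targets("m", dbs, min_src=2)
        # both genes have ranks {1,2}: tie broken lexicographically
        assert ct.table["gene"].tolist() == ["a", "b"]

    def test_invalid_min_src(self):
        with pytest.raises(ValueError, match="min_src"):
            consensus_targets("m", self.DBS, min_src=4)

    def test_database_order_invariance(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(30)]
        dbs = [
            {"m": list(rng.choice(genes, size=rng.integers(5, 20), replace=False))}
            for _ in range(5)
        ]
        base = consensus_targets("m", dbs).table
        for _ in range(5):
            order = rng.permutation(5)
            got = consensus_targets("m", [dbs[i] for i in order]).table
            assert got["gene"].tolist() == base["gene"].tolist()
            assert np.allclose(got["aggregate_rank"], base["aggregate_rank"])

    def test_matches_brute_force_oracle(self):
        """Full cross-tabulation of membership and rank geometric means."""
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(25)]
        for trial in range(30):
            n_db = int(rng.integers(2, 6))
            dbs = [
                {"m": list(rng.choice(genes, size=rng.integers(1, 20), replace=False))}
                for _ in range(n_db)
            ]
            min_src = int(rng.integers(1, n_db + 1))
            got = consensus_targets("m", dbs, min_src=min_src).table
            # oracle
            rows = {}
            for g in genes:
                ranks = [db["m"].index(g) + 1 for db in dbs if g in db["m"]]
                if len(ranks) >= min_src:
                    rows[g] = (len(ranks), float(np.prod(ranks) ** (1 / len(ranks))))
            expected = sorted(rows.items(), key=lambda kv: (round(kv[1][1], 9), kv[0]))
            assert got["gene"].tolist() == [g for g, _ in expected]
            for g, (n_src, agg) in expected:
                row = got.set_index("gene").loc[g]
                assert row["n_sources"] == n_src
                assert row["aggregate_rank"] == pytest.approx(agg, rel=1e-12)


class TestTargetSummary:
    def test_single_mirna_enumeration(self):
        mirna_result = de_with({"mir1": "down"})  # young-enriched
        gene_dirs = {f"g{i}": "up" for i in range(10)}  # aged-enriched genes
        gene_de = de_with(gene_dirs)
        from regage.mirna import ConsensusTargets

        table = pd.DataFrame(
            {"gene": ["g0", "g1", "g2"], "n_sources": 2, "aggregate_rank": 1.0,
             "source_ranks": [{}] * 3}
        )
        summary = target_summary(mirna_result, {"mir1": ConsensusTargets("mir1", table)},
                                 gene_de)
        assert summary["young"]["mean_targets"] == 3
        assert summary["young"]["sd_targets"] == 0.0
        assert summary["young"]["sd_undefined"]
        assert summary["young"]["coverage_fraction"] == pytest.approx(0.3)

    def test_duplicate_target_sets_leave_coverage_unchanged(self):
        from regage.mirna import ConsensusTargets

        table = pd.DataFrame(
            {"gene": ["g0", "g1"], "n_sources": 2, "aggregate_rank": 1.0,
             "source_ranks": [{}] * 2}
        )
        gene_de = de_with({f"g{i}": "up" for i in range(10)})
        one = target_summary(
            de_with({"mir1": "down"}),
            {"mir1": ConsensusTargets("mir1", table)}, gene_de,
        )
        two = target_summary(
            de_with({"mir1": "down", "mir2": "down"}),
            {"mir1": ConsensusTargets("mir1", table),
             "mir2": ConsensusTargets("mir2", table.copy())}, gene_de,
        )
        assert one["young"]["coverage_fraction"] == two["young"]["coverage_fraction"]

    def test_consensus_retention_matches_binomial_closed_form(self):
        """Observed mean consensus targets per DE miRNA within 3 SE of the
        >= 2-of-5 binomial retention expectation at db_recall 0.7."""
        cfg = SimulationConfig(n_mirnas=75, db_recall=0.7, seed=3)
        _, truth = simulate_bulk(cfg)
        _, dbs, _, ledger = simulate_mirna(truth, cfg)
        de_mirnas = sorted(ledger.mirna_truth)
        assert len(de_mirnas) == 50
        counts = [len(consensus_targets(m, dbs, min_src=2).genes) for m in de_mirnas]
        n_true = cfg.targets_per_mirna
        p_keep = 1 - stats.binom.cdf(1, cfg.n_target_dbs, cfg.db_recall)
        # decoys: each non-target gene enters a db's decoy list uniformly
        p_decoy = cfg.decoy_targets_per_db / (cfg.n_genes - n_true)
        e_decoy = (cfg.n_genes - n_true) * (
            1 - stats.binom.cdf(1, cfg.n_target_dbs, p_decoy)
        )
        expected = n_true * p_keep + e_decoy
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) <= 3 * se


class TestBuildMirNetworks:
    def _setup(self):
        mirna_result = de_with({"mir1": "down", "mir2": "up", "mir3": "ns"})
        gene_de = de_with({"gU": "up", "gD": "down", "TF1": "up", "gN": "ns"})
        from regage.mirna import ConsensusTargets

        def ct(mid, genes):
            return ConsensusTargets(mid, pd.DataFrame(
                {"gene": genes, "n_sources": 2, "aggregate_rank": 1.0,
                 "source_ranks": [{}] * len(genes)}))

        consensus = {"mir1": ct("mir1", ["gU", "gD"]), "mir2": ct("mir2", ["gU", "gD"])}
        return mirna_result, gene_de, consensus

    def test_opposite_condition_rule(self):
        mirna_result, gene_de, consensus = self._setup()
        tf_mir = pd.DataFrame(columns=["tf_id", "mirna_id", "evidence"])
        net, _ = build_mir_networks(mirna_result, gene_de, consensus, tf_mir, gene_de)
        pairs = {(e["source"], e["target"]) for e in net.edges}
        # mir1 young-enriched -> targets aged-enriched genes only
        assert ("mir1", "gU") in pairs and ("mir1", "gD") not in pairs
        # mir2 aged-enriched -> targets young-enriched genes only
        assert ("mir2", "gD") in pairs and ("mir2", "gU") not in pairs

    def test_curated_edges_require_de_on_both_ends(self):
        mirna_result, gene_de, consensus = self._setup()
        tf_mir = pd.DataFrame(
            {"tf_id": ["TF1", "TF1", "gN"], "mirna_id": ["mir1", "mir3", "mir2"],
             "evidence": "x"}
        )
        net, per_tf = build_mir_networks(
            mirna_result, gene_de, consensus, tf_mir, gene_de,
            roles=[TFRole("TF1", "repressor")],
        )
        curated = [(e["source"], e["target"]) for e in net.edges
                   if e["provenance"] == "curated_tf_mirna"]
        assert curated == [("TF1", "mir1")]  # non-DE miRNA and non-DE TF dropped
        assert per_tf.to_dict() == {"TF1": 1}

    def test_planted_tf_mirna_edges_recovered(self, small_study):
        truth = small_study["truth"]
        mirna_result = mirna_de(small_study["mirna"])
        gene_de = diffexpr.run_de(small_study["bulk"])
        consensus = consensus_for_de(mirna_result, small_study["target_dbs"])
        net, _ = build_mir_networks(
            mirna_result, gene_de, consensus, small_study["tf_mir"], gene_de,
        )
        curated = {(e["source"], e["target"]) for e in net.edges
                   if e["provenance"] == "curated_tf_mirna"}
        planted = {(e["tf_id"], e["mirna_id"]) for e in truth.tf_mirna_edges}
        decoys = {(str(r.tf_id), str(r.mirna_id))
                  for r in small_study["tf_mir"].itertuples(index=False)} - planted
        assert planted <= curated
        assert not (decoys & curated)
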