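import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_expr, small_config
from regage import diffexpr
from regage.diffexpr import (
    DEResult,
    ModerationFit,
    abundance_filter,
    bh_adjust,
    fit_gene_models,
    intersect_concordant,
    moderate_variances,
    posterior_variance,
    sc_de,
    sc_filter_cells,
    size_factors,
)
from regage.diffexpr import test_de as run_test_de
from regage.synthdata import SimulationConfig, simulate_bulk, simulate_cells


class TestSizeFactors:
    def test_identical_samples_equal_factors(self):
        mat = make_expr([[10, 10], [4, 4]], ["young", "aged"])
        f = size_factors(mat)
        assert np.allclose(f, [1.0, 1.0])

    def test_doubled_sample_gives_sqrt2_factors(self):
        # sample2 = 2 x sample1: geometric-mean reference c*sqrt(2)
        mat = make_expr([[10, 20], [4, 8], [100, 200]], ["young", "aged"])
        f = size_factors(mat)
        assert np.allclose(f, [1 / np.sqrt(2), np.sqrt(2)], atol=1e-6)

    def test_single_sample_factor_one(self):
        mat = make_expr([[5], [7]], ["young"])
        assert np.allclose(size_factors(mat), [1.0])

    def test_no_eligible_gene_advises_fallback(self):
        mat = make_expr([[0, 5], [3, 0]], ["young", "aged"])
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(mat)


class TestFitGeneModels:
    def test_two_group_coef_is_difference_of_log_means(self):
        vals = np.array([[8, 16, 32, 64, 128, 256]], dtype=float)
        mat = make_expr(vals, ["young"] * 3 + ["aged"] * 3, unit="tpm")
        models = fit_gene_models(mat)
        y = np.log2(vals + 0.5)
        expected = y[0, 3:].mean() - y[0, :3].mean()
        assert models["coef"].iloc[0] == pytest.approx(expected, abs=1e-12)
        assert models["df"].iloc[0] == 4

    def test_orthogonal_batch_leaves_coef_unchanged(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(3, 1, size=(20, 8))
        cond = ["young"] * 4 + ["aged"] * 4
        no_batch = make_expr(vals, cond, ["b1"] * 8, unit="tpm")
        batched = make_expr(vals, cond, ["b1", "b2"] * 4, unit="tpm")  # balanced
        m0 = fit_gene_models(no_batch)
        m1 = fit_gene_models(batched)
        assert np.allclose(m0["coef"], m1["coef"], atol=1e-10)

    def test_saturated_design_errors(self):
        mat = make_expr([[1, 2]], ["young", "aged"], unit="tpm")
        with pytest.raises(ValueError, match="zero residual df"):
            fit_gene_models(mat)

    def test_confounded_batch_errors(self):
        mat = make_expr([[1, 2, 3, 4]], ["young", "young", "aged", "aged"],
                        ["b1", "b1", "b2", "b2"], unit="tpm")
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_gene_models(mat)


class TestModeration:
    def test_posterior_formula(self):
        # (d0*s0 + df*s^2)/(d0+df) = (4*1 + 4*4)/8 = 2.5
        fit = ModerationFit(4.0, 1.0, np.array([]))
        assert posterior_variance(fit, np.array([4.0]), np.array([4.0]))[0] == 2.5

    def test_d0_zero_is_ordinary_variance(self):
        fit = ModerationFit(0.0, 99.0, np.array([]))
        s = np.array([1.0, 2.0, 3.0])
        assert np.array_equal(posterior_variance(fit, s, np.full(3, 4.0)), s)

    def test_equal_variances_hit_infinity_branch(self):
        fit = moderate_variances(np.full(50, 2.0), np.full(50, 6.0))
        assert np.isinf(fit.d0)
        assert fit.s0_sq == pytest.approx(2.0)
        assert np.allclose(fit.posterior_s_sq, 2.0)

    def test_recovers_prior_from_simulated_scaled_f(self):
        # s^2 ~ s0^2 * F(df, d0): the moment-matched d0 should land near truth
        rng = np.random.default_rng(1)
        d0, s0, df = 8.0, 1.5, 6.0
        n = 20000
        s_sq = s0 * (rng.chisquare(df, n) / df) / (rng.chisquare(d0, n) / d0)
        fit = moderate_variances(s_sq, np.full(n, df))
        assert fit.d0 == pytest.approx(d0, rel=0.15)
        assert fit.s0_sq == pytest.approx(s0, rel=0.1)

    def test_moderated_t_limits(self):
        rng = np.random.default_rng(2)
        models = pd.DataFrame(
            {
                "coef": rng.normal(0, 1, 30),
                "se_unit": 0.5,
                "s_sq": rng.chisquare(4, 30) / 4,
                "df": 4.0,
            },
            index=[f"g{i}" for i in range(30)],
        )
        # d0 = 0: ordinary t
        de0 = run_test_de(models, ModerationFit(0.0, 1.0, models["s_sq"].to_numpy()))
        t_ord = models["coef"] / (np.sqrt(models["s_sq"]) * 0.5)
        assert np.allclose(de0.table["statistic"], t_ord, atol=1e-12)
        # d0 = inf: z statistic at the common prior variance
        de_inf = run_test_de(models, ModerationFit(np.inf, 2.0, models["s_sq"].to_numpy()))
        assert np.allclose(de_inf.table["statistic"],
                           models["coef"] / (np.sqrt(2.0) * 0.5), atol=1e-12)


class TestBHAdjust:
    def test_hand_step_up(self):
        q = bh_adjust([0.01, 0.04, 0.03, 0.005])
        assert np.allclose(q, [0.02, 0.04, 0.04, 0.02])

    def test_degenerate_inputs(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 200))
            expected = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_adjust(p), expected, atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40), st.randoms())
    def test_permutation_equivariance(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        q = bh_adjust(p)
        q_perm = bh_adjust([p[i] for i in perm])
        assert np.allclose([q[i] for i in perm], q_perm, atol=1e-12)


class TestTestDE:
    def test_zero_effect_gene_is_ns(self):
        models = pd.DataFrame(
            {"coef": [0.0, 3.0], "se_unit": 0.5, "s_sq": [1.0, 1.0], "df": 4.0},
            index=["null_gene", "big_gene"],
        )
        de = run_test_de(models, None, alpha=0.05, lfc_min=1.0)
        assert de.direction_of("null_gene") == "ns"

    def test_threshold_relaxation_is_monotone(self, default_study):
        mat = default_study["bulk"]
        models = fit_gene_models(mat)
        fit = moderate_variances(models["s_sq"].to_numpy(), models["df"].to_numpy())
        strict = run_test_de(models, fit, alpha=0.01, lfc_min=1.0)
        loose = run_test_de(models, fit, alpha=0.05, lfc_min=0.0)
        assert strict.significant() <= loose.significant()

    def test_planted_sensitivity_and_fdr(self, default_study):
        """Planted effects (2.0 log2, 8 vs 3) recovered at the stated thresholds."""
        truth = default_study["truth"]
        de = diffexpr.run_de(default_study["bulk"])
        true = set(truth.de_genes)
        sig = de.significant()
        tp = len(sig & true)
        assert tp / len(true) >= 0.9
        assert (len(sig) - tp) / max(1, len(sig)) <= 0.05
        # planted signs are recovered
        for g in sig & true:
            want = "up" if truth.de_genes[g]["true_log2fc"] > 0 else "down"
            assert de.direction_of(g) == want


class TestAbundanceFilter:
    def _de(self, genes):
        table = pd.DataFrame(
            {"log2fc": 2.0, "se": 0.1, "statistic": 5.0, "df_total": 10.0,
             "p": 0.001, "q": 0.001, "direction": "up"},
            index=genes,
        )
        return DEResult(table, 0.01, 1.0)

    def test_boundary_and_rules(self):
        # medians per gene: (0.5, 0.9) removed; (0.0, 1.0) kept (floor inclusive)
        tpm = make_expr(
            [[0.5, 0.5, 0.9, 0.9], [0.0, 0.0, 1.0, 1.0]],
            ["young", "young", "aged", "aged"],
            unit="tpm",
        )
        de = self._de(["g1", "g2"])
        kept = abundance_filter(de, tpm, min_median=1.0)
        assert set(kept.table.index) == {"g2"}

    def test_zero_floor_is_identity(self):
        tpm = make_expr([[0.1, 0.2], [5, 6]], ["young", "aged"], unit="tpm")
        de = self._de(["g1", "g2"])
        kept = abundance_filter(de, tpm, min_median=0.0)
        assert set(kept.table.index) == {"g1", "g2"}


class TestIntersectConcordant:
    def _de(self, up, down):
        genes = sorted(up | down)
        table = pd.DataFrame(
            {"log2fc": [2.0 if g in up else -2.0 for g in genes],
             "se": 0.1, "statistic": 5.0, "df_total": 10.0, "p": 0.001, "q": 0.001,
             "direction": ["up" if g in up else "down" for g in genes]},
            index=genes,
        )
        return DEResult(table, 0.01, 1.0)

    def test_identical_inputs_fully_concordant(self):
        a = self._de({"g1"}, {"g2"})
        res = intersect_concordant(a, a)
        assert res.concordance_fraction == 1.0
        assert res.shared_genes == {"g1", "g2"}

    def test_hand_enumeration(self):
        a = self._de({"g1", "g2"}, {"g3"})
        b = self._de({"g1"}, {"g2", "g3"})
        res = intersect_concordant(a, b)
        assert res.shared_genes == {"g1", "g2", "g3"}
        assert res.concordant_genes == {"g1", "g3"}
        assert res.discordant_genes == {"g2"}
        assert res.concordance_fraction == pytest.approx(2 / 3)

    def test_disjoint_sets_flagged(self):
        res = intersect_concordant(self._de({"g1"}, set()), self._de({"g2"}, set()))
        assert res.empty_flag
        assert res.concordance_fraction == 1.0


class TestSCFilter:
    def _cells(self, counts, genes):
        n = np.asarray(counts).shape[1]
        return make_expr(counts, ["control"] * n, unit="count", genes=genes)

    def test_boundary_cell_is_kept(self):
        # exactly 15% mito and exactly min_genes detected: both filters strict
        genes = ["MT-1", "g1", "g2"]
        cells = self._cells([[15, 16], [45, 84], [40, 0]], genes)
        kept = sc_filter_cells(cells, max_mito_pct=15, min_genes=3)
        # s1: mito 15/100 = 15% (kept), 3 genes (kept); s2: 16% mito -> removed
        assert kept.sample_ids == ["s1"]

    def test_low_gene_count_removed(self):
        genes = ["MT-1", "g1", "g2"]
        cells = self._cells([[1, 1], [50, 50], [49, 0]], genes)
        kept = sc_filter_cells(cells, max_mito_pct=50, min_genes=3)
        assert kept.sample_ids == ["s1"]

    def test_no_mito_genes_skips_filter(self):
        cells = self._cells([[50, 50], [50, 50]], ["g1", "g2"])
        kept = sc_filter_cells(cells, max_mito_pct=1, min_genes=1)
        assert kept.sample_ids == ["s1", "s2"]

    def test_planted_low_quality_cells_exactly_removed(self, small_study):
        cells = small_study["cells"]
        truth = small_study["truth"]
        cfg = small_study["config"]
        kept = sc_filter_cells(cells, max_mito_pct=cfg.sc_max_mito_pct,
                               min_genes=cfg.sc_min_genes)
        removed = set(cells.sample_ids) - set(kept.sample_ids)
        assert removed == set(truth.low_quality_cells)


class TestSCDE:
    def test_expression_floor_excludes_rare_genes(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(5, size=(3, 40))
        counts[0] = 0
        counts[0, [0, 20]] = 3  # 5% detection in both groups
        cells = make_expr(counts, ["control"] * 20 + ["tf_active"] * 20)
        de = sc_de(cells, ("control", "tf_active"))
        assert "g1" not in de.table.index

    def test_small_group_rejected(self):
        cells = make_expr(np.ones((5, 4), dtype=int), ["control"] * 2 + ["tf_active"] * 2)
        with pytest.raises(ValueError, match=">= 3 cells"):
            sc_de(cells, ("control", "tf_active"))

    def test_label_permutation_null_is_calibrated(self, small_study):
        """Splitting one homogeneous group at random yields ~uniform p-values."""
        cells = small_study["cells"]
        ctrl = [s for s, c in cells.conditions().items() if c == "control"]
        sub = cells.subset_samples(ctrl)
        rng = np.random.default_rng(0)
        fracs = []
        for _ in range(5):
            labels = rng.permutation(["a"] * (len(ctrl) // 2)
                                     + ["b"] * (len(ctrl) - len(ctrl) // 2))
            sub2 = sub.subset_samples(ctrl)
            sub2.sample_meta = sub2.sample_meta.copy()
            sub2.sample_meta["condition"] = labels
            de = sc_de(sub2, ("a", "b"))
            fracs.append((de.table["p"] < 0.05).mean())
        assert np.mean(fracs) <= 0.07

    def test_planted_targets_recovered_as_repressed(self, default_study):
        truth = default_study["truth"]
        cells = sc_filter_cells(default_study["cells"])
        de = sc_de(cells, ("control", "tf_active"))
        targets = truth.targets_of(truth.regulons[0]["tf_id"])
        tested = targets & set(de.table.index)
        down = de.down
        assert len(tested & down) / len(targets) >= 0.8


class TestNullCalibration:
    def test_null_fdr_controlled_across_seeds(self):
        """With no planted effects, q<0.01 discoveries are rare (FDR <= 0.03)."""
        fdrs = []
        for seed in range(40):
            cfg = SimulationConfig(
                n_genes=250, n_regulons=0, regulon_roles=[],
                n_background_de_genes=0, seed=seed,
            )
            mat, _ = simulate_bulk(cfg)
            de = diffexpr.run_de(mat, alpha=0.01, lfc_min=0.0)
            n_disc = len(de.significant())
            fdrs.append(1.0 if n_disc > 0 else 0.0)
        assert np.mean(fdrs) <= 0.03
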