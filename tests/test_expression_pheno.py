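import numpy as np
import pandas as pd
import pytest

from enhancerscape.expression_pheno import (
    ExpressionMatrix,
    TraitRecord,
    de_filter,
    fpkm,
    gene_trait_network,
    load_diet_composition,
    load_rnaseq_qc,
    pheno_formulas,
    qc_summary,
    round2,
    venn_intersect,
)


def expr_matrix(counts: dict, lengths, mapped):
    df = pd.DataFrame(counts)
    df.index = [f"g{i}" for i in range(len(df))]
    return ExpressionMatrix(
        df, pd.Series(lengths, index=df.index), pd.Series(mapped, index=df.columns)
    )


class TestFpkm:
    def test_unit_case(self):
        em = expr_matrix({"s": [100]}, [1000], {"s": 1_000_000})
        assert fpkm(em).iloc[0, 0] == pytest.approx(100.0)

    def test_direct_arithmetic(self):
        em = expr_matrix({"s": [50]}, [2000], {"s": 10_000_000})
        assert fpkm(em).iloc[0, 0] == pytest.approx(2.5)

    def test_doubling_depth_halves_fpkm(self):
        em1 = expr_matrix({"s": [30]}, [500], {"s": 1_000_000})
        em2 = expr_matrix({"s": [30]}, [500], {"s": 2_000_000})
        assert fpkm(em2).iloc[0, 0] == pytest.approx(fpkm(em1).iloc[0, 0] / 2)


class TestDeFilter:
    def _fpkm(self, a_vals, b_vals):
        data = {f"L{i+1}": [v] for i, v in enumerate(a_vals)}
        data.update({f"H{i+1}": [v] for i, v in enumerate(b_vals)})
        return pd.DataFrame(data, index=["g0"])

    def test_identical_groups_do_not_pass(self):
        mat = self._fpkm([10, 10, 10], [10, 10, 10])
        groups = {"L": ["L1", "L2", "L3"], "H": ["H1", "H2", "H3"]}
        (rec,) = de_filter(mat, groups, "HvsL")
        assert rec.log2fc == 0 and not rec.passes

    def test_strong_shift_passes_with_expected_log2fc(self):
        mat = self._fpkm([10, 10.2, 9.8], [80, 80.5, 79.5])
        groups = {"L": ["L1", "L2", "L3"], "H": ["H1", "H2", "H3"]}
        (rec,) = de_filter(mat, groups, "HvsL")
        assert rec.log2fc == pytest.approx(np.log2(81 / 11), abs=0.01)
        assert rec.passes

    def test_genes_with_missing_values_excluded(self):
        mat = pd.DataFrame(
            {"L1": [1.0, np.nan], "L2": [2.0, 5.0], "H1": [9.0, 7.0], "H2": [8.0, 6.0]},
            index=["keep", "drop"],
        )
        groups = {"L": ["L1", "L2"], "H": ["H1", "H2"]}
        recs = de_filter(mat, groups, "HvsL")
        assert [r.gene_id for r in recs] == ["keep"]

    def test_small_group_rejected(self):
        mat = self._fpkm([10, 10, 10], [20, 20, 20])
        with pytest.raises(ValueError):
            de_filter(mat, {"L": ["L1"], "H": ["H1", "H2"]}, "HvsL")

    def test_label_permuted_null_pass_rate(self):
        """On exchangeable data the DE pass rate stays near the alpha level."""
        passes, total = 0, 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            mat = pd.DataFrame(
                rng.lognormal(3, 0.3, size=(200, 6)),
                index=[f"g{i}" for i in range(200)],
                columns=["a", "b", "c", "d", "e", "f"],
            )
            groups = {"L": ["a", "b", "c"], "H": ["d", "e", "f"]}
            recs = de_filter(mat, groups, "HvsL")
            passes += sum(r.passes for r in recs)
            total += len(recs)
        assert passes / total <= 0.07


class TestVenn:
    def test_small_example(self):
        regions, common = venn_intersect({"a", "b"}, {"b", "c"}, {"b"})
        assert common == {"b"}
        assert sum(regions.values()) == 3

    def test_disjoint(self):
        regions, common = venn_intersect({"a"}, {"b"}, {"c"})
        assert common == set()
        assert sum(regions.values()) == 3

    def test_identical_sets_all_in_triple_region(self):
        regions, common = venn_intersect({"a", "b"}, {"a", "b"}, {"a", "b"})
        assert regions["all_three"] == 2 and common == {"a", "b"}

    def test_partition_property(self, rng):
        pool = [f"g{i}" for i in range(50)]
        sets = [set(rng.choice(pool, 20, replace=False)) for _ in range(3)]
        regions, _ = venn_intersect(*sets)
        assert sum(regions.values()) == len(set().union(*sets))


class TestQcSummary:
    def test_printed_table_reproduces_stated_averages(self):
        summary = qc_summary(load_rnaseq_qc())
        assert summary.loc["raw_reads", "mean"] == 47.78
        assert summary.loc["q20", "mean"] == 97.99
        assert summary.loc["q30", "mean"] == 94.12
        assert summary.loc["gc", "mean"] == 54.24
        assert summary.loc["q20", "min"] == 97.41
        assert summary.loc["q20", "max"] == 98.41

    def test_single_record(self):
        (rec,) = load_rnaseq_qc()[:1]
        summary = qc_summary([rec])
        assert summary.loc["gc", "mean"] == round2(rec.gc)

    def test_rounding_is_half_up(self):
        assert round2(1.005) == 1.01
        assert round2(2.675) == 2.68


class TestPhenoFormulas:
    def test_dressing_percentage(self):
        out = pheno_formulas(TraitRecord("s", live_weight=30, carcass_weight=15))
        assert out["dressing_pct"] == pytest.approx(50.0)

    def test_thaw_and_cook_loss(self):
        out = pheno_formulas(
            TraitRecord(
                "s",
                pre_freeze_weight=100,
                post_thaw_weight=95,
                pre_cook_weight=95,
                post_cook_weight=76,
            )
        )
        assert out["thaw_loss_pct"] == pytest.approx(5.0)
        assert out["cook_loss_pct"] == pytest.approx(20.0)

    def test_diet_table_ratios(self):
        comp = load_diet_composition()
        nfc = comp.loc["non_fiber_carbohydrates_pct"]
        ndf = comp.loc["neutral_detergent_fiber_pct"]
        ratios = [
            pheno_formulas(TraitRecord("x", nfc_pct=nfc[g], ndf_pct=ndf[g]))["nfc_ndf_ratio"]
            for g in ("L", "M", "H")
        ]
        assert ratios == [0.71, 1.16, 1.82]

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError):
            pheno_formulas(TraitRecord("s", live_weight=0, carcass_weight=1))


class TestGeneTraitNetwork:
    def test_monotone_noise_free_trait_has_unit_rho(self):
        expr = pd.DataFrame([[1.0, 5.0, 2.0, 9.0, 4.0]], index=["g"],
                            columns=[f"s{i}" for i in range(5)])
        traits = pd.DataFrame(
            {"t": np.exp(expr.loc["g"])}, index=expr.columns
        )
        edges, _ = gene_trait_network(expr, traits, alpha=0.5)
        assert edges and edges[0].rho == pytest.approx(1.0)

    def test_hand_computed_rank_formula(self):
        # x=(1..5), y=(2,1,4,3,5): d=(-1,1,-1,1,0), Sum d^2=4
        # rho = 1 - 6*4/(5*24) = 0.8
        expr = pd.DataFrame([[1, 2, 3, 4, 5]], index=["g"],
                            columns=[f"s{i}" for i in range(5)], dtype=float)
        traits = pd.DataFrame({"t": [2.0, 1.0, 4.0, 3.0, 5.0]}, index=expr.columns)
        edges, _ = gene_trait_network(expr, traits, alpha=1.1)
        assert edges[0].rho == pytest.approx(0.8)

    def test_exact_permutation_p_matches_enumeration(self):
        from itertools import permutations

        expr = pd.DataFrame([[1, 2, 3, 4, 5]], index=["g"],
                            columns=[f"s{i}" for i in range(5)], dtype=float)
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        traits = pd.DataFrame({"t": y}, index=expr.columns)
        edges, _ = gene_trait_network(expr, traits, alpha=1.1)
        obs = 0.8
        count = 0
        ranks = np.array(y).argsort().argsort() + 1.0
        rx = np.arange(1, 6.0)
        for perm in permutations(ranks):
            r = np.corrcoef(rx, perm)[0, 1]
            if abs(r) >= obs - 1e-12:
                count += 1
        assert edges[0].pvalue == pytest.approx(count / 120)

    def test_independent_pairs_false_edge_rate(self):
        rng = np.random.default_rng(8)
        expr = pd.DataFrame(
            rng.normal(size=(20, 9)), index=[f"g{i}" for i in range(20)],
            columns=[f"s{i}" for i in range(9)],
        )
        traits = pd.DataFrame(
            rng.normal(size=(9, 5)), index=expr.columns,
            columns=[f"t{i}" for i in range(5)],
        )
        edges, _ = gene_trait_network(expr, traits, alpha=0.05)
        assert len(edges) <= 0.05 * 100

    def test_zero_variance_vector_omitted_with_warning(self):
        expr = pd.DataFrame([[1.0, 1.0, 1.0, 1.0]], index=["g"],
                            columns=[f"s{i}" for i in range(4)])
        traits = pd.DataFrame({"t": [1.0, 2.0, 3.0, 4.0]}, index=expr.columns)
        with pytest.warns(RuntimeWarning):
            edges, _ = gene_trait_network(expr, traits)
        assert edges == []

    def test_trait_trait_matrix_is_pearson(self):
        rng = np.random.default_rng(9)
        expr = pd.DataFrame(rng.normal(size=(2, 6)), index=["g1", "g2"],
                            columns=[f"s{i}" for i in range(6)])
        traits = pd.DataFrame(rng.normal(size=(6, 3)), index=expr.columns,
                              columns=["a", "b", "c"])
        _, tt = gene_trait_network(expr, traits)
        assert np.allclose(tt, np.corrcoef(traits.T))
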