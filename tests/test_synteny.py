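"""Synteny classification, trend test, and per-class expression ratios."""

import itertools

import numpy as np
import pytest
from scipy import stats

import armshuffle as ash
from armshuffle.synteny import CLASSES
from armshuffle.synthetic import TABLE1_COUNTS
from conftest import make_gene


class TestClassifySynteny:
    @pytest.mark.parametrize(
        "left,right,expected",
        [
            (True, True, "singleton"),
            (True, False, "unisyntenic"),
            (False, True, "unisyntenic"),
            (False, False, "bisyntenic"),
        ],
    )
    def test_plain_flank_rules(self, left, right, expected):
        g = make_gene("g", left_ch=left, right_ch=right)
        assert ash.classify_synteny(g, "OLC") == expected

    def test_nested_gene_is_always_bisyntenic(self):
        host = make_gene("h", left_ch=True, right_ch=True)
        g = make_gene("g", left_ch=True, right_ch=True, nested_in="h")
        from armshuffle.genome_model import link_nesting

        link_nesting([host, g])
        assert ash.classify_synteny(g, "OLC") == "bisyntenic"
        # the host, with both flanks changed, is demoted to unisyntenic
        assert ash.classify_synteny(host, "OLC") == "unisyntenic"

    def test_host_with_one_changed_flank_keeps_plain_rule(self):
        host = make_gene("h", left_ch=True, right_ch=False)
        g = make_gene("g", nested_in="h")
        from armshuffle.genome_model import link_nesting

        link_nesting([host, g])
        assert ash.classify_synteny(host, "OLC") == "unisyntenic"

    def test_nested_host_gene_is_bisyntenic(self):
        # a gene that both is nested and hosts others: the nested rule wins
        a = make_gene("a", left_ch=True, right_ch=True)
        b = make_gene("b", left_ch=True, right_ch=True, nested_in="a")
        c = make_gene("c", nested_in="b")
        from armshuffle.genome_model import link_nesting

        link_nesting([a, b, c])
        assert ash.classify_synteny(b, "OLC") == "bisyntenic"

    def test_total_and_exclusive(self, small_bundle):
        for g in small_bundle.genes:
            assert ash.classify_synteny(g, "OLC") in CLASSES

    def test_missing_flags_error(self):
        g = make_gene("g")
        with pytest.raises(KeyError, match="GO"):
            ash.classify_synteny(g, "GO")


class TestClassTagTable:
    def test_published_fixture_counts_reproduced(self):
        genes = ash.make_table1_fixture("OLC")
        t = ash.build_class_tag_table(genes, "OLC")
        assert t.counts.tolist() == [[32, 47], [230, 408], [295, 1336]]
        assert (t.No, t.Nt) == (557, 1791)

    def test_fixture_column_sums(self):
        genes = ash.make_table1_fixture("GOO")
        t = ash.build_class_tag_table(genes, "GOO")
        assert (t.No, t.Nt) == (551, 1717)

    def test_untagged_variant_gives_zero_table(self):
        genes = ash.make_table1_fixture("OLC", tagged=False)
        t = ash.build_class_tag_table(genes, "OLC")
        assert t.counts.sum() == 0

    def test_no_tagged_genes(self):
        genes = [make_gene(f"g{i}") for i in range(4)]
        assert ash.build_class_tag_table(genes, "OLC").counts.sum() == 0

    def test_permuting_tags_preserves_column_totals(self, small_bundle, rng):
        genes = small_bundle.genes
        before = ash.build_class_tag_table(genes, "OLC")
        new_tags = ash.permute_tags_within_arms(genes, rng)
        after = ash.build_class_tag_table(
            genes, "OLC", tags={g.id: t for g, t in zip(genes, new_tags)}
        )
        assert (after.No, after.Nt) == (before.No, before.Nt)
        assert after.counts.tolist() != before.counts.tolist()  # rows move


class TestTrendChiSquare:
    @pytest.mark.parametrize(
        "definition,expected",
        [("OLC", 89.35), ("GO", 73.13), ("GOO", 22.56)],
    )
    def test_published_values_reproduced(self, definition, expected):
        res = ash.trend_chi_square(np.array(TABLE1_COUNTS[definition]))
        assert res.chi_square == pytest.approx(expected, abs=0.01)
        assert res.degrees_of_freedom == 1
        assert res.p_value < 1e-4

    def test_constant_proportion_gives_zero(self):
        res = ash.trend_chi_square(np.array([[10, 20], [20, 40], [5, 10]]))
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)

    def test_affine_score_invariance(self):
        table = np.array(TABLE1_COUNTS["OLC"])
        a = ash.trend_chi_square(table, scores=(0, 1, 2))
        b = ash.trend_chi_square(table, scores=(10, 20, 30))
        assert b.chi_square == pytest.approx(a.chi_square, rel=1e-12)

    def test_two_row_table_reduces_to_pearson(self):
        table = np.array([[12, 30], [45, 9]])
        ours = ash.trend_chi_square(table, scores=(0, 1))
        pearson = stats.chi2_contingency(table, correction=False)
        assert ours.chi_square == pytest.approx(pearson.statistic, rel=1e-12)
        assert ours.p_value == pytest.approx(pearson.pvalue, rel=1e-9)

    def test_linear_by_linear_cross_check(self):
        # statsmodels' ordinal-association z-score squared is the
        # linear-by-linear chi-square (N-1) * r^2, while the trend
        # chi-square is N * r^2: they must agree after rescaling.
        sm = pytest.importorskip("statsmodels.api")
        for d in TABLE1_COUNTS:
            table = np.array(TABLE1_COUNTS[d])
            N = table.sum()
            lbl = sm.stats.Table(table).test_ordinal_association()
            ours = ash.trend_chi_square(table)
            assert ours.chi_square == pytest.approx(
                float(lbl.zscore) ** 2 * N / (N - 1), rel=1e-9
            )

    def test_degenerate_single_row_signals(self):
        with pytest.raises(ash.UndefinedStatisticError):
            ash.trend_chi_square(np.array([[5, 7], [0, 0], [0, 0]]))


class TestClassExpressionRatio:
    def test_published_arithmetic(self):
        t = ash.build_class_tag_table(ash.make_table1_fixture("OLC"), "OLC")
        assert ash.class_expression_ratio(t, "singleton") == pytest.approx(
            (32 / 557) / (47 / 1791)
        )
        assert ash.class_expression_ratio(t, "bisyntenic") == pytest.approx(
            (295 / 557) / (1336 / 1791)
        )

    def test_equal_composition_gives_one(self):
        t = ash.ClassTagTable(np.array([[10, 30], [20, 60], [5, 15]]))
        for c in CLASSES:
            assert ash.class_expression_ratio(t, c) == pytest.approx(1.0)

    def test_zero_testis_in_class_signals(self):
        t = ash.ClassTagTable(np.array([[1, 0], [2, 3], [3, 4]]))
        with pytest.raises(ash.UndefinedStatisticError):
            ash.class_expression_ratio(t, "singleton")


class TestClassRatioPermutationTest:
    def test_forced_identity_permutation_gives_full_ties(self):
        # every gene tagged: the within-arm shuffle can only permute equal
        # tags among identical genes -> null ratios all equal the observed
        genes = [
            make_gene("a", left_ch=True, right_ch=True, tag="ovary_specific"),
            make_gene("b", left_ch=True, right_ch=True, tag="testis_specific"),
        ]
        out = ash.class_ratio_permutation_test(genes, "OLC", replicates=200, seed=0)
        res = out["singleton"]
        assert res.p_upper == res.p_lower == 1.0

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        # 8 genes on one arm, 4 singleton + 4 bisyntenic, 2 ovary + 2 testis
        genes = []
        for i in range(4):
            genes.append(make_gene(f"s{i}", left_ch=True, right_ch=True))
        for i in range(4):
            genes.append(make_gene(f"b{i}"))
        genes[0].tag = "ovary_specific"
        genes[1].tag = "testis_specific"
        genes[4].tag = "ovary_specific"
        genes[5].tag = "testis_specific"

        is_singleton = [True] * 4 + [False] * 4
        vals = []
        for ov in itertools.combinations(range(8), 2):
            rest = [i for i in range(8) if i not in ov]
            for te in itertools.combinations(rest, 2):
                no = sum(is_singleton[i] for i in ov)
                nt = sum(is_singleton[i] for i in te)
                vals.append(None if nt == 0 else (no / 2) / (nt / 2))
        valid = [v for v in vals if v is not None]
        obs = (1 / 2) / (1 / 2)
        exact_upper = sum(v >= obs for v in valid) / len(valid)

        res = ash.class_ratio_permutation_test(genes, "OLC", replicates=10_000, seed=11)[
            "singleton"
        ]
        assert res.observed == pytest.approx(obs)
        se = np.sqrt(exact_upper * (1 - exact_upper) / res.n_valid)
        assert abs(res.p_upper - exact_upper) <= 3 * se
        assert res.n_invalid > 0

    def test_marginal_consistency_of_null_tables(self, small_bundle):
        out = ash.class_ratio_permutation_test(small_bundle.genes, "OLC",
                                               replicates=100, seed=3)
        # Sum over classes of no equals No in every replicate: equivalently the
        # per-class null ratios, weighted by observed-class testis shares,
        # stay finite and the three results share replicate counts.
        assert len({res.replicates for res in out.values()}) == 1

    def test_planted_testis_concentration_in_bisyntenic_recovered(self):
        hits = 0
        for i in range(40):
            b = ash.simulate_bundle(
                ash.SyntheticConfig(seed=600 + i, class_tag_bias=3.0)
            )
            res = ash.class_ratio_permutation_test(b.genes, "OLC", replicates=500, seed=i)[
                "bisyntenic"
            ]
            hits += res.observed < 1 and res.p_lower <= 0.05
        assert hits >= 0.8 * 40
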