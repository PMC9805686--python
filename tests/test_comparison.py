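"""POR/RPOR coefficients, randomization significance, differential terms."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import phenocompare as pc
from phenocompare import DataError, OverlapCounts


def forbes_printed_formula(a, b, c):
    """Direct evaluation of the corrected Forbes coefficient as printed."""
    n = a + b + c
    num = a * (n + math.sqrt(n))
    den = (a + b) * (a + c) + a * math.sqrt(n) + (b * c) / 2
    return num / den if den else 0.0


class TestJaccard:
    def test_case_study_counts(self):
        assert round(pc.por_jaccard_from_counts(139, 273), 3) == 0.509
        assert round(pc.por_jaccard_from_counts(106, 734), 3) == 0.144

    def test_identity_and_empty(self):
        A = {("d", "T1"), ("d", "T2")}
        assert pc.por_jaccard(A, A) == 1.0
        assert pc.por_jaccard(set(), set()) == 0.0

    def test_partial_overlap(self):
        assert pc.por_jaccard({("d", "T1"), ("d", "T2")},
                              {("d", "T2"), ("d", "T3")}) == pytest.approx(1 / 3)


class TestForbes:
    def test_printed_formula_example(self):
        assert pc.por_forbes(OverlapCounts(2, 1, 1)) == pytest.approx(12 / 13.5)

    def test_disjoint_and_subset(self):
        assert pc.por_forbes(OverlapCounts(0, 5, 3)) == 0.0
        assert pc.por_forbes(OverlapCounts(3, 0, 2)) == 1.0
        assert pc.por_forbes(OverlapCounts(3, 2, 0)) == 1.0
        assert pc.por_forbes(OverlapCounts(0, 0, 0)) == 0.0

    def test_matches_printed_formula_generally(self):
        for a in range(1, 12):
            for b in range(1, 12):
                for c in range(1, 12):
                    got = pc.por_forbes(OverlapCounts(a, b, c))
                    assert got == pytest.approx(forbes_printed_formula(a, b, c))
                    assert 0.0 <= got <= 1.0

    def test_increasing_in_overlap_for_fixed_union(self):
        for n in range(2, 31):
            prev_j = prev_f = -1.0
            for a in range(0, n + 1):
                rest = n - a
                b = rest // 2
                c = rest - b
                j = pc.por_jaccard_from_counts(a, n)
                f = pc.por_forbes(OverlapCounts(a, b, c))
                assert j > prev_j - 1e-15
                assert f >= prev_f - 1e-12
                prev_j, prev_f = j, f


class TestEmpiricalP:
    def test_strictly_greater_counting(self):
        assert pc.empirical_pvalue([0.1, 0.2, 0.9], 0.5) == pytest.approx(1 / 3)

    def test_ties_not_counted(self):
        assert pc.empirical_pvalue([0.5, 0.5, 0.9], 0.5) == pytest.approx(1 / 3)

    def test_pseudocount_variant(self):
        assert pc.empirical_pvalue([0.5, 0.5, 0.9], 0.5, pseudocount=True) == \
            pytest.approx(4 / 4)
        assert pc.empirical_pvalue([0.1], 0.5, pseudocount=True) == pytest.approx(1 / 2)

    def test_lattice_property(self):
        vals = [0.0, 0.25, 0.5, 0.75, 1.0]
        p = pc.empirical_pvalue(vals, 0.3)
        assert p in {i / 5 for i in range(6)}


class TestSignificantTerms:
    def test_empty_when_nothing_significant(self, fx):
        res = pc.enrich(fx.genes_a, [fx.db_phenotype])
        out = pc.significant_terms(res, alpha=1e-12)
        assert len(out) == 0

    def test_bonferroni_subset_of_raw(self, fx):
        res = pc.enrich(fx.genes_a, [fx.db_phenotype, fx.db_disease])
        raw = pc.significant_terms(res, criterion="raw").terms
        bon = pc.significant_terms(res, criterion="bonferroni").terms
        assert bon <= raw

    def test_sentinels_excluded_by_default(self, fx):
        db = fx.db_disease
        # a gene set annotated only to the sentinel makes it significant
        sid = db.sentinel_id
        only = sorted(g for g, t in db.associations if t == sid)
        if not only:
            pytest.skip("fixture has no sentinel-only genes")
        res = pc.enrich(pc.GeneSet.from_iterable("s", only), [db])
        incl = pc.significant_terms(res, include_sentinels=True).terms
        excl = pc.significant_terms(res).terms
        assert not any(t == sid for _, t in excl)
        assert incl >= excl


class TestPorSignificance:
    def test_identical_sets_por_one(self, fx):
        plan = pc.RandomizationPlan(m=20, mode="overlapping", seed=5)
        res = pc.por_significance(fx.genes_a, fx.genes_a,
                                  [fx.db_phenotype, fx.db_disease], plan)
        assert res.por == 1.0
        # nothing strictly exceeds 1 unless a null replicate also reaches 1
        n_at_one = np.sum(res.null_values >= 1.0)
        assert res.empirical_p == pytest.approx(
            np.sum(res.null_values > 1.0) / len(res.null_values))
        assert n_at_one >= 0  # ties never counted

    def test_null_value_counts_by_mode(self, fx):
        dbs = [fx.db_phenotype]
        over = pc.por_significance(
            fx.genes_a, fx.genes_b, dbs,
            pc.RandomizationPlan(m=30, mode="overlapping", seed=2))
        cond = pc.por_significance(
            fx.genes_a, fx.genes_b, dbs,
            pc.RandomizationPlan(m=30, mode="conditional", seed=2))
        assert len(over.null_values) == 60
        assert len(cond.null_values) == 30

    def test_seed_reproducibility(self, fx):
        plan = pc.RandomizationPlan(m=25, seed=11)
        a = pc.por_significance(fx.genes_a, fx.genes_b, [fx.db_phenotype], plan)
        b = pc.por_significance(fx.genes_a, fx.genes_b, [fx.db_phenotype], plan)
        np.testing.assert_array_equal(a.null_values, b.null_values)
        assert a.empirical_p == b.empirical_p

    def test_empirical_p_on_lattice(self, fx):
        plan = pc.RandomizationPlan(m=16, mode="conditional", seed=3)
        res = pc.por_significance(fx.genes_a, fx.genes_b, [fx.db_phenotype], plan)
        assert res.empirical_p in {i / 16 for i in range(17)}

    def test_invalid_plan_rejected(self):
        with pytest.raises(DataError):
            pc.RandomizationPlan(m=0)

    def test_universe_too_small(self, fx):
        big = pc.GeneSet.from_iterable("big", [f"Z{i}" for i in range(100)])
        with pytest.raises(DataError):
            pc.por_significance(big, fx.genes_a, [fx.db_phenotype],
                                pc.RandomizationPlan(m=5, seed=1))


class TestRpor:
    def _two_term_dbs(self):
        genes = [f"Y{i}" for i in range(12)]
        db = pc.AnnotationDatabase(
            name="r",
            associations={(genes[0], "T1"), (genes[0], "T2"),
                          (genes[1], "T2"), (genes[1], "T3"),
                          (genes[5], "T4")},
            terms={t: pc.TermRecord(t) for t in ["T1", "T2", "T3", "T4"]})
        return pc.standardize(db, pc.GeneUniverse.from_iterable(genes)), genes

    def test_annotated_term_overlap(self):
        db, genes = self._two_term_dbs()
        A = pc.GeneSet.from_iterable("a", [genes[0]])   # terms {T1,T2}
        B = pc.GeneSet.from_iterable("b", [genes[1]])   # terms {T2,T3}
        assert pc.rpor(A, B, [db]) == pytest.approx(1 / 3)

    def test_disjoint_annotations(self):
        db, genes = self._two_term_dbs()
        A = pc.GeneSet.from_iterable("a", [genes[0]])
        C = pc.GeneSet.from_iterable("c", [genes[5]])   # term {T4}
        assert pc.rpor(A, C, [db]) == 0.0


class TestDifferentialTerms:
    def test_identical_results_no_exclusives(self, fx):
        res = pc.enrich(fx.genes_a, [fx.db_phenotype, fx.db_disease])
        out = pc.differential_terms(res, res)
        assert out.exclusive_to_a.empty and out.exclusive_to_b.empty

    def test_partition_of_union(self, fx):
        ra = pc.enrich(fx.genes_a, [fx.db_phenotype, fx.db_disease])
        rb = pc.enrich(fx.genes_b, [fx.db_phenotype, fx.db_disease])
        out = pc.differential_terms(ra, rb)
        union = len(pc.significant_terms(ra).terms | pc.significant_terms(rb).terms)
        assert len(out.shared) + len(out.exclusive_to_a) + len(out.exclusive_to_b) == union

    def test_exclusive_rows_carry_other_side_p(self, fx):
        ra = pc.enrich(fx.genes_a, [fx.db_phenotype, fx.db_disease])
        rb = pc.enrich(fx.genes_b, [fx.db_phenotype, fx.db_disease])
        out = pc.differential_terms(ra, rb)
        assert {"p_raw_a", "p_raw_b", "g_a", "g_b"} <= set(out.exclusive_to_a.columns)
        assert out.exclusive_to_a["p_raw_b"].notna().all()

    def test_database_mismatch_rejected(self, fx):
        ra = pc.enrich(fx.genes_a, [fx.db_phenotype])
        rb = pc.enrich(fx.genes_b, [fx.db_phenotype, fx.db_disease])
        with pytest.raises(DataError, match="mismatch"):
            pc.differential_terms(ra, rb)


class TestRelevanceRegression:
    def test_perfect_fit(self):
        out = pc.relevance_regression([(1, 2), (2, 4), (3, 6)])
        assert out.defined
        assert out.slope == pytest.approx(2.0)
        assert out.r2_adj == pytest.approx(1.0)

    def test_hand_computed_ols(self):
        out = pc.relevance_regression([(1, 1), (2, 3), (3, 2)])
        assert out.r2 == pytest.approx(0.25, abs=1e-12)
        assert out.r2_adj == pytest.approx(-0.5, abs=1e-12)

    def test_constant_y_zero_slope(self):
        out = pc.relevance_regression([(1, 5), (2, 5), (3, 5)])
        assert out.defined
        assert out.slope == pytest.approx(0.0, abs=1e-12)
        assert out.r2 == pytest.approx(0.0, abs=1e-12)
        assert out.low_information

    def test_undefined_cases(self):
        assert not pc.relevance_regression([(1, 2), (2, 3)]).defined
        assert not pc.relevance_regression([(2, 1), (2, 5), (2, 9)]).defined


class TestSummarize:
    def test_message_contains_counts_and_por(self, fx):
        plan = pc.RandomizationPlan(m=10, seed=1)
        res = pc.por_significance(fx.genes_a, fx.genes_b,
                                  [fx.db_phenotype, fx.db_disease], plan)
        msg = res.summary_message
        assert str(res.counts.a) in msg
        assert str(res.counts.n) in msg
        assert f"{res.por:.3f}" in msg

    def test_empty_shared_message(self, fx):
        plan = pc.RandomizationPlan(m=5, seed=1)
        res = pc.por_significance(fx.genes_a, fx.genes_b,
                                  [fx.db_phenotype, fx.db_disease], plan,
                                  alpha=1e-14)
        assert "no significant terms" in res.summary_message.lower()

    def test_undefined_regression_omitted(self, fx):
        plan = pc.RandomizationPlan(m=5, seed=1)
        res = pc.por_significance(fx.genes_a, fx.genes_b,
                                  [fx.db_phenotype, fx.db_disease], plan,
                                  alpha=1e-14)
        assert "R²" not in res.summary_message


@given(st.integers(0, 10), st.integers(0, 10), st.integers(0, 10))
def test_coefficients_bounded(a, b, c):
    counts = OverlapCounts(a, b, c)
    assert 0.0 <= pc.por_forbes(counts) <= 1.0
    assert 0.0 <= pc.por_jaccard_from_counts(a, counts.n) <= 1.0


def test_gene_overlap_percent_reporting():
    """19 shared genes of a 35-gene panel report as 54.3%."""
    genes_pd = [f"P{i:02d}" for i in range(35)]
    genes_eod = genes_pd[:19] + [f"E{i:02d}" for i in range(31)]
    uni = pc.GeneUniverse.from_iterable(genes_pd + genes_eod + ["F1", "F2"])
    db = pc.AnnotationDatabase(
        name="d", associations={(g, "T1") for g in genes_pd[:10]},
        terms={"T1": pc.TermRecord("T1")})
    db = pc.standardize(db, uni)
    res = pc.por_significance(
        pc.GeneSet.from_iterable("PD", genes_pd),
        pc.GeneSet.from_iterable("EOD", genes_eod),
        [db], pc.RandomizationPlan(m=5, seed=1))
    assert res.gene_overlap == 19
    assert round(res.gene_overlap_percent, 1) == 54.3
    assert "54.3%" in res.summary_message
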