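import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cytomdr import GenotypeDataset
from cytomdr.association import (
    TwoByTwo,
    adjusted_model_or,
    allele_frequencies,
    bonferroni,
    crude_model_scan,
    fisher_genotype_test,
    hwe_test,
    inheritance_tables,
    odds_ratio_2x2,
    select_best_model_aic,
)
from cytomdr.datamodel import DegenerateInputError, GenotypeCountTable
from cytomdr.simulate import CohortSpec, PenetranceModel, simulate_cohort

from _oracles import enumerate_fisher_2x3, enumerate_hwe_exact


def table_by_rsid(tables, rsid):
    return next(t for t in tables if t.snp.rsid == rsid)


class TestAlleleFrequencies:
    def test_reference_il1a(self, ref_tables):
        af = allele_frequencies(table_by_rsid(ref_tables, "rs1800587"))
        ctrl_g = af[(af["class"] == "control") & (af.allele == "G")].iloc[0]
        case_a = af[(af["class"] == "case") & (af.allele == "A")].iloc[0]
        assert ctrl_g["count"] == 1173
        assert round(ctrl_g.pct, 1) == 82.6
        assert case_a["count"] == 110
        assert round(case_a.pct, 1) == 24.9

    def test_empty_class_signalled(self, ref_tables):
        t = GenotypeCountTable(ref_tables[0].snp, np.array([[0, 0, 0], [1, 1, 0]]))
        with pytest.raises(DegenerateInputError):
            allele_frequencies(t)


class TestHWE:
    def test_perfect_proportions_statistic_zero(self):
        stat, p = hwe_test(25, 50, 25, "chi2")
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_complete_het_deficit_statistic_100(self):
        # hand computation: n=100, p=q=0.5, expected (25,50,25),
        # chi2 = 25 + 50 + 25 = 100
        stat, _ = hwe_test(50, 0, 50, "chi2")
        assert stat == pytest.approx(100.0)

    def test_monomorphic_p_one(self):
        for method in ("chi2", "exact"):
            _, p = hwe_test(40, 0, 0, method)
            assert p == 1.0

    @given(
        st.integers(0, 25), st.integers(0, 25), st.integers(0, 25)
    )
    @settings(max_examples=60, deadline=None)
    def test_exact_matches_enumeration_oracle(self, n0, n1, n2):
        if n0 + n1 + n2 == 0:
            return
        _, p = hwe_test(n0, n1, n2, "exact")
        assert p == pytest.approx(enumerate_hwe_exact(n0, n1, n2), abs=1e-9)


class TestOddsRatio:
    def test_published_dominant_example(self):
        # 97/124 exposed/unexposed cases vs 195/515 controls
        res = odds_ratio_2x2(TwoByTwo(97, 124, 195, 515))
        assert res.or_value == pytest.approx(2.066, abs=5e-4)
        assert res.ci_low == pytest.approx(1.51, abs=5e-3)
        assert res.ci_high == pytest.approx(2.82, abs=5e-3)

    def test_symmetric_table_or_one(self):
        res = odds_ratio_2x2(TwoByTwo(10, 10, 10, 10))
        assert res.or_value == pytest.approx(1.0)

    def test_published_codominant_hom_example(self):
        res = odds_ratio_2x2(TwoByTwo(16, 127, 23, 486))
        assert res.or_value == pytest.approx(2.66, abs=5e-3)
        assert res.ci_low == pytest.approx(1.36, abs=6e-3)
        assert res.ci_high == pytest.approx(5.18, abs=1e-2)

    def test_haldane_on_zero_cell(self):
        res = odds_ratio_2x2(TwoByTwo(10, 0, 0, 10))
        assert res.corrected
        assert res.or_value == pytest.approx(441.0)

    def test_both_diagonals_zero_signalled(self):
        with pytest.raises(DegenerateInputError):
            odds_ratio_2x2(TwoByTwo(0, 0, 5, 5))

    @given(st.integers(1, 60), st.integers(1, 60), st.integers(1, 60), st.integers(1, 60))
    @settings(max_examples=40, deadline=None)
    def test_swap_reciprocal_and_ci_coverage(self, a, b, c, d):
        t = TwoByTwo(a, b, c, d)
        res = odds_ratio_2x2(t)
        swapped = odds_ratio_2x2(t.swapped())
        assert swapped.or_value == pytest.approx(1 / res.or_value)
        assert res.ci_low <= res.or_value <= res.ci_high
        # Fisher p invariant under exposure swap
        assert swapped.p == pytest.approx(res.p, rel=1e-9)


class TestInheritanceTables:
    def test_tnfa_codominant_het(self, ref_tables):
        t = table_by_rsid(ref_tables, "rs1800629")
        [(label, tab)] = inheritance_tables(t, "codominant_het")
        assert (tab.a, tab.b, tab.c, tab.d) == (21, 154, 72, 634)
        assert odds_ratio_2x2(tab).or_value == pytest.approx(1.20, abs=5e-3)

    def test_ifng_recessive(self, ref_tables):
        t = table_by_rsid(ref_tables, "rs2069705")
        [(_, tab)] = inheritance_tables(t, "recessive")
        assert odds_ratio_2x2(tab).or_value == pytest.approx(1.35, abs=5e-3)

    def test_zero_cell_exercises_haldane(self, ref_tables):
        t = GenotypeCountTable(ref_tables[0].snp, np.array([[5, 0, 5], [3, 2, 7]]))
        [(_, tab)] = inheritance_tables(t, "overdominant")
        assert 0 in (tab.a, tab.b, tab.c, tab.d)
        res = odds_ratio_2x2(tab)
        assert res.corrected

    def test_empty_exposure_margin_undefined(self, ref_tables):
        # both classes have an empty het column: no exposed subjects at all
        t = GenotypeCountTable(ref_tables[0].snp, np.array([[5, 0, 5], [3, 0, 7]]))
        [(_, tab)] = inheritance_tables(t, "overdominant")
        with pytest.raises(DegenerateInputError):
            odds_ratio_2x2(tab)


class TestCrudeScan:
    def test_il6_dominant_and_recessive(self, ref_tables):
        scan = {r.model: r for r in crude_model_scan(table_by_rsid(ref_tables, "rs1800796"))}
        assert scan["dominant"].or_value == pytest.approx(2.066, abs=5e-4)
        assert scan["recessive"].or_value == pytest.approx(0.451, abs=5e-4)

    def test_il1a_overdominant(self, ref_tables):
        scan = {r.model: r for r in crude_model_scan(table_by_rsid(ref_tables, "rs1800587"))}
        assert scan["overdominant"].or_value == pytest.approx(1.3813, abs=5e-5)

    def test_null_snp_all_ors_exactly_one(self, ref_tables):
        t = GenotypeCountTable(ref_tables[0].snp, np.array([[50, 30, 20], [50, 30, 20]]))
        for res in crude_model_scan(t):
            assert res.or_value == pytest.approx(1.0)


class TestFisherGenotype:
    def test_identical_rows_p_one(self, ref_tables):
        t = GenotypeCountTable(ref_tables[0].snp, np.array([[5, 5, 5], [5, 5, 5]]))
        assert fisher_genotype_test(t) == pytest.approx(1.0)

    def test_extreme_table_matches_enumeration(self, ref_tables):
        t = GenotypeCountTable(ref_tables[0].snp, np.array([[5, 0, 0], [0, 0, 5]]))
        p = fisher_genotype_test(t)
        assert p == pytest.approx(enumerate_fisher_2x3([[5, 0, 0], [0, 0, 5]]), abs=1e-12)
        # extreme hypergeometric mass: 2 tables of prob 1/C(10,5) each
        assert p == pytest.approx(2 / 252, abs=1e-12)

    @given(st.lists(st.integers(0, 12), min_size=6, max_size=6))
    @settings(max_examples=40, deadline=None)
    def test_matches_enumeration_oracle(self, cells):
        counts = [cells[:3], cells[3:]]
        if sum(cells[:3]) == 0 or sum(cells[3:]) == 0:
            return
        t = GenotypeCountTable(_snp(), np.array(counts))
        assert fisher_genotype_test(t) == pytest.approx(
            enumerate_fisher_2x3(counts), abs=1e-10
        )

    def test_large_table_agrees_with_chi2(self, ref_tables):
        counts = np.array([[210, 240, 260], [180, 260, 250]])
        t = GenotypeCountTable(ref_tables[0].snp, counts)
        p_exact = fisher_genotype_test(t)
        _, p_chi2, _, _ = stats.chi2_contingency(counts, correction=False)
        assert abs(p_exact - p_chi2) < 0.05


def _snp():
    from cytomdr.datamodel import SNPDescriptor

    return SNPDescriptor("rs_test", "X", "G", "A")


class TestBonferroni:
    def test_arithmetic_and_cap(self):
        assert list(bonferroni([0.01])) == [0.01]
        assert list(bonferroni([0.01, 0.04])) == pytest.approx([0.02, 0.08])
        assert list(bonferroni([0.5, 0.5, 0.5])) == [1.0, 1.0, 1.0]


class TestAdjustedModels:
    def _cohort(self, seed=13, n=2500):
        spec = CohortSpec(n, n, {"rs_x": 0.3}, seed=seed)
        model = PenetranceModel(("rs_x",), np.array([0.2, 0.35, 0.5]))
        ds = simulate_cohort(spec, model)
        rng = np.random.default_rng(seed + 1)
        ds.covariates = pd.DataFrame(
            {"noise": rng.normal(size=ds.n_subjects)}, index=ds.subjects
        )
        return ds

    def test_null_covariate_adjustment_matches_crude(self):
        from cytomdr.datamodel import marginal_counts

        ds = self._cohort()
        crude = {r.model: r for r in crude_model_scan(marginal_counts(ds, "rs_x"))}
        adj = adjusted_model_or(ds, "rs_x", "dominant", ["noise"])
        assert abs(np.log(adj.or_value) - np.log(crude["dominant"].or_value)) < 0.05
        assert adj.adjusted and adj.aic is not None

    def test_perfect_predictor_flags_separation(self):
        ds = self._cohort(n=200)
        ds.covariates["leak"] = ds.status.to_numpy().astype(float)
        res = adjusted_model_or(ds, "rs_x", "dominant", ["leak"])
        assert res.separation

    def test_constant_genotype_term_signalled(self):
        geno = pd.DataFrame({"rs_c": [0, 0, 0, 0]})
        ds = GenotypeDataset(geno, [0, 1, 0, 1])
        with pytest.raises(DegenerateInputError):
            adjusted_model_or(ds, "rs_c", "additive")


class TestAICSelection:
    def test_recessive_mechanism_recovered(self):
        """Under a recessive penetrance the winner is recessive, except for
        the AIC's known loss rate to the codominant model that nests it:
        P(chi2_1 > 2) ~ 0.157, so recessive wins ~84% asymptotically and
        never loses to a non-nesting model."""
        winners = []
        n_seeds = 40
        for seed in range(n_seeds):
            spec = CohortSpec(1000, 1000, {"rs_x": 0.35}, seed=1000 + seed)
            model = PenetranceModel(("rs_x",), np.array([0.1, 0.1, 0.45]))
            ds = simulate_cohort(spec, model)
            winners.append(select_best_model_aic(ds, "rs_x"))
        assert set(winners) <= {"recessive", "codominant"}
        # 0.843 minus 3 binomial SEs at n_seeds=40
        assert winners.count("recessive") / n_seeds >= 0.67

    def test_additive_mechanism_recovered(self):
        from scipy.special import expit

        hits = 0
        n_seeds = 15
        for seed in range(n_seeds):
            spec = CohortSpec(2500, 2500, {"rs_x": 0.3}, seed=2000 + seed)
            model = PenetranceModel(("rs_x",), expit(-1.0 + 0.7 * np.arange(3)))
            ds = simulate_cohort(spec, model)
            if select_best_model_aic(ds, "rs_x") == "additive":
                hits += 1
        assert hits / n_seeds >= 0.8

    def test_deterministic_given_data(self):
        spec = CohortSpec(300, 300, {"rs_x": 0.3}, seed=5)
        ds = simulate_cohort(spec, PenetranceModel(("rs_x",), np.full(3, 0.5)))
        assert select_best_model_aic(ds, "rs_x") == select_best_model_aic(ds, "rs_x")
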