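import numpy as np
import pandas as pd
import pytest

from cytomdr import GenotypeDataset
from cytomdr.datamodel import DegenerateInputError, ValidationError
from cytomdr.mdr import (
    classify,
    classifier_or,
    confusion_metrics,
    cross_validate,
    fit_mdr,
    label_cells,
    list_risk_combinations,
    permutation_test,
    search_best_models,
    stratified_folds,
)
from cytomdr.simulate import CohortSpec, simulate_cohort, uniform_penetrance

from _oracles import naive_search
from conftest import make_xor_cohort


def cells_by_combo(cells):
    return {c.genotype_combo: c for c in cells}


class TestLabelCells:
    def test_reference_single_locus_ratios(self, ref_dataset):
        """Ratios on the study counts: R = (0.780, 0.937, 36.95) -> low/low/high."""
        cells = cells_by_combo(label_cells(ref_dataset, ["rs1800629"], T=1.05))
        assert [cells[(g,)].risk_label for g in (0, 1, 2)] == ["low", "low", "high"]
        assert cells[(0,)].ratio == pytest.approx(0.780, abs=5e-4)
        assert cells[(1,)].ratio == pytest.approx(0.937, abs=5e-4)
        assert cells[(2,)].ratio == pytest.approx(36.95, abs=5e-2)

    def test_balanced_cell_is_low(self):
        geno = pd.DataFrame({"rs1": [0] * 10 + [0] * 10 + [1, 1]})
        ds = GenotypeDataset(geno, [1] * 10 + [0] * 10 + [0, 1])
        cells = cells_by_combo(label_cells(ds, ["rs1"], T=1.05))
        assert cells[(0,)].risk_label == "low"  # R = 1 exactly

    def test_zero_threshold_any_case_high(self):
        geno = pd.DataFrame({"rs1": [0, 1, 2, 2]})
        ds = GenotypeDataset(geno, [1, 0, 0, 1])
        cells = cells_by_combo(label_cells(ds, ["rs1"], T=0.0))
        assert cells[(0,)].risk_label == "high"
        assert cells[(1,)].risk_label == "low"  # control-only cell
        assert cells[(2,)].risk_label == "high"

    def test_empty_cell_labelled_empty(self):
        geno = pd.DataFrame({"rs1": [0, 0, 1, 1]})
        ds = GenotypeDataset(geno, [0, 1, 0, 1])
        cells = cells_by_combo(label_cells(ds, ["rs1"]))
        assert cells[(2,)].risk_label == "empty"


class TestClassifyAndMetrics:
    def test_high_cell_classifies_high_and_empty_low(self, ref_dataset):
        model = fit_mdr(ref_dataset, ["rs1800629"])
        assert classify(model, np.array([[2]]))[0]
        assert not classify(model, np.array([[0]]))[0]

    def test_unseen_cell_is_low(self):
        geno = pd.DataFrame({"rs1": [0, 0, 1, 1]})
        ds = GenotypeDataset(geno, [0, 1, 0, 1])
        model = fit_mdr(ds, ["rs1"])
        assert not classify(model, np.array([[2]]))[0]

    def test_reference_bookkeeping_46_cases_4_controls_high(self, ref_dataset):
        model = fit_mdr(ref_dataset, ["rs1800629"])
        labels = classify(model, ref_dataset.genotypes[["rs1800629"]].to_numpy())
        status = ref_dataset.status.to_numpy()
        assert ((status == 1) & labels).sum() == 46
        assert ((status == 0) & labels).sum() == 4

    def test_reference_confusion_metrics(self, ref_dataset):
        model = fit_mdr(ref_dataset, ["rs1800629"])
        ba, sens, spec = confusion_metrics(model, ref_dataset)
        assert sens == pytest.approx(46 / 221, abs=1e-12)
        assert spec == pytest.approx(706 / 710, abs=1e-12)
        assert ba == pytest.approx((46 / 221 + 706 / 710) / 2, abs=1e-12)

    def test_perfect_separation_metrics_one(self):
        geno = pd.DataFrame({"rs1": [0] * 10 + [2] * 10})
        ds = GenotypeDataset(geno, [0] * 10 + [1] * 10)
        model = fit_mdr(ds, ["rs1"])
        assert confusion_metrics(model, ds) == (1.0, 1.0, 1.0)

    def test_all_low_classifier_metrics(self):
        geno = pd.DataFrame({"rs1": [0] * 8 + [0] * 2})
        ds = GenotypeDataset(geno, [0] * 8 + [1] * 2)
        model = fit_mdr(ds, ["rs1"])  # single cell, R < 1 -> low
        ba, sens, spec = confusion_metrics(model, ds)
        assert (ba, sens, spec) == (0.5, 0.0, 1.0)
        with pytest.raises(DegenerateInputError):
            classifier_or(model, ds)

    def test_reference_classifier_or(self, ref_dataset):
        model = fit_mdr(ref_dataset, ["rs1800629"])
        res = classifier_or(model, ref_dataset)
        assert res.or_value == pytest.approx((46 * 706) / (175 * 4), rel=1e-12)

    def test_perfect_classifier_haldane_or(self):
        geno = pd.DataFrame({"rs1": [0] * 10 + [2] * 10})
        ds = GenotypeDataset(geno, [0] * 10 + [1] * 10)
        model = fit_mdr(ds, ["rs1"])
        res = classifier_or(model, ds)
        assert res.or_value == pytest.approx((10.5 * 10.5) / (0.5 * 0.5))


class TestCrossValidation:
    def test_perfect_snp_mean_ba_one(self):
        rng = np.random.default_rng(0)
        status = np.array([0, 1] * 50)
        geno = pd.DataFrame({"rs1": status * 2, "rs_noise": rng.integers(0, 3, 100)})
        ds = GenotypeDataset(geno, status)
        cv = cross_validate(ds, ["rs1"], rng=np.random.default_rng(1))
        assert cv.mean_test_ba == 1.0

    def test_same_seed_identical(self, xor_cohort):
        a = cross_validate(xor_cohort, ["snpA", "snpB"], rng=np.random.default_rng(9))
        b = cross_validate(xor_cohort, ["snpA", "snpB"], rng=np.random.default_rng(9))
        assert a.mean_test_ba == b.mean_test_ba
        assert a.fold_test_ba == b.fold_test_ba

    def test_stratified_folds_balanced(self):
        status = np.array([0] * 70 + [1] * 30)
        folds = stratified_folds(status, 10, np.random.default_rng(2))
        for f in range(10):
            assert (status[folds == f] == 1).sum() == 3
            assert (status[folds == f] == 0).sum() == 7

    def test_too_small_class_rejected(self):
        status = np.array([0] * 50 + [1] * 5)
        with pytest.raises(ValidationError, match="stratify"):
            stratified_folds(status, 10, np.random.default_rng(0))


class TestSearch:
    def test_combination_count_five_snps(self, ref_dataset):
        res = search_best_models(ref_dataset, 1, 5, rng=np.random.default_rng(0))
        assert res.n_combinations == 31
        assert sorted(res.models) == [1, 2, 3, 4, 5]

    def test_single_snp_dataset_consistency_10(self):
        rng = np.random.default_rng(3)
        status = rng.integers(0, 2, 200)
        geno = pd.DataFrame({"rs1": rng.integers(0, 3, 200)})
        ds = GenotypeDataset(geno, status)
        res = search_best_models(ds, 1, 1, rng=np.random.default_rng(4))
        assert res.models[1].snps == ("rs1",)
        assert res.models[1].cv_consistency == 10

    def test_xor_cohort_recovers_causal_pair(self, xor_cohort):
        res = search_best_models(xor_cohort, k_min=2, k_max=2,
                                 rng=np.random.default_rng(6))
        assert set(res.models[2].snps) == {"snpA", "snpB"}
        assert res.models[2].cv_consistency >= 8
        assert res.models[2].test_balanced_accuracy > 0.55

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_oracle(self, seed):
        """Engine equals a naive dict/loop reference for n <= 200, k <= 2."""
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(80, 200))
        n_snps = 4
        geno = pd.DataFrame(
            {f"rs{j}": rng.integers(0, 3, n) for j in range(n_snps)}
        )
        status = np.array([0] * (n // 2) + [1] * (n - n // 2))
        rng.shuffle(status)
        ds = GenotypeDataset(geno, status)
        folds = stratified_folds(status, 5, np.random.default_rng(200 + seed))
        res = search_best_models(ds, 1, 2, n_folds=5, folds=folds)
        ref = naive_search(
            geno.to_numpy().tolist(), status.tolist(), folds.tolist(),
            ds.snps, [1, 2], T=1.05,
        )
        for k in (1, 2):
            combo, consistency, mean_ba = ref[k]
            assert res.models[k].snps == combo
            assert res.models[k].cv_consistency == consistency
            assert res.models[k].test_balanced_accuracy == pytest.approx(mean_ba)

    def test_training_ba_monotone_in_k_at_classic_threshold(self, ref_dataset):
        """With T=1 the cell labelling is the BA-optimal one, so the best
        training BA cannot decrease as the genotype partition refines."""
        res = search_best_models(ref_dataset, 1, 5, T=1.0,
                                 rng=np.random.default_rng(11))
        sub = ref_dataset
        best_tr = []
        from itertools import combinations

        for k in range(1, 6):
            best = max(
                fit_mdr(sub, list(c), T=1.0).train_balanced_accuracy
                for c in combinations(sub.snps, k)
            )
            best_tr.append(best)
        assert all(b2 >= b1 - 1e-12 for b1, b2 in zip(best_tr, best_tr[1:]))

    def test_label_flip_symmetry(self):
        """Swapping classes and inverting T maps high <-> low for cells with
        both counts nonzero."""
        rng = np.random.default_rng(14)
        geno = pd.DataFrame({"rs1": rng.integers(0, 3, 120),
                             "rs2": rng.integers(0, 3, 120)})
        status = rng.integers(0, 2, 120)
        ds = GenotypeDataset(geno, status)
        flipped = GenotypeDataset(geno, 1 - status)
        T = 1.3
        cells = cells_by_combo(label_cells(ds, ["rs1", "rs2"], T=T))
        cells_f = cells_by_combo(label_cells(flipped, ["rs1", "rs2"], T=1 / T))
        for combo, cell in cells.items():
            if cell.n_cases > 0 and cell.n_controls > 0:
                # strict R > T both ways; R values never equal T or 1/T here
                assert (cell.risk_label == "high") == (
                    cells_f[combo].risk_label == "low"
                )


class TestPermutation:
    def test_p_never_zero(self, xor_cohort):
        p = permutation_test(xor_cohort, ["snpA", "snpB"], n_perm=19,
                             rng=np.random.default_rng(0))
        assert p == pytest.approx(1 / 20)

    def test_zero_perms_rejected(self, xor_cohort):
        with pytest.raises(ValidationError):
            permutation_test(xor_cohort, ["snpA"], n_perm=0)


class TestRiskCombinations:
    def test_reference_single_locus_listing(self, ref_dataset):
        model = fit_mdr(ref_dataset, ["rs1800629"])
        table, n_empty = list_risk_combinations(model)
        assert len(table) == 3 and n_empty == 0
        assert table.iloc[0]["rs1800629"] == 2  # top ratio row

    def test_uniform_data_all_low(self):
        geno = pd.DataFrame({"rs1": [0, 1, 2] * 4})
        ds = GenotypeDataset(geno, [0, 1] * 6)
        model = fit_mdr(ds, ["rs1"])
        table, _ = list_risk_combinations(model)
        assert (table.ratio == 1.0).all()
        assert (table.risk_label == "low").all()

    def test_empty_cells_counted_not_listed(self):
        geno = pd.DataFrame({"rs1": [0, 0, 1, 1]})
        ds = GenotypeDataset(geno, [0, 1, 0, 1])
        model = fit_mdr(ds, ["rs1"])
        table, n_empty = list_risk_combinations(model)
        assert len(table) == 2 and n_empty == 1
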