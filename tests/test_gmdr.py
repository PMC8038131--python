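"""GMDR engine: scores, cell partitioning, balanced accuracy, sign
test, cross-validation and exhaustive model search."""

import itertools

import numpy as np
import pandas as pd
import pytest

import gmdrprs as g
from gmdrprs.gmdr import (
    GMDRSearch,
    _cell_codes,
    fold_assignments,
    results_table,
)
from gmdrprs.synthetic import SNPSpec, both_carrier_cells


# ---------------------------------------------------------------- oracles
def classic_mdr_labels(geno, y):
    """Independent classic-MDR rule: a cell is high risk when its
    case:control ratio exceeds the overall ratio (ties low)."""
    geno = np.asarray(geno, dtype=float)
    y = np.asarray(y, dtype=float)
    overall = y.sum() / (len(y) - y.sum())
    labels = {}
    for cell in itertools.product((0, 1, 2), repeat=geno.shape[1]):
        m = np.all(geno == np.asarray(cell), axis=1)
        cases, ctrls = y[m].sum(), (1 - y[m]).sum()
        if m.sum() == 0:
            labels[cell] = 0
        elif ctrls == 0:
            labels[cell] = 1 if cases > 0 else 0
        else:
            labels[cell] = 1 if cases / ctrls > overall else 0
    return labels


def subject_level_ba(geno, y, labels):
    from sklearn.metrics import balanced_accuracy_score

    pred = np.array([labels[tuple(row.astype(int))] for row in np.asarray(geno)])
    return balanced_accuracy_score(np.asarray(y), pred)


# ------------------------------------------------------------------ tests
class TestScores:
    def test_balanced_no_covariates_gives_half(self):
        y = np.array([1, 1, 0, 0], dtype=float)
        np.testing.assert_allclose(g.compute_scores(y), [0.5, 0.5, -0.5, -0.5])

    def test_scores_sum_to_zero_with_intercept(self):
        rng = np.random.default_rng(51)
        y = (rng.random(500) < 0.3).astype(float)
        cov = pd.DataFrame({"x": rng.normal(size=500)})
        s = g.compute_scores(y, cov)
        assert abs(s.sum()) < 1e-6 * len(s)

    def test_scores_match_independent_logistic_residuals(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(52)
        n = 800
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.5 * x - 1)))).astype(float)
        cov = pd.DataFrame({"x": x})
        s = g.compute_scores(y, cov)
        oracle = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(s, oracle.resid_response, atol=1e-8)

    def test_nonbinary_outcome_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            g.compute_scores(np.array([0.0, 1.0, 2.0]))


class TestPartition:
    def test_positive_cell_sum_is_high(self):
        # one cell holding 3 cases (+0.5) and 1 control (-0.5): sum 1 > 0
        geno = np.zeros((4, 1))
        scores = np.array([0.5, 0.5, 0.5, -0.5])
        part = g.partition_cells(geno, scores)
        assert part.high[0]

    def test_empty_cells_low(self):
        geno = np.zeros((4, 2))  # only cell (0,0) observed
        scores = np.array([0.5, 0.5, 0.5, -0.5])
        part = g.partition_cells(geno, scores)
        assert part.high.sum() == 1 and part.observed.sum() == 1

    def test_tie_at_threshold_low(self):
        geno = np.zeros((2, 1))
        scores = np.array([0.5, -0.5])
        assert not g.partition_cells(geno, scores).high[0]

    def test_matches_classic_mdr_rule_on_balanced_data(self):
        rng = np.random.default_rng(53)
        for trial in range(20):
            n = 40
            geno = rng.integers(0, 3, size=(n, 2)).astype(float)
            y = np.repeat([1.0, 0.0], n // 2)
            rng.shuffle(y)
            scores = g.compute_scores(y)
            part = g.partition_cells(geno, scores)
            oracle = classic_mdr_labels(geno, y)
            for cell, lab in oracle.items():
                code = cell[0] + 3 * cell[1]
                assert int(part.high[code]) == lab, (trial, cell)


class TestBalancedAccuracy:
    def test_perfect_separation(self):
        geno = np.array([[0.0], [0.0], [2.0], [2.0]])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        part = g.partition_cells(geno, g.compute_scores(y))
        assert g.balanced_accuracy(part, geno, y) == 1.0

    def test_all_low_prediction_gives_half(self):
        geno = np.zeros((6, 1))
        y = np.array([1.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        part = g.partition_cells(geno, g.compute_scores(y))  # sum < 0 -> low
        assert g.balanced_accuracy(part, geno, y) == 0.5

    def test_confusion_arithmetic(self):
        # TP=3, FN=1, TN=2, FP=2 -> 0.5*(0.75 + 0.5) = 0.625
        geno = np.array([[0.0]] * 5 + [[1.0]] * 3)
        y = np.array([1, 1, 1, 0, 0, 1, 0, 0], dtype=float)
        # cell 0: 3 cases, 2 controls -> high; cell 1: 1 case, 2 controls -> low
        part = g.partition_cells(geno, np.where(y > 0, 1.0, -1.0))
        # cell 0 sums to +1 (high), cell 1 to -1 (low)
        assert part.high[0] and not part.high[1]
        assert g.balanced_accuracy(part, geno, y) == pytest.approx(0.625)

    def test_absent_class_errors(self):
        geno = np.zeros((3, 1))
        y = np.ones(3)
        part = g.partition_cells(geno, np.ones(3))
        with pytest.raises(ValueError, match="class"):
            g.balanced_accuracy(part, geno, y)


class TestSignTest:
    @pytest.mark.parametrize(
        "wins,expected",
        [(10, 0.0010), (9, 0.0107), (8, 0.0547), (7, 0.1719), (6, 0.3770)],
    )
    def test_published_tail_values(self, wins, expected):
        assert round(g.sign_test(wins, 10), 4) == expected

    def test_exact_fractions(self):
        assert g.sign_test(10, 10) == pytest.approx(1 / 1024)
        assert g.sign_test(8, 10) == pytest.approx(56 / 1024)
        assert g.sign_test(5, 10) == pytest.approx(638 / 1024)
        assert g.sign_test(0, 10) == 1.0

    def test_matches_enumeration_oracle_all_small_n(self):
        # brute force over all 2^n win/loss sequences
        for n in range(1, 13):
            for k in range(n + 1):
                count = sum(
                    1
                    for seq in itertools.product((0, 1), repeat=n)
                    if sum(seq) >= k
                )
                assert g.sign_test(k, n) == pytest.approx(count / 2**n)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            g.sign_test(11, 10)


class TestCrossValidation:
    def _planted_pair(self, n=3000, seed=54):
        specs = [SNPSpec(f"s{j}", "1", j + 1, "A", "G", 0.3) for j in range(4)]
        gm = g.simulate_genotypes(n, specs, seed=seed)
        model = g.DiseaseModel(
            epistasis_terms=[g.EpistasisTerm("s0", "s1", both_carrier_cells(1.2))],
            prevalence_target=0.5,
        )
        ct = g.simulate_outcome(gm, None, model, seed=seed + 1)
        return gm, ct.data["case"].to_numpy()

    def test_deterministic_given_seed(self):
        gm, y = self._planted_pair()
        a = g.cross_validate(gm.dosage[["s0", "s1"]], y, seed=1)
        b = g.cross_validate(gm.dosage[["s0", "s1"]], y, seed=1)
        assert a == b
        c = g.cross_validate(gm.dosage[["s0", "s1"]], y, seed=2)
        assert a.teba != c.teba

    def test_planted_pair_wins_most_folds(self):
        gm, y = self._planted_pair(n=5000)
        res = g.cross_validate(gm.dosage[["s0", "s1"]], y, seed=3)
        assert res.fold_wins >= 9
        assert res.teba > 0.5

    def test_subject_order_permutation_invariance(self):
        gm, y = self._planted_pair(n=600)
        df = gm.dosage[["s0", "s1"]]
        perm = np.random.default_rng(55).permutation(len(df))
        res1 = g.cross_validate(df, y, seed=9)
        res2 = g.cross_validate(df.iloc[perm], y[perm], seed=9)
        assert res1 == res2

    def test_fold_assignment_stratified(self):
        rng = np.random.default_rng(56)
        y = (rng.random(200) < 0.1).astype(int)
        ids = [f"S{i}" for i in range(200)]
        folds = fold_assignments(ids, y, n_folds=10, seed=0)
        per_fold_cases = [y[folds == f].sum() for f in range(10)]
        assert max(per_fold_cases) - min(per_fold_cases) <= 1

    def test_fold_without_cases_advises(self):
        y = np.array([1.0] + [0.0] * 49)
        geno = pd.DataFrame({"s": np.zeros(50)}, index=[f"S{i}" for i in range(50)])
        with pytest.raises(ValueError, match="fold"):
            g.cross_validate(geno, y, n_folds=10, seed=0)

    def test_trba_exceeds_teba_on_null_and_teba_calibrated(self):
        # overfitting direction: training accuracy >= test accuracy in
        # expectation on null data; mean TEBA ~ 0.5
        rng = np.random.default_rng(57)
        trbas, tebas, sig = [], [], 0
        for s in range(100):
            geno = pd.DataFrame(
                {"a": rng.integers(0, 3, 400), "b": rng.integers(0, 3, 400)},
                index=[f"S{i}" for i in range(400)],
            ).astype(float)
            y = np.repeat([1.0, 0.0], 200)
            res = g.cross_validate(geno, y, seed=s)
            trbas.append(res.trba)
            tebas.append(res.teba)
            sig += res.sign_p < 0.05
        assert np.mean(trbas) > np.mean(tebas)
        assert np.mean(tebas) == pytest.approx(0.5, abs=0.02)
        # null genotypes rarely reach sign-test significance
        assert sig <= 10


class TestSearch:
    def test_exhaustive_pair_count(self):
        specs = [SNPSpec(f"s{j}", "1", j + 1, "A", "G", 0.3) for j in range(10)]
        gm = g.simulate_genotypes(400, specs, seed=58)
        y = np.repeat([1.0, 0.0], 200)
        res = g.search_best_models(gm.dosage, y, k_range=[2], seed=1)
        assert res[0].n_evaluated == 45  # C(10,2)

    def test_single_causal_snp_found_at_k1(self):
        specs = [SNPSpec(f"s{j}", "1", j + 1, "A", "G", 0.3) for j in range(6)]
        gm = g.simulate_genotypes(4000, specs, seed=59)
        model = g.DiseaseModel(snp_log_or={"s3": 0.8}, prevalence_target=0.5)
        ct = g.simulate_outcome(gm, None, model, seed=60)
        res = g.search_best_models(gm.dosage, ct.data["case"].to_numpy(), k_range=[1], seed=2)
        assert res[0].snps == ("s3",)

    def test_k_above_m_rejected(self):
        gm = g.simulate_genotypes(100, [SNPSpec("s", "1", 1, "A", "G", 0.3)], seed=61)
        with pytest.raises(ValueError, match="exceeds"):
            g.search_best_models(gm.dosage, np.repeat([1.0, 0.0], 50), k_range=[2])

    def test_forward_strategy_produces_nested_models(self):
        specs = [SNPSpec(f"s{j}", "1", j + 1, "A", "G", 0.3) for j in range(5)]
        gm = g.simulate_genotypes(1000, specs, seed=62)
        y = np.repeat([1.0, 0.0], 500)
        res = g.search_best_models(gm.dosage, y, k_range=[1, 2, 3], seed=3, strategy="forward")
        sets = [set(r.snps) for r in res]
        assert sets[0] <= sets[1] <= sets[2]

    def test_results_table_shape(self):
        specs = [SNPSpec(f"s{j}", "1", j + 1, "A", "G", 0.3) for j in range(4)]
        gm = g.simulate_genotypes(600, specs, seed=63)
        y = np.repeat([1.0, 0.0], 300)
        res = g.search_best_models(gm.dosage, y, k_range=[1, 2], seed=4)
        table = results_table(res)
        assert list(table.columns) == [
            "k", "model", "trba", "teba", "fold_wins", "sign_p", "cvc", "n_evaluated",
        ]
        assert (table["cvc"].str.endswith("/10")).all()


class TestEstimator:
    def test_sklearn_get_set_params_clone(self):
        from sklearn.base import clone

        est = GMDRSearch(k_min=1, k_max=2, seed=5)
        params = est.get_params()
        assert params["k_max"] == 2
        est2 = clone(est).set_params(seed=9)
        assert est2.seed == 9

    def test_fit_predict_recovers_high_risk_cells(self):
        specs = [SNPSpec(f"s{j}", "1", j + 1, "A", "G", 0.35) for j in range(3)]
        gm = g.simulate_genotypes(4000, specs, seed=64)
        model = g.DiseaseModel(
            epistasis_terms=[g.EpistasisTerm("s0", "s1", both_carrier_cells(1.5))],
            prevalence_target=0.5,
        )
        ct = g.simulate_outcome(gm, None, model, seed=65)
        y = ct.data["case"].to_numpy()
        est = GMDRSearch(k_min=2, k_max=2, seed=6).fit(gm.dosage, y)
        assert set(est.best_snps_) == {"s0", "s1"}
        pred = est.predict(gm.dosage)
        from sklearn.metrics import balanced_accuracy_score

        assert balanced_accuracy_score(y, pred) > 0.55


def test_cell_codes_missing_genotype_excluded():
    geno = np.array([[0.0, 1.0], [np.nan, 2.0], [2.0, 0.0]])
    codes = _cell_codes(geno)
    assert codes[1] == -1
    assert codes[0] == 0 + 3 * 1
    assert codes[2] == 2
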