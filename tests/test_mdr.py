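"""MDR cells, cross-validation, model selection, and the interaction scan."""

import itertools

import numpy as np
import pytest

from genemdr.mdr import (
    MdrCvResult,
    classify_interaction,
    encode_cells,
    enumerate_snp_combinations,
    mdr_cross_validate,
    mdr_evaluate,
    mdr_permutation_test,
    mdr_train_cells,
    order_champions,
    run_interaction_scan,
    select_best_model,
    stratified_folds,
)
from conftest import make_dataset


# ---------------------------------------------------------------------------
# independent brute-force implementation (dicts and explicit loops)
# ---------------------------------------------------------------------------

def brute_force_cv(genotypes, case_mask, combos, fold_id, folds, balanced=True):
    """Plain-python re-implementation: cell dicts + confusion matrices."""
    out = {}
    for combo in combos:
        accs = []
        for f in range(folds):
            train = fold_id != f
            cells = {}
            for i in np.flatnonzero(train):
                key = tuple(genotypes[i, list(combo)])
                ca, co = cells.get(key, (0, 0))
                cells[key] = (ca + (1 if case_mask[i] else 0), co + (0 if case_mask[i] else 1))
            n_case_tr = sum(ca for ca, _ in cells.values())
            n_ctrl_tr = sum(co for _, co in cells.values())
            high = {
                key: ca * n_ctrl_tr >= n_case_tr * co
                for key, (ca, co) in cells.items()
            }
            tp = tn = fp = fn = 0
            for i in np.flatnonzero(~train):
                key = tuple(genotypes[i, list(combo)])
                pred_case = high.get(key, False)
                if case_mask[i]:
                    tp += pred_case
                    fn += not pred_case
                else:
                    fp += pred_case
                    tn += not pred_case
            if balanced:
                sens = tp / (tp + fn) if tp + fn else 0.0
                spec = tn / (tn + fp) if tn + fp else 0.0
                accs.append(0.5 * (sens + spec))
            else:
                accs.append((tp + tn) / (tp + tn + fp + fn))
        out[combo] = accs
    return out


# ---------------------------------------------------------------------------
# unit behaviour
# ---------------------------------------------------------------------------

class TestEnumeration:
    @pytest.mark.parametrize(
        "n_snps, expected",
        [(5, 5 + 10 + 10 + 5), (8, 8 + 28 + 56 + 70), (2, 3)],
    )
    def test_combination_counts(self, n_snps, expected):
        assert len(enumerate_snp_combinations(range(n_snps))) == expected

    def test_deterministic_order(self):
        combos = enumerate_snp_combinations([3, 1, 2], max_order=2)
        assert combos == [(1,), (2,), (3,), (1, 2), (1, 3), (2, 3)]


class TestCellsAndEvaluation:
    def test_balanced_fold_ratio_rule(self):
        cells = np.array([0, 0, 0, 0, 1, 1])
        case = np.array([1, 1, 1, 0, 0, 0], dtype=bool)  # T = 1
        ca, co, high = mdr_train_cells(cells, case, 2)
        assert high.tolist() == [True, False]  # 3:1 high, 0:2 low

    def test_tie_cell_labelled_high(self):
        cells = np.array([0, 0, 1, 1])
        case = np.array([1, 0, 1, 0], dtype=bool)
        _, _, high = mdr_train_cells(cells, case, 2)
        assert high.tolist() == [True, True]

    def test_empty_cell_not_high(self):
        cells = np.array([0, 0])
        case = np.array([1, 0], dtype=bool)
        _, _, high = mdr_train_cells(cells, case, 3)
        assert high.tolist() == [True, False, False]

    def test_all_high_rule_scores_half(self):
        high = np.ones(9, dtype=bool)
        cells = np.arange(9) % 9
        case = np.array([True, False] * 4 + [True])
        assert mdr_evaluate(high, cells, case) == 0.5

    def test_noiseless_xor_scores_one(self):
        g = np.array(list(itertools.product([0, 1, 2], repeat=2)), dtype=np.int8)
        g = np.repeat(g, 4, axis=0)
        case = ((g[:, 0] + g[:, 1]) % 2 == 1)
        cells = encode_cells(g, (0, 1))
        _, _, high = mdr_train_cells(cells, case, 9)
        assert mdr_evaluate(high, cells, case) == 1.0

    def test_evaluation_matches_confusion_matrix_oracle(self):
        rng = np.random.default_rng(61)
        g = rng.integers(0, 3, size=(80, 2)).astype(np.int8)
        case = rng.random(80) < 0.5
        cells = encode_cells(g, (0, 1))
        _, _, high = mdr_train_cells(cells, case, 9)
        tp = np.sum(high[cells] & case)
        fn = np.sum(~high[cells] & case)
        tn = np.sum(~high[cells] & ~case)
        fp = np.sum(high[cells] & ~case)
        expected = 0.5 * (tp / (tp + fn) + tn / (tn + fp))
        assert mdr_evaluate(high, cells, case) == pytest.approx(expected, abs=1e-12)

    def test_class_swap_maps_accuracy_to_complement(self):
        rng = np.random.default_rng(62)
        g = rng.integers(0, 3, size=(60, 2)).astype(np.int8)
        case = rng.random(60) < 0.5
        cells = encode_cells(g, (0, 1))
        _, _, high = mdr_train_cells(cells, case, 9)
        a = mdr_evaluate(high, cells, case)
        assert mdr_evaluate(high, cells, ~case) == pytest.approx(1 - a, abs=1e-12)


class TestCrossValidation:
    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(63)
        g = rng.integers(0, 3, size=(50, 4)).astype(np.int8)
        case = np.array([True] * 25 + [False] * 25)
        fold_id = stratified_folds(case, 5, np.random.default_rng(1))
        combos = enumerate_snp_combinations(range(4), max_order=3)
        mine = mdr_cross_validate(g, case, combos, folds=5, fold_id=fold_id)
        oracle = brute_force_cv(g, case, combos, fold_id, 5)
        for res in mine:
            assert res.fold_accuracy == pytest.approx(oracle[res.combo], abs=1e-12)

    def test_planted_xor_pair_wins_every_fold(self):
        rng = np.random.default_rng(64)
        g = rng.integers(0, 2, size=(200, 4)).astype(np.int8) * 2  # SNPs in {0,2}
        case = ((g[:, 0] + g[:, 1]) // 2 % 2 == 1)
        case[:3] = ~case[:3]  # tiny noise so both classes exist regardless
        combos = enumerate_snp_combinations(range(4), max_order=2)
        res = mdr_cross_validate(g, case, combos, folds=10, seed=3)
        best = select_best_model(res)
        assert best.combo == (0, 1)
        assert best.avg_testing_accuracy > 0.9
        assert best.cvc == 10

    def test_same_seed_reproduces_folds_and_results(self, null_cohort):
        combos = enumerate_snp_combinations(range(4), max_order=2)
        a = mdr_cross_validate(null_cohort.genotypes, null_cohort.case_mask, combos, seed=5)
        b = mdr_cross_validate(null_cohort.genotypes, null_cohort.case_mask, combos, seed=5)
        for x, y in zip(a, b):
            assert x.fold_accuracy == pytest.approx(y.fold_accuracy, abs=0)
            assert x.cvc == y.cvc

    def test_class_smaller_than_folds_is_error(self):
        case = np.array([True] * 3 + [False] * 30)
        with pytest.raises(ValueError, match="folds"):
            stratified_folds(case, 10, np.random.default_rng(0))


def _res(combo, acc, cvc):
    return MdrCvResult(combo=combo, fold_accuracy=np.full(10, acc),
                       avg_testing_accuracy=acc, cvc=cvc)


class TestSelectionAndClassification:
    def test_highest_accuracy_wins(self):
        results = [_res((0,), 0.52, 5), _res((1, 2), 0.61, 5), _res((3,), 0.58, 5)]
        assert select_best_model(results).combo == (1, 2)

    def test_accuracy_tie_broken_by_cvc(self):
        results = [_res((0, 1), 0.6, 6), _res((2, 3), 0.6, 9)]
        assert select_best_model(results).combo == (2, 3)

    def test_single_candidate_returned(self):
        assert select_best_model([_res((4,), 0.5, 1)]).combo == (4,)

    def test_order_champions_pick_max_cvc_per_order(self):
        results = [
            _res((0,), 0.55, 2), _res((1,), 0.50, 8),
            _res((0, 1), 0.60, 3), _res((0, 2), 0.58, 7),
        ]
        champs = order_champions(results)
        assert [c.combo for c in champs] == [(1,), (0, 2)]

    def test_order1_best_is_no_within_gene_interaction(self):
        ok, reason = classify_interaction(
            _res((0,), 0.6, 10), "within", {0: "A"}, ("A",), folds=10
        )
        assert not ok and "order-1" in reason

    def test_between_requires_spanning_both_genes(self):
        gene_of = {0: "A", 1: "A", 2: "B"}
        ok, reason = classify_interaction(
            _res((0, 1), 0.6, 10), "between", gene_of, ("A", "B"), folds=10
        )
        assert not ok and "span" in reason
        ok, _ = classify_interaction(
            _res((0, 2), 0.6, 10), "between", gene_of, ("A", "B"), folds=10
        )
        assert ok

    def test_low_consistency_fails_candidacy(self):
        gene_of = {0: "A", 2: "B"}
        ok, reason = classify_interaction(
            _res((0, 2), 0.6, 7), "between", gene_of, ("A", "B"), folds=10
        )
        assert not ok and "consistency" in reason


class TestPermutationTest:
    def test_observed_above_all_permuted_gives_min_p(self):
        rng = np.random.default_rng(65)
        g = rng.integers(0, 3, size=(100, 2)).astype(np.int8)
        case = np.array([True] * 50 + [False] * 50)
        p = mdr_permutation_test(g, case, (0, 1), observed_accuracy=1.01,
                                 n_permutations=49, seed=1)
        assert p == pytest.approx(1 / 50)

    def test_same_seed_identical(self, null_cohort):
        args = (null_cohort.genotypes, null_cohort.case_mask, (0, 3), 0.55, 50)
        assert mdr_permutation_test(*args, seed=2) == mdr_permutation_test(*args, seed=2)

    def test_label_permutation_roundtrip_restores_results(self, null_cohort):
        rng = np.random.default_rng(66)
        perm = rng.permutation(null_cohort.n_samples)
        inverse = np.argsort(perm)
        g = null_cohort.genotypes
        case = null_cohort.case_mask
        combos = [(0, 4)]
        fold_id = stratified_folds(case, 10, np.random.default_rng(3))
        base = mdr_cross_validate(g, case, combos, fold_id=fold_id)
        back = mdr_cross_validate(
            g[perm][inverse], case[perm][inverse], combos, fold_id=fold_id
        )
        assert base[0].fold_accuracy == pytest.approx(back[0].fold_accuracy, abs=0)


class TestScan:
    def test_scan_covers_genes_and_pairs(self, null_cohort):
        df = run_interaction_scan(null_cohort, n_permutations=5, seed=4)
        assert (df.scope == "within").sum() == 2
        assert (df.scope == "between").sum() == 1

    def test_ten_genes_give_55_scans(self):
        rng = np.random.default_rng(67)
        g = rng.integers(0, 3, size=(60, 10)).astype(np.int8)
        d = make_dataset(g, ["case"] * 30 + ["control"] * 30,
                         genes=[f"G{k}" for k in range(10)])
        df = run_interaction_scan(d, n_permutations=2, seed=5, folds=5)
        assert (df.scope == "within").sum() == 10
        assert (df.scope == "between").sum() == 45

    def test_deterministic_given_seed(self, null_cohort):
        a = run_interaction_scan(null_cohort, n_permutations=20, seed=6)
        b = run_interaction_scan(null_cohort, n_permutations=20, seed=6)
        assert a.equals(b)

    def test_monotone_power_in_penetrance_gap(self):
        from genemdr import simulate as sim

        rates = []
        for ba in (0.52, 0.56, 0.60):
            hits = 0
            for rep in range(10):
                cfg, pools = sim.scenario_config("epistasis", 3000 + rep)
                cfg.missing_rate = 0.0
                cfg.n_case, cfg.n_control = 500, 500
                cfg.penetrance_models = [
                    sim.plant_epistasis(pools, [(0, 1), (1, 0)], target_balanced_accuracy=ba)
                ]
                d = sim.simulate_dataset(cfg, pools=pools)
                row = run_interaction_scan(d, n_permutations=50, seed=rep)
                row = row[row.scope == "between"].iloc[0]
                hits += bool(row.candidate) and row.pfdr < 0.05
            rates.append(hits)
        assert rates[0] <= rates[2]
        assert rates[2] >= 5
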