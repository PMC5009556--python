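"""Ranking evaluation: c-index, PC-index, SNR classes, ROC/AUC, precision."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cogsyn import (
    GoldStandard,
    c_index,
    evaluate_ranking,
    load_gold_standard,
    normalize_pc,
    pc_extremes,
    pc_index,
    pc_permutation_pvalue,
    precision_at_k,
    roc_curve,
    snr_classify,
)


def make_gold(eob, sem):
    n = len(eob)
    pairs = list(itertools.combinations([f"d{i}" for i in range(n)], 2))[:n]
    if len(pairs) < n:  # enough synthetic drug names for any n
        pairs = [(f"a{i}", f"b{i}") for i in range(n)]
    return GoldStandard(pd.DataFrame({
        "drug_a": [p[0] for p in pairs],
        "drug_b": [p[1] for p in pairs],
        "eob_mean": np.asarray(eob, dtype=float),
        "eob_sem": np.broadcast_to(np.asarray(sem, dtype=float), (n,)).copy(),
    }))


def brute_force_c_index(u, v):
    total = 0.0
    n = len(u)
    for q in range(n):
        for r in range(q + 1, n):
            du, dv = u[q] - u[r], v[q] - v[r]
            if du * dv > 0:
                total += 1.0
            elif du == 0 or dv == 0:
                total += 0.5
    return total / (n * (n - 1) / 2)


class TestCIndex:
    def test_perfect_concordance(self):
        u = np.arange(1, 8)
        assert c_index(u, u) == 1.0

    def test_full_discordance(self):
        u = np.arange(1, 8)
        assert c_index(u, u[::-1]) == 0.0

    def test_one_swap_example(self):
        assert c_index([1, 2, 3], [1, 3, 2]) == pytest.approx(2 / 3)

    def test_ties_contribute_half(self):
        assert c_index([1, 2, 3], [1, 1, 2]) == pytest.approx((0.5 + 1 + 1) / 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            c_index([1, 2], [1, 2, 3])

    def test_matches_brute_force_on_random_permutations(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(2, 12))
            u = rng.permutation(n) + 1
            v = rng.permutation(n) + 1
            assert c_index(u, v) == pytest.approx(brute_force_c_index(u, v))


class TestPcIndex:
    def test_tiny_sems_give_near_perfect_score(self):
        gold = make_gold([10.0, 0.0], sem=0.01)
        v = gold.table["gold_rank"].to_numpy()
        assert pc_index(gold, v) == pytest.approx(1.0, abs=1e-12)

    def test_reversal_complements_to_one(self):
        rng = np.random.default_rng(1)
        gold = make_gold(rng.normal(size=9), sem=rng.uniform(0.5, 2, 9))
        v = rng.permutation(9) + 1
        assert pc_index(gold, v) + pc_index(gold, 10 - v) == pytest.approx(1.0, abs=1e-12)

    def test_small_sem_limit_equals_c_index(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = int(rng.integers(3, 10))
            eob = rng.normal(size=n) * 5
            gap = np.min(np.abs(np.subtract.outer(eob, eob))[np.triu_indices(n, 1)])
            gold = make_gold(eob, sem=1e-9 * max(gap, 1e-6))
            v = rng.permutation(n) + 1
            u = gold.table["gold_rank"].to_numpy()
            assert pc_index(gold, v) == pytest.approx(c_index(u, v), abs=1e-9)

    def test_zero_sem_equal_eob_contributes_half(self):
        gold = make_gold([1.0, 1.0], sem=0.0)
        assert pc_index(gold, [1, 2]) == pytest.approx(0.5)

    def test_random_ranking_expectation_is_half(self):
        rng = np.random.default_rng(3)
        gold = make_gold(rng.normal(size=8), sem=rng.uniform(0.2, 1.5, 8))
        b = 1000
        vals = np.array([pc_index(gold, rng.permutation(8) + 1) for _ in range(b)])
        se = vals.std(ddof=1) / np.sqrt(b)
        assert vals.mean() == pytest.approx(0.5, abs=3 * se)


class TestPcExtremesAndNormalization:
    def test_negligible_sems_reach_limits(self):
        rng = np.random.default_rng(4)
        gold = make_gold(rng.normal(size=7) * 10, sem=1e-9)
        pc_max, pc_min = pc_extremes(gold)
        assert pc_max == pytest.approx(1.0, abs=1e-9)
        assert pc_min == pytest.approx(0.0, abs=1e-9)

    def test_two_pair_symmetry(self):
        gold = make_gold([3.0, -1.0], sem=1.0)
        pc_max, pc_min = pc_extremes(gold)
        assert pc_max == pytest.approx(1.0 - pc_min)

    def test_normalization_endpoints_and_reported_constants(self):
        assert normalize_pc(0.90, 0.90, 0.10) == pytest.approx(1.0)
        assert normalize_pc(0.10, 0.90, 0.10) == pytest.approx(0.0)
        assert normalize_pc(0.663, 0.90, 0.10) == pytest.approx(0.70375)

    def test_degenerate_gold_standard_rejected(self):
        with pytest.raises(ValueError):
            normalize_pc(0.5, 0.4, 0.4)


class TestSnrClassify:
    def test_rule(self):
        df = pd.DataFrame({
            "eob_mean": [4.0, -4.0, 1.0, 0.0],
            "eob_sem": [1.0, 1.0, 1.0, 1.0],
        })
        assert list(snr_classify(df)) == ["synergistic", "antagonistic", "additive", "additive"]

    def test_boundary_snr_of_two_is_additive(self):
        df = pd.DataFrame({"eob_mean": [2.0, -2.0], "eob_sem": [1.0, 1.0]})
        assert list(snr_classify(df)) == ["additive", "additive"]


class TestRocCurve:
    def test_perfect_separation(self):
        labels = ["synergistic"] * 3 + ["additive"] * 4
        ranks = np.arange(1, 8)
        _, auc = roc_curve(labels, ranks, positive="synergistic")
        assert auc == 1.0

    def test_inverted_ranking(self):
        labels = ["synergistic"] * 3 + ["additive"] * 4
        ranks = np.arange(7, 0, -1)
        _, auc = roc_curve(labels, ranks, positive="synergistic")
        assert auc == 0.0

    def test_interleaved_example(self):
        labels = ["synergistic", "additive", "synergistic", "additive"]
        _, auc = roc_curve(labels, [1, 2, 3, 4], positive="synergistic")
        assert auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve(["synergistic"] * 3, [1, 2, 3], positive="synergistic")

    def test_agrees_with_sklearn_auc(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(6, 25))
            labels = rng.choice(["synergistic", "additive"], size=n)
            if len(set(labels)) < 2:
                continue
            ranks = rng.permutation(n) + 1
            _, auc = roc_curve(labels, ranks, positive="synergistic")
            ref = roc_auc_score(labels == "synergistic", -ranks)
            assert auc == pytest.approx(ref)

    def test_antagonism_direction_reverses_sweep(self):
        labels = ["antagonistic", "additive", "additive", "antagonistic"]
        _, auc = roc_curve(labels, [1, 2, 3, 4], positive="antagonistic", direction="antagonism")
        # reversed order: ranks 4,3,2,1 -> labels ant, add, add, ant
        _, ref = roc_curve(labels[::-1], [1, 2, 3, 4], positive="antagonistic")
        assert auc == pytest.approx(ref)


class TestPrecisionAtK:
    def test_all_top_positive(self):
        labels = ["synergistic"] * 2 + ["additive"] * 3
        assert precision_at_k(labels, [1, 2, 3, 4, 5], 2, "synergistic") == 1.0

    def test_k_equal_n_gives_prevalence(self):
        labels = ["synergistic"] * 2 + ["additive"] * 3
        assert precision_at_k(labels, [1, 2, 3, 4, 5], 5, "synergistic") == pytest.approx(0.4)

    def test_random_ranking_expectation_matches_prevalence(self):
        # 16 positives of 91: expected precision at k=16 is 16/91 ~ 17.6 %
        rng = np.random.default_rng(6)
        labels = np.array(["synergistic"] * 16 + ["additive"] * 75)
        b = 3000
        vals = [precision_at_k(labels, rng.permutation(91) + 1, 16, "synergistic")
                for _ in range(b)]
        se = np.std(vals, ddof=1) / np.sqrt(b)
        assert np.mean(vals) == pytest.approx(16 / 91, abs=3 * se)
        assert round(100 * 16 / 91, 1) == 17.6

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            precision_at_k(["synergistic", "additive"], [1, 2], 3, "synergistic")


class TestReportAndIO:
    def test_gold_standard_roundtrip_and_report(self, tmp_path):
        rng = np.random.default_rng(7)
        eob = np.concatenate([rng.uniform(3, 6, 4), rng.uniform(-6, -3, 4), rng.normal(0, 0.5, 4)])
        gold = make_gold(eob, sem=1.0)
        path = tmp_path / "gold.tsv"
        gold.table[["drug_a", "drug_b", "eob_mean", "eob_sem"]].to_csv(path, sep="\t", index=False)
        back = load_gold_standard(path)
        assert np.allclose(back.table["eob_mean"], gold.table["eob_mean"])
        v = back.table["gold_rank"].to_numpy()
        report = evaluate_ranking(back, v, b_permutations=200, seed=0)
        assert report["c_index"] == 1.0
        assert report["pc_min"] <= report["pc_index"] <= report["pc_max"]
        assert 0.0 <= report["pc_index_norm"] <= 1.0
        assert report["pc_permutation_p"] <= 1 / 100  # perfect ranking is extreme
        assert report["n_synergistic"] + report["n_antagonistic"] + report["n_additive"] == 12

    def test_permutation_pvalue_null_behaviour(self):
        rng = np.random.default_rng(8)
        gold = make_gold(rng.normal(size=8), sem=1.0)
        ps = [pc_permutation_pvalue(gold, rng.permutation(8) + 1, 200, seed=i)
              for i in range(20)]
        assert min(ps) > 0 and max(ps) <= 1
        assert 0.2 < np.mean(ps) < 0.8  # roughly uniform under the null
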