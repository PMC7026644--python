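"""Confusion counts, MCC/sensitivity/precision, PR curves, max-MCC cutoffs."""

import math

import numpy as np
import pytest

from coda.evaluate import (
    ConfusionCounts,
    confusion,
    max_mcc_threshold,
    mcc,
    pr_curve,
    precision,
    sensitivity,
)
from coda.structures import ReferenceStructure


def naive_metrics(tp, fp, tn, fn):
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    m = (tp * tn - fp * fn) / denom if denom else 0.0
    s = tp / (tp + fn) if tp + fn else 0.0
    p = tp / (tp + fp) if tp + fp else 0.0
    return m, s, p


def naive_pr_sweep(scores, ref, L):
    """Threshold-by-threshold recomputation from scratch (the oracle)."""
    thresholds = sorted({v for v in scores.values()}, reverse=True)
    pts = []
    for t in thresholds:
        pred = {k for k, v in scores.items() if v >= t}
        tp = len(pred & ref)
        pts.append((tp / len(ref), tp / len(pred)))
    r = np.array([0.0] + [x for x, _ in pts])
    p = np.array([pts[0][1]] + [y for _, y in pts])
    return pts, float(np.trapezoid(p, r))


def naive_max_mcc(scores, ref, L):
    universe = L * (L - 1) // 2
    best = None
    for t in sorted({v for v in scores.values()}, reverse=True):
        pred = {k for k, v in scores.items() if v >= t}
        tp = len(pred & ref)
        fp = len(pred - ref)
        fn = len(ref - pred)
        tn = universe - tp - fp - fn
        m = naive_metrics(tp, fp, tn, fn)[0]
        if best is None or m > best[0]:
            best = (m, t)
    return best


def random_instance(rng, L=30, n_ref=8, n_scored=60):
    positions = [(i, j) for i in range(1, L + 1) for j in range(i + 1, L + 1)]
    ref_idx = rng.choice(len(positions), n_ref, replace=False)
    ref = set()
    used = set()
    for k in ref_idx:
        i, j = positions[k]
        if i in used or j in used:
            continue
        ref.add((i, j))
        used.update((i, j))
    scored_idx = rng.choice(len(positions), n_scored, replace=False)
    scores = {positions[k]: float(rng.normal()) for k in scored_idx}
    for pair in list(ref)[: n_ref // 2]:
        scores[pair] = float(rng.normal(1.5))
    return scores, ReferenceStructure(length=L, pairs=ref)


class TestConfusion:
    def test_near_complete_recovery_example(self):
        """26-pair reference on an 81-mer: 25 recovered plus one spurious."""
        rng = np.random.default_rng(7)
        ref_pairs = {(i, 81 - i + 1) for i in range(1, 27)}
        ref = ReferenceStructure(length=81, pairs=ref_pairs)
        predicted = set(list(sorted(ref_pairs))[:25]) | {(30, 40)}
        c = confusion(predicted, ref)
        assert (c.tp, c.fp, c.fn) == (25, 1, 1)
        assert c.tn == 81 * 80 // 2 - 27
        assert c.total == 81 * 80 // 2

    def test_perfect_prediction(self):
        ref = ReferenceStructure(length=20, pairs={(1, 20), (2, 19)})
        c = confusion(ref.pairs, ref)
        assert c.fp == c.fn == 0 and c.tp == 2

    def test_empty_prediction(self):
        ref = ReferenceStructure(length=20, pairs={(1, 20), (2, 19)})
        c = confusion(set(), ref)
        assert c.tp == 0 and c.fp == 0 and c.fn == 2

    def test_out_of_range_prediction_rejected(self):
        ref = ReferenceStructure(length=20, pairs={(1, 20)})
        with pytest.raises(ValueError):
            confusion({(1, 25)}, ref)

    @pytest.mark.parametrize("seed", range(20))
    def test_partition_identity(self, seed):
        rng = np.random.default_rng(seed)
        scores, ref = random_instance(rng)
        predicted = {k for k, v in scores.items() if v > 0}
        c = confusion(predicted, ref, length=30)
        assert c.total == 30 * 29 // 2


class TestMetrics:
    def test_worked_example_cpeb3_numbers(self):
        c = ConfusionCounts(tp=25, fp=1, tn=3213, fn=1)
        assert mcc(c) == pytest.approx(0.961, abs=5e-4)
        assert sensitivity(c) == pytest.approx(25 / 26)
        assert precision(c) == pytest.approx(25 / 26)

    def test_worked_example_twister_numbers(self):
        universe = 48 * 47 // 2
        c = ConfusionCounts(tp=14, fp=0, fn=3, tn=universe - 17)
        assert sensitivity(c) == pytest.approx(14 / 17)
        assert precision(c) == 1.0

    def test_perfect_prediction_mcc_one(self):
        assert mcc(ConfusionCounts(tp=5, fp=0, tn=100, fn=0)) == pytest.approx(1.0)

    def test_zero_denominator_returns_zero(self):
        assert mcc(ConfusionCounts(tp=0, fp=0, tn=10, fn=5)) == 0.0
        assert precision(ConfusionCounts(tp=0, fp=0, tn=10, fn=5)) == 0.0
        assert sensitivity(ConfusionCounts(tp=0, fp=0, tn=15, fn=0)) == 0.0

    def test_agrees_with_naive_formulas_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            tp, fp, tn, fn = rng.integers(0, 50, 4)
            c = ConfusionCounts(tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn))
            nm, ns, np_ = naive_metrics(int(tp), int(fp), int(tn), int(fn))
            assert mcc(c) == pytest.approx(nm)
            assert sensitivity(c) == pytest.approx(ns)
            assert precision(c) == pytest.approx(np_)


class TestPRCurve:
    def test_perfect_ranking_gives_unit_area(self):
        ref = ReferenceStructure(length=20, pairs={(1, 20), (2, 19), (3, 18)})
        scores = {(1, 20): 3.0, (2, 19): 2.5, (3, 18): 2.0, (5, 10): -1.0, (6, 11): -2.0}
        _, auc = pr_curve(scores, ref)
        assert auc == pytest.approx(1.0)

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(3)
        L = 60
        pairs = {(i, L - i + 1) for i in range(1, 13)}
        ref = ReferenceStructure(length=L, pairs=pairs)
        positions = [(i, j) for i in range(1, L + 1) for j in range(i + 1, L + 1)]
        aucs = []
        for _ in range(20):
            scores = {pos: float(rng.normal()) for pos in positions}
            aucs.append(pr_curve(scores, ref)[1])
        prevalence = len(pairs) / len(positions)
        assert np.mean(aucs) == pytest.approx(prevalence, rel=0.5)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_brute_force_sweep(self, seed):
        rng = np.random.default_rng(seed)
        scores, ref = random_instance(rng)
        curve, auc = pr_curve(scores, ref)
        naive_curve, naive_auc = naive_pr_sweep(scores, ref.pairs, 30)
        assert auc == pytest.approx(naive_auc, abs=1e-9)
        assert curve == pytest.approx(naive_curve)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(11)
        scores, ref = random_instance(rng)
        _, auc = pr_curve(scores, ref)
        warped = {k: math.exp(3 * v) + 1 for k, v in scores.items()}
        _, auc2 = pr_curve(warped, ref)
        assert auc2 == pytest.approx(auc, abs=1e-12)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            pr_curve({(1, 5): 1.0}, ReferenceStructure(length=10, pairs=set()))


class TestMaxMCC:
    def test_perfect_separation(self):
        ref = ReferenceStructure(length=20, pairs={(1, 20), (2, 19)})
        scores = {(1, 20): 5.0, (2, 19): 4.0, (3, 10): -1.0}
        threshold, counts = max_mcc_threshold(scores, ref)
        assert mcc(counts) == pytest.approx(1.0)
        assert threshold == pytest.approx(4.0)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_exhaustive_sweep(self, seed):
        rng = np.random.default_rng(1000 + seed)
        scores, ref = random_instance(rng)
        threshold, counts = max_mcc_threshold(scores, ref, length=30)
        naive_best, naive_t = naive_max_mcc(scores, ref.pairs, 30)
        assert mcc(counts) == pytest.approx(naive_best, abs=1e-9)
        assert threshold == pytest.approx(naive_t)

    def test_tie_resolves_to_sparser_prediction(self):
        ref = ReferenceStructure(length=20, pairs={(1, 20)})
        # both cutoffs give MCC below 1; equal-MCC cutoffs pick the larger
        scores = {(1, 20): 5.0, (2, 19): 5.0}
        threshold, _ = max_mcc_threshold(scores, ref)
        assert threshold == 5.0

    def test_single_true_scored_pair_positive_mcc(self):
        ref = ReferenceStructure(length=20, pairs={(1, 20), (3, 18)})
        threshold, counts = max_mcc_threshold({(1, 20): 2.0}, ref)
        assert mcc(counts) > 0
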