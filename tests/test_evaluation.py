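"""Metrics against brute-force oracles and sklearn cross-checks."""
import numpy as np
import pytest
from sklearn.metrics import average_precision_score, roc_auc_score

from chromaloop.evaluation import (
    EvalSpec,
    average_precision,
    chip_inner_product_baseline,
    evaluate,
    evaluate_scores,
    pr_curve,
    roc_auc,
    sample_negatives,
    topn_accuracy,
)
from chromaloop.labeling import BandSpec


def brute_force_ap(scores, labels):
    """Precision at each positive's rank, by explicit iteration (same
    deterministic tie order as the implementation: stable sort on -score)."""
    order = np.argsort(-np.asarray(scores, float), kind="stable")
    y = np.asarray(labels)[order]
    precisions, tp = [], 0
    for rank, yi in enumerate(y, start=1):
        if yi:
            tp += 1
            precisions.append(tp / rank)
    return float(np.mean(precisions))


def brute_force_auc(scores, labels):
    """All positive-negative pairs, half credit for ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels) > 0
    pos, neg = scores[labels], scores[~labels]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (pos.size * neg.size)


class TestAveragePrecision:
    def test_worked_example(self):
        assert average_precision([0.9, 0.8, 0.7], [1, 0, 1]) == pytest.approx(
            (1 + 2 / 3) / 2
        )

    def test_perfect_ranking(self):
        assert average_precision([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_single_positive_ranked_last(self):
        m = 25
        scores = np.linspace(1, 0, m)
        labels = np.zeros(m)
        labels[-1] = 1
        assert average_precision(scores, labels) == pytest.approx(1 / m)

    def test_requires_a_positive(self):
        with pytest.raises(ValueError):
            average_precision([0.5], [0])


class TestRocAuc:
    def test_worked_example(self):
        assert roc_auc([0.9, 0.8, 0.7], [1, 0, 1]) == pytest.approx(0.5)

    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores(self):
        assert roc_auc([0.4] * 6, [1, 0, 1, 0, 0, 0]) == pytest.approx(0.5)

    def test_requires_both_classes(self):
        with pytest.raises(ValueError):
            roc_auc([0.5, 0.6], [1, 1])


class TestOracleAgreement:
    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            m = int(rng.integers(5, 200))
            # discrete score levels force plenty of ties
            scores = rng.integers(0, 8, size=m) / 7.0
            labels = (rng.random(m) < 0.3).astype(int)
            if labels.sum() in (0, m):
                labels[0], labels[-1] = 1, 0
            assert average_precision(scores, labels) == pytest.approx(
                brute_force_ap(scores, labels), abs=1e-12
            )
            assert roc_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_matches_sklearn_on_tie_free_scores(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            m = int(rng.integers(10, 150))
            scores = rng.permutation(np.linspace(0.01, 0.99, m))
            labels = (rng.random(m) < 0.4).astype(int)
            if labels.sum() in (0, m):
                labels[0], labels[-1] = 1, 0
            assert average_precision(scores, labels) == pytest.approx(
                average_precision_score(labels, scores), abs=1e-10
            )
            assert roc_auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-10
            )


class TestPrCurve:
    def test_recall_nondecreasing_and_endpoint(self):
        rng = np.random.default_rng(2)
        scores = rng.random(60)
        labels = (rng.random(60) < 0.3).astype(int)
        labels[0] = 1
        curve = pr_curve(scores, labels)
        recalls = [r for r, _ in curve]
        assert recalls == sorted(recalls)
        assert recalls[-1] == pytest.approx(1.0)


class TestTopNAccuracy:
    def _ranked(self, flags):
        return [(0, k + 2, 1.0 - 0.01 * k) for k in range(len(flags))]

    def test_perfect_predictor(self):
        lab = np.zeros((10, 10))
        lab[0, 2] = lab[0, 3] = 1
        ranked = [(0, 2, 0.9), (0, 3, 0.8), (0, 4, 0.1), (0, 5, 0.05)]
        assert topn_accuracy(ranked, lab) == 100.0

    def test_positives_at_ranks_one_and_three(self):
        lab = np.zeros((10, 10))
        lab[0, 2] = lab[0, 4] = 1
        ranked = [(0, 2, 0.9), (0, 3, 0.8), (0, 4, 0.7), (0, 5, 0.6)]
        assert topn_accuracy(ranked, lab, N=2) == 50.0

    def test_no_positives_in_top_n(self):
        lab = np.zeros((10, 10))
        lab[0, 5] = 1
        ranked = [(0, 2, 0.9), (0, 3, 0.8), (0, 5, 0.1)]
        assert topn_accuracy(ranked, lab, N=2) == 0.0

    def test_default_n_equals_recall_at_p(self):
        rng = np.random.default_rng(3)
        lab = np.zeros((30, 30))
        pix = [(i, j) for i in range(30) for j in range(i + 2, 30)]
        flags = rng.random(len(pix)) < 0.2
        for (i, j), f in zip(pix, flags):
            lab[i, j] = int(f)
        scores = rng.random(len(pix))
        order = np.argsort(-scores)
        ranked = [(pix[k][0], pix[k][1], scores[k]) for k in order]
        P = int(flags.sum())
        expected = 100.0 * sum(lab[i, j] for i, j, _ in ranked[:P]) / P
        assert topn_accuracy(ranked, lab) == pytest.approx(expected)

    def test_invalid_n_rejected(self):
        lab = np.zeros((5, 5))
        lab[0, 2] = 1
        with pytest.raises(ValueError):
            topn_accuracy([(0, 2, 0.5)], lab, N=0)


class TestSampleNegatives:
    def _mask_and_labels(self, n_pos=10, n_pix=500):
        lab = np.zeros((60, 60))
        pix = [(i, j) for i in range(60) for j in range(i + 2, 60)][:n_pix]
        for i, j in pix[:n_pos]:
            lab[i, j] = 1
        return lab, set(pix)

    def test_five_pos_draws_five_times_positives(self):
        lab, mask = self._mask_and_labels()
        rng = np.random.default_rng(0)
        ni, nj = sample_negatives(lab, mask, "5pos", rng)
        assert ni.size == 50
        assert not lab[ni, nj].any()

    def test_all_mode_returns_every_negative(self):
        lab, mask = self._mask_and_labels()
        ni, _ = sample_negatives(lab, mask, "all", np.random.default_rng(0))
        assert ni.size == 490

    def test_capped_when_request_exceeds_available(self):
        lab, mask = self._mask_and_labels(n_pos=10, n_pix=100)
        ni, _ = sample_negatives(lab, mask, "100pos", np.random.default_rng(0))
        assert ni.size == 90  # capped at available negatives

    def test_no_positives_raises(self):
        lab = np.zeros((10, 10))
        with pytest.raises(ValueError, match="no positives"):
            sample_negatives(lab, {(0, 2)}, "pos", np.random.default_rng(0))


class TestChipInnerProductBaseline:
    def test_constant_track_interior_pixel(self):
        chip = np.ones(100)
        scores = chip_inner_product_baseline(chip, {(40, 60)})
        assert scores[0] == pytest.approx(11.0)

    def test_zero_track(self):
        scores = chip_inner_product_baseline(np.zeros(50), {(10, 20), (12, 30)})
        assert (scores == 0).all()

    def test_left_clipped_window(self):
        # i=2 clips offsets to [-2, 5]: 8 surviving terms on a constant track
        chip = np.ones(100)
        scores = chip_inner_product_baseline(chip, {(2, 50)})
        assert scores[0] == pytest.approx(8.0)

    def test_matches_direct_sum(self):
        rng = np.random.default_rng(4)
        chip = rng.random(80)
        mask = {(5, 30), (0, 75), (40, 79), (10, 12)}
        scores = chip_inner_product_baseline(chip, mask)
        for (i, j), s in zip(sorted(mask), scores):
            direct = sum(
                chip[i + a] * chip[j + a]
                for a in range(-5, 6)
                if 0 <= i + a < 80 and 0 <= j + a < 80
            )
            assert s == pytest.approx(direct)


class TestEvaluate:
    def test_labels_as_scores_are_perfect(self):
        rng = np.random.default_rng(5)
        n = 80
        lab = np.zeros((n, n))
        iu = np.triu_indices(n, 2)
        pos = rng.choice(iu[0].size, 30, replace=False)
        lab[iu[0][pos], iu[1][pos]] = 1
        lab = np.maximum(lab, lab.T)
        spec = EvalSpec(band=BandSpec(2, 40), seed=0, n_repeats=3)
        rep = evaluate(lab.astype(float), lab, spec)
        for mode in spec.neg_modes:
            assert rep[mode].ap == pytest.approx(1.0)
            assert rep[mode].auc == pytest.approx(1.0)

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(6)
        n = 100
        lab = np.zeros((n, n))
        iu = np.triu_indices(n, 2)
        pos = rng.choice(iu[0].size, 60, replace=False)
        lab[iu[0][pos], iu[1][pos]] = 1
        lab = np.maximum(lab, lab.T)
        scores = rng.random((n, n))
        spec = EvalSpec(band=BandSpec(2, 60), neg_modes=("all",), seed=0)
        rep = evaluate(scores, lab, spec)
        assert rep["all"].auc == pytest.approx(0.5, abs=0.07)

    def test_unmappable_pixels_excluded(self):
        n = 40
        lab = np.zeros((n, n))
        lab[5, 10] = lab[10, 5] = 1
        scores = np.zeros((n, n))
        spec = EvalSpec(band=BandSpec(2, 20), seed=0, n_repeats=2)
        # excluding bin 5 removes the only positive -> error
        with pytest.raises(ValueError, match="no positives"):
            evaluate(scores, lab, spec, unmappable={5})
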