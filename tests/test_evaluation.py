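"""Metric hub tests: confusion counts, scalar metrics, areas, AUC, error masks."""

import numpy as np
import pytest

from burntseg.evaluation import (ConfusionCounts, area_stats, burnt_fraction,
                                 confusion, error_mask, metrics,
                                 normalized_confusion, pixels_to_hectares,
                                 probabilities_to_mask, roc_auc)

# published confusion counts for the two models (pixels)
UNET_COUNTS = ConfusionCounts(tp=4_719_050, fp=199_264, fn=365_344, tn=27_101_423)
GRU_COUNTS = ConfusionCounts(tp=4_911_715, fp=142_747, fn=172_679, tn=27_157_940)


def brute_force_auc(scores, labels):
    """All-pairs concordance oracle: ties count 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_agreement_all_burnt(self):
        m = np.ones((3, 3), dtype=np.uint8)
        c = confusion(m, m)
        assert (c.tp, c.fp, c.fn, c.tn) == (9, 0, 0, 0)

    def test_total_miss(self):
        c = confusion(np.zeros((3, 3), np.uint8), np.ones((3, 3), np.uint8))
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 9, 0)

    def test_four_pixel_enumeration(self):
        c = confusion(np.array([1, 0, 1, 1]), np.array([1, 1, 0, 1]))
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 1, 1, 0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.array([0, 2]), np.array([0, 1]))

    def test_tally_exhaustive_on_random_masks(self, rng):
        pred = (rng.random((17, 13)) > 0.5).astype(np.uint8)
        ref = (rng.random((17, 13)) > 0.7).astype(np.uint8)
        c = confusion(pred, ref)
        assert c.total == pred.size


class TestMetrics:
    def test_published_counts_reproduce_printed_metrics(self):
        m = metrics(UNET_COUNTS)
        assert round(m["precision"], 3) == 0.959
        assert round(m["recall"], 3) == 0.928
        assert round(m["accuracy"], 3) == 0.983
        assert round(m["dice"], 3) == 0.944
        assert round(m["iou_burnt"], 3) == 0.893

    def test_f1_equals_dice_identity(self, rng):
        for _ in range(50):
            tp, fp, fn, tn = rng.integers(1, 1000, size=4)
            m = metrics(ConfusionCounts(int(tp), int(fp), int(fn), int(tn)))
            assert m["f1"] == pytest.approx(m["dice"], abs=1e-12)

    def test_degenerate_class_gives_nan_not_zero(self):
        m = metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=5))
        assert m["accuracy"] == 1.0
        assert np.isnan(m["precision"])
        assert np.isnan(m["recall"])

    def test_self_comparison_is_perfect(self, rng):
        mask = (rng.random((20, 20)) > 0.5).astype(np.uint8)
        m = metrics(confusion(mask, mask))
        assert m["precision"] == m["recall"] == m["accuracy"] == 1.0


class TestNormalizedConfusion:
    @pytest.mark.parametrize("counts,expected", [
        (UNET_COUNTS, (0.837, 0.006, 0.011, 0.146)),
        (GRU_COUNTS, (0.839, 0.004, 0.005, 0.152)),
    ])
    def test_published_normalized_rows(self, counts, expected):
        n = normalized_confusion(counts)
        assert (round(n["tn"], 3), round(n["fp"], 3),
                round(n["fn"], 3), round(n["tp"], 3)) == expected

    def test_sums_to_one_and_roundtrips(self, rng):
        tp, fp, fn, tn = (int(v) for v in rng.integers(1, 10_000, size=4))
        c = ConfusionCounts(tp, fp, fn, tn)
        n = normalized_confusion(c)
        assert sum(n.values()) == pytest.approx(1.0, abs=1e-12)
        assert round(n["tp"] * c.total) == tp


class TestBurntFraction:
    def test_reference_fraction_of_published_counts(self):
        assert round(burnt_fraction(UNET_COUNTS, "reference"), 1) == 15.7

    def test_predicted_fractions_of_published_counts(self):
        assert round(burnt_fraction(UNET_COUNTS, "predicted"), 2) == 15.19
        assert round(burnt_fraction(GRU_COUNTS, "predicted"), 2) == 15.61


class TestAreaStats:
    def test_pixel_to_hectare_conversion_3m(self):
        assert round(pixels_to_hectares(3_711_195, 3.0), 2) == 3340.08
        assert round(pixels_to_hectares(655_001, 3.0), 2) == 589.50

    def test_empty_mask(self):
        s = area_stats(np.zeros((4, 4), np.uint8))
        assert s["burnt_ha"] == 0.0 and s["burnt_pct"] == 0.0

    def test_counts_partition_the_mask(self, rng):
        mask = (rng.random((30, 30)) > 0.8).astype(np.uint8)
        s = area_stats(mask, 3.0)
        assert s["burnt_pixels"] + s["unburnt_pixels"] == mask.size


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1])) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc(np.full(6, 0.3), np.array([0, 1, 0, 1, 0, 1])) == 0.5

    def test_hand_computed_four_points(self):
        auc = roc_auc(np.array([0.1, 0.4, 0.35, 0.8]), np.array([0, 0, 1, 1]))
        assert auc == pytest.approx(0.75)

    def test_matches_brute_force_concordance(self, rng):
        for _ in range(25):
            n = int(rng.integers(10, 200))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.random(n), 2)  # force ties
            assert roc_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12)

    def test_label_complement_symmetry(self, rng):
        scores = rng.random(60)
        labels = rng.integers(0, 2, size=60)
        assert roc_auc(scores, labels) + roc_auc(scores, 1 - labels) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_curve_is_returned(self):
        auc, (fpr, tpr) = roc_auc(np.array([0.1, 0.4, 0.35, 0.8]),
                                  np.array([0, 0, 1, 1]), return_curve=True)
        assert fpr[0] == 0.0 and tpr[-1] == 1.0


class TestErrorMask:
    def test_no_errors_when_masks_agree(self, rng):
        m = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        em = error_mask(m, m)
        assert not np.any((em == 1) | (em == 2))  # no FP, no FN

    def test_toy_four_pixel_placement(self):
        em = error_mask(np.array([1, 0, 1, 1]), np.array([1, 1, 0, 1]))
        assert em.tolist() == [3, 2, 1, 3]  # TP, FN, FP, TP

    def test_category_counts_equal_confusion(self, rng):
        pred = (rng.random((40, 40)) > 0.5).astype(np.uint8)
        ref = (rng.random((40, 40)) > 0.5).astype(np.uint8)
        em = error_mask(pred, ref)
        c = confusion(pred, ref)
        assert (np.sum(em == 3), np.sum(em == 1), np.sum(em == 2),
                np.sum(em == 0)) == (c.tp, c.fp, c.fn, c.tn)


class TestProbabilitiesToMask:
    def test_argmax_with_ties_toward_unburnt(self):
        probs = np.array([[[0.3, 0.7], [0.5, 0.5], [0.6, 0.4]]])
        assert probabilities_to_mask(probs).tolist() == [[1, 0, 0]]
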