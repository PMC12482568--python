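"""Loss arithmetic, metrics vs brute force, voting, run statistics, loop."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from histofusion import nn
from histofusion.training import (LeakageError, TileDataset, TrainRecipe,
                                  compare_runs, compute_metrics,
                                  cross_entropy, effect_size_label,
                                  majority_vote, paired_t_and_effect, train,
                                  vote_by_image)
from histofusion.data import TileRecord


# ------------------------------------------------------------ cross entropy

def test_uniform_logits_loss_is_log_of_class_count():
    logits = nn.Tensor(np.zeros((3, 4), np.float32))
    loss = cross_entropy(logits, np.array([0, 1, 3]))
    assert loss.item() == pytest.approx(math.log(4), rel=1e-6)
    assert loss.item() == pytest.approx(1.38629, abs=1e-5)


def test_single_sample_loss_matches_hand_arithmetic():
    # logits (2,0,0,0), true class 0: -2 + ln(e^2 + 3)
    logits = nn.Tensor(np.array([[2.0, 0.0, 0.0, 0.0]], np.float32))
    loss = cross_entropy(logits, np.array([0]))
    assert loss.item() == pytest.approx(-2 + math.log(math.exp(2) + 3),
                                        rel=1e-6)
    assert loss.item() == pytest.approx(0.34075, abs=1e-5)


def test_batch_loss_is_mean_of_per_sample_losses(rng):
    logits = rng.normal(0, 2, (6, 5)).astype(np.float32)
    labels = rng.integers(0, 5, 6)
    batch = cross_entropy(nn.Tensor(logits), labels).item()
    singles = [cross_entropy(nn.Tensor(logits[i:i + 1]), labels[i:i + 1])
               .item() for i in range(6)]
    assert batch == pytest.approx(np.mean(singles), rel=1e-5)


def test_cross_entropy_rejects_non_finite_logits():
    bad = np.array([[np.inf, 0.0]], np.float32)
    with pytest.raises(ValueError):
        cross_entropy(nn.Tensor(bad), np.array([0]))


def test_cross_entropy_rejects_out_of_range_labels():
    with pytest.raises(ValueError):
        cross_entropy(nn.Tensor(np.zeros((1, 3), np.float32)), np.array([3]))


# ----------------------------------------------------------------- metrics

def test_perfect_predictions_score_one_everywhere():
    labels = np.array([0, 1, 2, 3] * 5)
    probs = np.eye(4)[labels]
    m = compute_metrics(probs, labels)
    assert m.accuracy == 1.0
    assert m.macro_precision == m.macro_recall == m.macro_f1 == 1.0
    assert m.auc_micro == 1.0
    assert all(v == 1.0 for v in m.auc_per_class.values())


def test_binary_confusion_example_matches_hand_values():
    # TP=8, FP=2, FN=2, TN=8 for class 1
    labels = np.array([1] * 10 + [0] * 10)
    preds = np.array([1] * 8 + [0] * 2 + [0] * 8 + [1] * 2)
    probs = np.stack([1.0 - preds, preds], axis=1).astype(float)
    m = compute_metrics(probs, labels)
    assert m.per_class[1]["precision"] == pytest.approx(0.8)
    assert m.per_class[1]["recall"] == pytest.approx(0.8)
    assert m.per_class[1]["f1"] == pytest.approx(0.8)
    assert m.accuracy == pytest.approx(0.8)


def test_metrics_agree_with_brute_force_counter(rng):
    C = 4
    labels = rng.integers(0, C, 300)
    probs = rng.random((300, C))
    probs /= probs.sum(axis=1, keepdims=True)
    m = compute_metrics(probs, labels)
    preds = probs.argmax(axis=1)
    # independent brute-force confusion counting
    for c in range(C):
        tp = int(np.sum((labels == c) & (preds == c)))
        fp = int(np.sum((labels != c) & (preds == c)))
        fn = int(np.sum((labels == c) & (preds != c)))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        assert m.per_class[c]["precision"] == pytest.approx(prec)
        assert m.per_class[c]["recall"] == pytest.approx(rec)
    assert m.accuracy == pytest.approx(np.mean(preds == labels))
    assert m.accuracy == pytest.approx(np.trace(m.confusion)
                                       / m.confusion.sum())
    # confusion marginals match label/prediction counts
    np.testing.assert_array_equal(m.confusion.sum(axis=1),
                                  np.bincount(labels, minlength=C))
    np.testing.assert_array_equal(m.confusion.sum(axis=0),
                                  np.bincount(preds, minlength=C))


def test_absent_class_recall_reported_zero_with_warning():
    labels = np.array([0, 0, 1, 1])
    probs = np.eye(3)[labels]
    with pytest.warns(UserWarning, match="absent"):
        m = compute_metrics(probs, labels)
    assert m.per_class[2]["recall"] == 0.0


# ----------------------------------------------------------- majority vote

def test_strict_majority_wins():
    assert majority_vote(np.array([2, 2, 1, 2])) == 2


def test_single_patch_is_its_own_label():
    assert majority_vote(np.array([3])) == 3


def test_tie_broken_by_mean_probability():
    labels = np.array([1, 1, 2, 2])
    probs = np.array([[0.0, 0.6, 0.4],
                      [0.0, 0.5, 0.5],
                      [0.0, 0.2, 0.7],
                      [0.0, 0.3, 0.8]])
    # mean prob class 1 = 0.4, class 2 = 0.6 -> class 2
    assert majority_vote(labels, probs) == 2


def test_full_tie_falls_back_to_lowest_class_id():
    labels = np.array([1, 2])
    probs = np.array([[0.0, 0.5, 0.5], [0.0, 0.5, 0.5]])
    assert majority_vote(labels, probs) == 1


def test_empty_group_raises():
    with pytest.raises(ValueError):
        majority_vote(np.array([]))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.integers(0, 3), min_size=1, max_size=30))
def test_vote_matches_brute_force_count(votes):
    votes = np.array(votes)
    got = majority_vote(votes)
    counts = {c: int((votes == c).sum()) for c in set(votes.tolist())}
    best = max(counts.values())
    tied = sorted(c for c, n in counts.items() if n == best)
    assert got == tied[0]  # no probs -> lowest tied class id


def test_vote_by_image_groups_correctly():
    image_ids = np.array(["a", "a", "a", "b"])
    labels = np.array([0, 1, 1, 2])
    out = vote_by_image(image_ids, labels)
    assert out == {"a": 1, "b": 2}


# ----------------------------------------------------------- run statistics

def test_identical_runs_flagged_degenerate_with_zero_effect():
    r = paired_t_and_effect([90, 92, 94], [90, 92, 94])
    assert r.degenerate and r.cohens_d == 0.0
    assert math.isnan(r.t_stat) and math.isnan(r.p_value)


def test_three_run_example_matches_hand_arithmetic():
    # diffs (-3, -2, -4): mean -3, sd 1 -> d = -3, t = -3*sqrt(3)
    r = paired_t_and_effect([90, 92, 94], [93, 94, 98], correction="none")
    assert r.cohens_d == pytest.approx(-3.0)
    assert r.t_stat == pytest.approx(-3 * math.sqrt(3), rel=1e-6)
    assert r.t_stat == pytest.approx(-5.196, abs=1e-3)
    # reference p from the t(2) distribution (independent implementation)
    from scipy import stats
    p_ref = 2 * stats.t.sf(3 * math.sqrt(3), df=2)
    assert r.p_value == pytest.approx(p_ref, rel=1e-9)
    assert r.effect_label == "large"


def test_effect_size_bands():
    assert effect_size_label(0.1) == "negligible"
    assert effect_size_label(0.3) == "small"
    assert effect_size_label(0.6) == "medium"
    assert effect_size_label(-1.2) == "large"


def test_benjamini_hochberg_adjusted_p_monotone_in_rank(rng):
    runs = {"ref": rng.normal(95, 1, 10)}
    for i in range(5):
        runs[f"m{i}"] = rng.normal(95 - i * 0.4, 1, 10)
    comps = compare_runs(runs, "ref", correction="benjamini_hochberg")
    raw = sorted((c.p_value, c.adjusted_p) for c in comps.values())
    adj_in_rank_order = [a for _, a in raw]
    assert all(a <= b + 1e-12 for a, b in zip(adj_in_rank_order,
                                              adj_in_rank_order[1:]))
    assert all(c.adjusted_p >= c.p_value - 1e-12 for c in comps.values())


def test_bonferroni_adjustment_multiplies_by_family_size():
    r = paired_t_and_effect([1.0, 2.0, 3.1], [2.0, 3.0, 4.0],
                            correction="bonferroni", n_comparisons=4)
    assert r.adjusted_p == pytest.approx(min(r.p_value * 4, 1.0))


def test_unequal_lengths_raise():
    with pytest.raises(ValueError):
        paired_t_and_effect([1, 2], [1, 2, 3])


# ------------------------------------------------------------ training loop

def _toy_sets(n=24, size=32, records=True):
    rng = np.random.default_rng(0)
    X = rng.random((n, 3, size, size)).astype(np.float32)
    y = (X.mean(axis=(1, 2, 3)) > np.median(X.mean(axis=(1, 2, 3)))) \
        .astype(np.int64)
    recs = [TileRecord(source_image_id=f"im{i}", label=int(y[i]))
            for i in range(n)] if records else None
    half = n // 2
    return (TileDataset(X[:half], y[:half],
                        recs[:half] if recs else None),
            TileDataset(X[half:], y[half:],
                        recs[half:] if recs else None))


def test_training_refuses_leaky_splits(tiny_model):
    train_set, _ = _toy_sets()
    with pytest.raises(LeakageError):
        train(tiny_model, train_set, train_set,
              TrainRecipe(epochs=1, batch_size=8), seed=0)


def test_constant_validation_loss_stops_after_patience_epochs(monkeypatch):
    import histofusion.training as tr
    from histofusion.fusion import HistoFusionNet
    from tests.conftest import tiny_config
    model = HistoFusionNet(tiny_config(2), image_size=32)
    train_set, val_set = _toy_sets()
    # validation loss constant by construction: the first epoch sets the
    # best value, every later epoch is stale
    monkeypatch.setattr(tr, "evaluate", lambda m, d, **k: (1.0, 0.5))
    recipe = TrainRecipe(lr=1e-4, epochs=50, batch_size=8,
                         early_stop_patience=5, warmup_epochs=0)
    result = tr.train(model, train_set, val_set, recipe, seed=0)
    assert result.stopped_early
    assert len(result.history) == 1 + recipe.early_stop_patience


def test_warmup_schedule_reaches_configured_peak_in_history():
    from histofusion.fusion import HistoFusionNet
    from tests.conftest import tiny_config
    model = HistoFusionNet(tiny_config(2), image_size=32)
    train_set, val_set = _toy_sets()
    recipe = TrainRecipe(lr=2e-4, epochs=6, warmup_epochs=5, batch_size=8)
    result = train(model, train_set, val_set, recipe, seed=0)
    assert result.history[4]["lr"] == pytest.approx(2e-4)
    assert result.history[0]["lr"] == pytest.approx(2e-4 / 5)


def test_loss_decreases_on_separable_toy_problem():
    from histofusion.fusion import HistoFusionNet
    from tests.conftest import tiny_config
    rng = np.random.default_rng(1)
    # linearly separable: class differs by overall brightness
    X0 = rng.random((16, 3, 32, 32)).astype(np.float32) * 0.4
    X1 = rng.random((16, 3, 32, 32)).astype(np.float32) * 0.4 + 0.6
    X = np.concatenate([X0, X1])
    y = np.array([0] * 16 + [1] * 16)
    model = HistoFusionNet(tiny_config(2), image_size=32)
    train_set = TileDataset(X, y)
    val_set = TileDataset(X.copy(), y.copy())
    result = train(model, train_set, val_set,
                   TrainRecipe(lr=1e-3, epochs=8, batch_size=8,
                               warmup_epochs=2), seed=0)
    losses = [h["train_loss"] for h in result.history]
    assert losses[-1] < losses[0]
    assert result.best_val_accuracy > 0.6
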