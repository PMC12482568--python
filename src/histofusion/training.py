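"""Loss, training loop, classification metrics, majority voting, run stats.

The training recipe follows standard practice for this model family: AdamW
(peak learning rate 2e-4, weight decay 0.01), batch size 32, up to 50
epochs with linear warmup followed by cosine annealing, early stopping when
the validation loss has not improved for 15 consecutive epochs, and
checkpointing of the weights with the best validation accuracy.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from . import nn
from .data import TileRecord, augment


# --------------------------------------------------------------------- loss

def cross_entropy(logits: nn.Tensor, labels: np.ndarray) -> nn.Tensor:
    """Batch-mean multi-class cross-entropy in log-sum-exp form,
    -x_y + log(sum_j exp x_j), computed with a max shift for stability."""
    if not np.all(np.isfinite(logits.data)):
        raise ValueError("non-finite logits passed to cross_entropy")
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= logits.shape[1]:
        raise ValueError("labels outside [0, C)")
    logp = nn.log_softmax(logits, axis=1)
    return -logp.take_rows(labels).mean()


# ------------------------------------------------------------------- metrics

@dataclass
class MetricsReport:
    accuracy: float
    confusion: np.ndarray                      # (C, C), rows = true class
    per_class: dict                            # class -> metric dict
    macro_precision: float
    macro_recall: float
    macro_f1: float
    auc_per_class: dict
    auc_micro: float

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy,
                "confusion": self.confusion.tolist(),
                "per_class": self.per_class,
                "macro_precision": self.macro_precision,
                "macro_recall": self.macro_recall,
                "macro_f1": self.macro_f1,
                "auc_per_class": self.auc_per_class,
                "auc_micro": self.auc_micro}


def compute_metrics(pred_probs: np.ndarray,
                    labels: np.ndarray) -> MetricsReport:
    """Confusion-matrix metrics plus one-vs-rest and micro-average ROC AUC.

    Per class the report carries precision, recall, F1, and two "accuracy"
    flavours that are often conflated in the literature: ``recall`` (per-class
    sensitivity) and ``ovr_accuracy`` (one-vs-rest accuracy counting that
    class's TP+TN over all samples); both are labeled explicitly.
    A class absent from ``labels`` gets recall 0 with a warning.
    """
    pred_probs = np.asarray(pred_probs, float)
    labels = np.asarray(labels)
    C = pred_probs.shape[1]
    preds = pred_probs.argmax(axis=1)
    n = len(labels)
    confusion = np.zeros((C, C), np.int64)
    np.add.at(confusion, (labels, preds), 1)

    per_class = {}
    for c in range(C):
        tp = confusion[c, c]
        fp = confusion[:, c].sum() - tp
        fn = confusion[c, :].sum() - tp
        tn = n - tp - fp - fn
        if confusion[c, :].sum() == 0:
            warnings.warn(f"class {c} absent from labels; recall set to 0")
            recall = 0.0
        else:
            recall = tp / (tp + fn)
        precision = tp / (tp + fp) if (tp + fp) else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if (precision + recall) else 0.0)
        per_class[c] = {"precision": float(precision),
                        "recall": float(recall), "f1": float(f1),
                        "ovr_accuracy": float((tp + tn) / n),
                        "support": int(confusion[c, :].sum())}

    auc_per_class = {}
    onehot = np.eye(C)[labels]
    for c in range(C):
        if 0 < onehot[:, c].sum() < n:
            auc_per_class[c] = float(roc_auc_score(onehot[:, c],
                                                   pred_probs[:, c]))
        else:
            warnings.warn(f"AUC undefined for class {c}; set to 0")
            auc_per_class[c] = 0.0
    auc_micro = float(roc_auc_score(onehot.ravel(), pred_probs.ravel()))

    return MetricsReport(
        accuracy=float(np.trace(confusion) / n),
        confusion=confusion, per_class=per_class,
        macro_precision=float(np.mean([m["precision"]
                                       for m in per_class.values()])),
        macro_recall=float(np.mean([m["recall"]
                                    for m in per_class.values()])),
        macro_f1=float(np.mean([m["f1"] for m in per_class.values()])),
        auc_per_class=auc_per_class, auc_micro=auc_micro)


# ------------------------------------------------------------ majority vote

def majority_vote(patch_labels: np.ndarray,
                  patch_probs: np.ndarray | None = None) -> int:
    """Modal patch label for one image.  Ties are broken by the highest mean
    softmax probability among the tied classes, then by lowest class id."""
    patch_labels = np.asarray(patch_labels)
    if patch_labels.size == 0:
        raise ValueError("majority_vote needs at least one patch")
    values, counts = np.unique(patch_labels, return_counts=True)
    tied = values[counts == counts.max()]
    if len(tied) == 1 or patch_probs is None:
        return int(tied.min())
    mean_probs = np.asarray(patch_probs, float).mean(axis=0)
    best = tied[np.argmax(mean_probs[tied])]
    # np.argmax takes the first maximum, i.e. the lowest tied class id
    return int(best)


def vote_by_image(image_ids, patch_labels, patch_probs=None) -> dict:
    """Aggregate patch-level predictions to image-level labels."""
    image_ids = np.asarray(image_ids)
    patch_labels = np.asarray(patch_labels)
    out = {}
    for img in np.unique(image_ids):
        sel = image_ids == img
        probs = None if patch_probs is None else \
            np.asarray(patch_probs)[sel]
        out[img] = majority_vote(patch_labels[sel], probs)
    return out


# ---------------------------------------------------------------- training

@dataclass
class TrainRecipe:
    lr: float = 2e-4
    weight_decay: float = 0.01
    epochs: int = 50
    batch_size: int = 32
    warmup_epochs: int = 5
    early_stop_patience: int = 15
    augment_policy: str | None = None     # "bach" | "breakhis" | None


@dataclass
class TileDataset:
    X: np.ndarray                         # (N, 3, S, S) float in [0, 1]
    y: np.ndarray                         # (N,)
    records: list[TileRecord] | None = None

    def __len__(self):
        return len(self.y)


@dataclass
class TrainResult:
    best_state: dict
    best_epoch: int
    best_val_accuracy: float
    history: list = field(default_factory=list)
    stopped_early: bool = False


class LeakageError(RuntimeError):
    pass


def _audit_disjoint(train_set: TileDataset, val_set: TileDataset) -> None:
    if train_set.records is None or val_set.records is None:
        return
    for attr in ("source_image_id", "patient_id"):
        a = {getattr(r, attr) for r in train_set.records} - {None}
        b = {getattr(r, attr) for r in val_set.records} - {None}
        shared = a & b
        if shared:
            raise LeakageError(
                f"train/val leakage: {len(shared)} shared {attr} values, "
                f"e.g. {sorted(shared)[:3]}")


def evaluate(model, dataset: TileDataset, batch_size: int = 64):
    """Mean loss and accuracy in eval mode (no graph recording)."""
    model.eval()
    losses, correct = [], 0
    with nn.no_grad():
        for s in range(0, len(dataset), batch_size):
            xb = dataset.X[s:s + batch_size]
            yb = dataset.y[s:s + batch_size]
            logits = model.logits(xb)
            losses.append(cross_entropy(logits, yb).item() * len(yb))
            correct += int((logits.data.argmax(axis=1) == yb).sum())
    return sum(losses) / len(dataset), correct / len(dataset)


def predict_probs(model, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
    model.eval()
    out = []
    with nn.no_grad():
        for s in range(0, len(X), batch_size):
            out.append(model(X[s:s + batch_size]).data)
    return np.concatenate(out)


def train(model, train_set: TileDataset, val_set: TileDataset,
          recipe: TrainRecipe | None = None, seed: int = 0) -> TrainResult:
    """Run the full recipe; returns the best checkpoint and the history.

    Refuses to train when the leakage audit finds shared source images or
    patients between train and validation.  Early stopping monitors the
    validation loss; checkpoint selection uses validation accuracy.
    """
    recipe = recipe or TrainRecipe()
    _audit_disjoint(train_set, val_set)
    nn.manual_seed(seed)
    rng = np.random.default_rng(seed)
    opt = nn.AdamW(model.parameters(), lr=recipe.lr,
                   weight_decay=recipe.weight_decay)
    result = TrainResult(best_state=model.state_dict(), best_epoch=-1,
                         best_val_accuracy=-1.0)
    best_val_loss = np.inf
    stale = 0
    n = len(train_set)
    for epoch in range(recipe.epochs):
        lr = nn.cosine_warmup_lr(epoch, recipe.lr, recipe.warmup_epochs,
                                 recipe.epochs)
        opt.lr = lr
        model.train()
        order = rng.permutation(n)
        ep_loss, ep_correct = 0.0, 0
        for s in range(0, n, recipe.batch_size):
            idx = order[s:s + recipe.batch_size]
            xb = train_set.X[idx]
            if recipe.augment_policy:
                xb = np.stack([
                    augment(x.transpose(1, 2, 0), recipe.augment_policy,
                            rng).transpose(2, 0, 1) for x in xb])
            logits = model.logits(xb)
            loss = cross_entropy(logits, train_set.y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += loss.item() * len(idx)
            ep_correct += int((logits.data.argmax(axis=1)
                               == train_set.y[idx]).sum())
        val_loss, val_acc = evaluate(model, val_set)
        result.history.append({
            "epoch": epoch, "lr": lr, "train_loss": ep_loss / n,
            "train_accuracy": ep_correct / n,
            "val_loss": val_loss, "val_accuracy": val_acc})
        if val_acc > result.best_val_accuracy:
            result.best_val_accuracy = val_acc
            result.best_epoch = epoch
            result.best_state = model.state_dict()
        if val_loss < best_val_loss - 1e-9:
            best_val_loss = val_loss
            stale = 0
        else:
            stale += 1
            if stale >= recipe.early_stop_patience:
                result.stopped_early = True
                break
    model.load_state_dict(result.best_state)
    model.eval()
    return result


def save_checkpoint(path, model, config) -> None:
    """Weights plus an embedded config snapshot, in npz form."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(config.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path):
    """Returns ``(state_dict, config_dict)``."""
    data = dict(np.load(path))
    cfg = json.loads(data.pop("__config__").tobytes().decode())
    return data, cfg


# ------------------------------------------------------------- run statistics

@dataclass
class RunComparison:
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t_stat: float
    p_value: float
    cohens_d: float
    adjusted_p: float
    correction: str
    degenerate: bool = False
    effect_label: str = ""


def effect_size_label(d: float) -> str:
    """Conventional interpretation bands: 0.2 small, 0.5 medium, 0.8 large."""
    a = abs(d)
    if a >= 0.8:
        return "large"
    if a >= 0.5:
        return "medium"
    if a >= 0.2:
        return "small"
    return "negligible"


def paired_t_and_effect(runs_a, runs_b,
                        correction: str = "benjamini_hochberg",
                        n_comparisons: int = 1) -> RunComparison:
    """Paired t-test and paired Cohen's d (mean(diff)/sd(diff)) between two
    matched run vectors (e.g. accuracies over seeds 0-9).

    With zero-variance differences the t statistic is undefined: the result
    is flagged ``degenerate`` (t and p reported as NaN, never silently).
    ``n_comparisons`` sets the family size for single-number corrections;
    for a full family use :func:`compare_runs`.
    """
    a = np.asarray(runs_a, float)
    b = np.asarray(runs_b, float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length run vectors of length >= 2")
    diff = a - b
    sd_diff = diff.std(ddof=1)
    base = dict(mean_a=float(a.mean()), mean_b=float(b.mean()),
                sd_a=float(a.std(ddof=1)), sd_b=float(b.std(ddof=1)),
                correction=correction)
    if sd_diff == 0:
        d = 0.0 if diff.mean() == 0 else float(np.inf * np.sign(diff.mean()))
        return RunComparison(t_stat=float("nan"), p_value=float("nan"),
                             cohens_d=d, adjusted_p=float("nan"),
                             degenerate=True,
                             effect_label=effect_size_label(d), **base)
    t_stat, p = stats.ttest_rel(a, b)
    d = float(diff.mean() / sd_diff)
    adj = _adjust_single(float(p), correction, n_comparisons)
    return RunComparison(t_stat=float(t_stat), p_value=float(p),
                         cohens_d=d, adjusted_p=adj,
                         effect_label=effect_size_label(d), **base)


def _adjust_single(p: float, correction: str, m: int) -> float:
    if correction == "none" or m <= 1:
        return p
    if correction == "bonferroni":
        return min(p * m, 1.0)
    if correction == "benjamini_hochberg":
        # single smallest-rank bound; full families go through compare_runs
        return min(p * m, 1.0)
    raise ValueError(f"unknown correction {correction!r}")


def compare_runs(runs: dict, reference: str,
                 correction: str = "benjamini_hochberg") -> dict:
    """Compare every model's run vector against ``reference`` with a family-
    wise correction (Benjamini-Hochberg by default, Bonferroni optional)."""
    names = [k for k in runs if k != reference]
    comps = {name: paired_t_and_effect(runs[reference], runs[name],
                                       correction="none")
             for name in names}
    testable = [n for n in names if not comps[n].degenerate]
    if testable and correction != "none":
        method = {"benjamini_hochberg": "fdr_bh",
                  "bonferroni": "bonferroni"}[correction]
        _, adj, _, _ = multipletests([comps[n].p_value for n in testable],
                                     method=method)
        for n, q in zip(testable, adj):
            comps[n].adjusted_p = float(q)
            comps[n].correction = correction
    return comps
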