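"""Training loop, data splits, six-fold cross-validation and reporting.

The default evaluation unit is the subject: folds partition subjects, so
no individual contributes segments to both a training and a test fold.
Segment-level folding (which leaks subject identity across folds and
inflates accuracy) is available behind ``level='segment'`` for
comparison.  Per-subject predictions fuse the subject's per-segment
positive-class scores with the multi-scale sliding-window rule before
thresholding.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import autodiff as ad
from .features import SubjectDataset
from .losses import FusionConfig, multiscale_fusion
from .metrics import ConfusionMatrix, MetricsReport, compute_metrics, roc_auc
from .network import Model, ModelSpec, build_model

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 64
    epochs: int = 20
    dropout: float = 0.4
    optimizer: str = "adam"
    patience: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


@dataclass
class FoldPlan:
    k: int
    assignment: dict[str, int]   # item id -> fold index
    seed: int
    level: str = "subject"

    def fold_members(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.assignment.items() if f == fold)


def split_80_10_10(subjects: list[str], labels: np.ndarray,
                   seed: int = 0) -> tuple[list[str], list[str], list[str]]:
    """Stratified 80/10/10 partition: |val| = |test| = floor(0.1 n),
    remainder to train; deterministic given seed."""
    subjects = list(subjects)
    labels = np.asarray(labels, dtype=int)
    n = len(subjects)
    if n < 3:
        raise ValueError("need at least 3 subjects for an 80-10-10 split")
    n_hold = n // 10
    rng = np.random.default_rng(seed)

    by_class: dict[int, list[str]] = {}
    for s, y in zip(subjects, labels):
        by_class.setdefault(int(y), []).append(s)
    for members in by_class.values():
        rng.shuffle(members)

    def draw(count: int) -> list[str]:
        # largest-remainder allocation of `count` across classes
        sizes = {c: len(m) for c, m in by_class.items()}
        total = sum(sizes.values())
        quotas = {c: count * sizes[c] / total for c in sizes} if total else {}
        base = {c: int(np.floor(q)) for c, q in quotas.items()}
        short = count - sum(base.values())
        for c in sorted(quotas, key=lambda c: quotas[c] - base[c], reverse=True):
            if short <= 0:
                break
            if base[c] < sizes[c]:
                base[c] += 1
                short -= 1
        out: list[str] = []
        for c, k in base.items():
            out += [by_class[c].pop() for _ in range(k)]
        return out

    test = draw(n_hold)
    val = draw(n_hold)
    train = sorted(s for m in by_class.values() for s in m)
    present = {int(labels[subjects.index(s)]) for s in train}
    if present != set(int(y) for y in np.unique(labels)):
        raise ValueError("a class is absent from the training split")
    return train, sorted(val), sorted(test)


def stratified_kfold(subjects: list[str], labels: np.ndarray, k: int = 6,
                     seed: int = 0, level: str = "subject") -> FoldPlan:
    """Stratified k-fold assignment (delegated to sklearn), per-fold class
    counts within +/-1 of proportionality; deterministic given seed."""
    subjects = list(subjects)
    labels = np.asarray(labels, dtype=int)
    if k > len(subjects):
        raise ValueError(f"k={k} exceeds the number of items ({len(subjects)})")
    if k == len(subjects):  # leave-one-out degenerate case
        order = np.argsort(subjects)
        assignment = {subjects[i]: int(f) for f, i in enumerate(order)}
        return FoldPlan(k=k, assignment=assignment, seed=seed, level=level)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(subjects)), labels)):
        for i in test_idx:
            assignment[subjects[i]] = fold
    return FoldPlan(k=k, assignment=assignment, seed=seed, level=level)


def _onehot(y: np.ndarray, n_classes: int = 2) -> np.ndarray:
    return np.eye(n_classes)[np.asarray(y, dtype=int)]


def _eval_loss_acc(model: Model, X: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    logits, n_steps = model.forward(X, training=False)
    y_rep = np.tile(y, n_steps)
    loss = float(ad.softmax_cross_entropy(logits, _onehot(y_rep)).data)
    probs = model.predict_proba(X)
    acc = float(np.mean(np.argmax(probs, axis=1) == y))
    return loss, acc


def train(model: Model, train_data: tuple[np.ndarray, np.ndarray],
          val_data: tuple[np.ndarray, np.ndarray] | None,
          cfg: TrainConfig) -> tuple[Model, dict]:
    """Gradient-based minimization of the cross-entropy objective.

    Adam on minibatches, early stopping on validation loss with the
    configured patience (best-epoch weights restored).  Fully seeded.
    """
    cfg.validate()
    X, y = train_data
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(X) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    opt = ad.Adam(model.parameters(), lr=cfg.learning_rate)
    history: dict[str, list[float]] = {"train_loss": [], "train_acc": [],
                                       "val_loss": [], "val_acc": []}
    best_loss, best_weights, since_best = np.inf, None, 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(X))
        epoch_loss = 0.0
        for start in range(0, len(X), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits, n_steps = model.forward(X[idx], training=True, rng=rng)
            y_rep = np.tile(y[idx], n_steps)
            loss = ad.softmax_cross_entropy(logits, _onehot(y_rep))
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss.data}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        tr_loss = epoch_loss / len(X)
        _, tr_acc = _eval_loss_acc(model, X, y)
        history["train_loss"].append(tr_loss)
        history["train_acc"].append(tr_acc)
        if val_data is not None and len(val_data[0]) > 0:
            v_loss, v_acc = _eval_loss_acc(model, *val_data)
            history["val_loss"].append(v_loss)
            history["val_acc"].append(v_acc)
            if v_loss < best_loss - 1e-12:
                best_loss, best_weights, since_best = v_loss, model.get_weights(), 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    logger.info("early stopping at epoch %d", epoch)
                    break
    if best_weights is not None:
        model.set_weights(best_weights)
    return model, history


# ---------------------------------------------------------------------------
# cross-validation

def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=(0, 1))
    sd = np.maximum(X.std(axis=(0, 1)), np.finfo(float).eps)
    return mean, sd


def _gather(dataset: SubjectDataset, sids: list[str]
            ) -> tuple[np.ndarray, np.ndarray]:
    if not sids:
        return np.empty((0, 1, 1)), np.empty(0, dtype=int)
    xs, ys = [], []
    for sid in sids:
        f = dataset.features_for(sid)
        xs.append(f)
        ys.append(np.full(len(f), dataset.label_for(sid), dtype=int))
    return np.concatenate(xs), np.concatenate(ys)


def _fuse_subject(step_scores: np.ndarray, fusion: FusionConfig) -> np.ndarray:
    """Per-segment scores (n_seg, C) -> one fused class-score vector."""
    T = len(step_scores)
    widths = [p for p in fusion.window_widths if p <= T] or [T]
    return multiscale_fusion(step_scores, FusionConfig(window_widths=widths,
                                                       literal=fusion.literal))


def _inner_val_split(sids: list[str], labels: np.ndarray, seed: int,
                     frac: float = 0.15) -> tuple[list[str], list[str]]:
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[str]] = {}
    for s, y in zip(sids, labels):
        by_class.setdefault(int(y), []).append(s)
    val: list[str] = []
    for members in by_class.values():
        rng.shuffle(members)
        # at least one validation subject per class, but never the last one
        n_val = min(max(1, int(np.floor(frac * len(members)))),
                    len(members) - 1)
        val += members[:n_val]
    train = [s for s in sids if s not in set(val)]
    return train, val


def cross_validate(dataset: SubjectDataset, spec_builder, cfg: TrainConfig,
                   k: int = 6, level: str = "subject",
                   fusion: FusionConfig | None = None) -> dict:
    """k-fold cross-validation with per-fold metric reports.

    ``spec_builder()`` must return a fresh :class:`ModelSpec`.  At subject
    level each fold holds out whole subjects; their segment scores are
    fused into one prediction per subject.  At segment level folds
    partition pooled segments (the leakage-prone protocol) and metrics are
    per segment.  Held-out features are only read after the fold's model
    has finished training.
    """
    fusion = fusion or FusionConfig()
    if level not in ("subject", "segment"):
        raise ValueError("level must be 'subject' or 'segment'")

    if level == "subject":
        items = dataset.subjects
        item_labels = dataset.labels
    else:
        seg_index: list[tuple[str, int]] = []
        for sid in dataset.subjects:
            n_seg = len(dataset.features_for(sid))
            seg_index += [(sid, i) for i in range(n_seg)]
        items = [f"{sid}#{i}" for sid, i in seg_index]
        item_labels = np.array([dataset.label_for(sid) for sid, _ in seg_index])

    plan = stratified_kfold(items, item_labels, k=k, seed=cfg.seed, level=level)
    fold_reports: list[MetricsReport] = []
    all_scores: list[float] = []
    all_true: list[int] = []

    for fold in range(k):
        test_items = plan.fold_members(fold)
        test_set = set(test_items)
        test_labels = np.array([item_labels[items.index(s)] for s in test_items])
        if len(np.unique(test_labels)) < 2:
            raise ValueError(f"fold {fold} contains a single class; "
                             "use fewer folds or more subjects")
        train_items = [s for s in items if s not in test_set]
        train_labels = np.array([item_labels[items.index(s)] for s in train_items])
        inner_train, inner_val = _inner_val_split(train_items, train_labels,
                                                  seed=cfg.seed + 1000 + fold)

        if level == "subject":
            X_tr, y_tr = _gather(dataset, inner_train)
            X_va, y_va = _gather(dataset, inner_val)
        else:
            X_tr, y_tr = _gather_segments(dataset, inner_train)
            X_va, y_va = _gather_segments(dataset, inner_val)

        mean, sd = _standardize_fit(X_tr)
        X_tr = (X_tr - mean) / sd
        X_va = (X_va - mean) / sd

        model = build_model(spec_builder(), seed=cfg.seed + fold)
        fold_cfg = TrainConfig(**{**cfg.__dict__, "seed": cfg.seed + fold})
        model, _ = train(model, (X_tr, y_tr), (X_va, y_va), fold_cfg)

        # held-out data is read only now, after training
        y_pred, y_true, scores = [], [], []
        if level == "subject":
            for sid in test_items:
                X_te = (dataset.features_for(sid) - mean) / sd
                seg_scores = model.predict_step_scores(X_te).mean(axis=1)
                fused = _fuse_subject(seg_scores, fusion)
                scores.append(float(fused[1]))
                y_pred.append(int(fused[1] >= 0.5))
                y_true.append(dataset.label_for(sid))
        else:
            X_te, y_te = _gather_segments(dataset, test_items)
            X_te = (X_te - mean) / sd
            probs = model.predict_proba(X_te)
            scores = list(probs[:, 1])
            y_pred = list((probs[:, 1] >= 0.5).astype(int))
            y_true = list(y_te)

        cm = ConfusionMatrix.from_predictions(np.array(y_true), np.array(y_pred))
        report = compute_metrics(cm)
        try:
            report.auc, _, _ = roc_auc(np.array(scores), np.array(y_true))
        except ValueError:
            report.auc = None
        fold_reports.append(report)
        all_scores += list(scores)
        all_true += list(y_true)
        logger.info("fold %d: accuracy=%.3f", fold, report.accuracy)

    metric_names = ["accuracy", "precision", "recall", "specificity", "f1"]
    summary = {}
    for m in metric_names:
        vals = np.array([getattr(r, m) for r in fold_reports])
        summary[m] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1))}
    pooled_auc, fpr, tpr = roc_auc(np.array(all_scores), np.array(all_true))
    summary["auc_pooled"] = pooled_auc
    return {"k": k, "level": level,
            "folds": [r.as_dict() for r in fold_reports],
            "summary": summary,
            "roc": {"fpr": fpr.tolist(), "tpr": tpr.tolist()},
            "scores": {"score": list(map(float, all_scores)),
                       "label": list(map(int, all_true))}}


def _gather_segments(dataset: SubjectDataset, seg_items: list[str]
                     ) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for item in seg_items:
        sid, i = item.rsplit("#", 1)
        xs.append(dataset.features_for(sid)[int(i)])
        ys.append(dataset.label_for(sid))
    return np.stack(xs), np.array(ys, dtype=int)
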