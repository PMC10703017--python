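"""Training-loop contracts (zero-lr, determinism, early stopping) and
cross-validation bookkeeping, including the guarded-access check that
held-out subjects are never read before their fold's model is trained."""

import numpy as np
import pytest

from pdeeg.features import SubjectDataset
from pdeeg.network import LayerSpec, ModelSpec, build_model
from pdeeg.traineval import TrainConfig, cross_validate, train
from pdeeg import traineval


def toy_dataset(n_per_class=6, n_seg=8, T=5, F=4, effect=2.0, seed=0):
    """Random sequences; class 1 shifted by `effect` along one feature."""
    rng = np.random.default_rng(seed)
    feats, labels = {}, {}
    for c in (0, 1):
        for i in range(n_per_class):
            sid = f"c{c}s{i}"
            x = rng.standard_normal((n_seg, T, F))
            x[..., 0] += effect * c
            feats[sid] = x
            labels[sid] = c
    return SubjectDataset(feats, labels)


def tiny_spec_builder(T=5, F=4):
    return lambda: ModelSpec([
        LayerSpec("input", steps=T, features=F),
        LayerSpec("bilstm", units=3, return_sequences=True),
        LayerSpec("dense", units=2)])


def test_zero_learning_rate_leaves_parameters_unchanged():
    ds = toy_dataset()
    X = np.concatenate([ds.features_for(s) for s in ds.subjects])
    y = np.concatenate([[ds.label_for(s)] * 8 for s in ds.subjects])
    model = build_model(tiny_spec_builder()(), seed=0)
    before = model.get_weights()
    train(model, (X, y), None, TrainConfig(learning_rate=0.0, epochs=1, seed=0))
    after = model.get_weights()
    assert all(np.allclose(b, a) for b, a in zip(before, after))


def test_identical_seeds_give_identical_losses():
    ds = toy_dataset()
    X = np.concatenate([ds.features_for(s) for s in ds.subjects])
    y = np.concatenate([[ds.label_for(s)] * 8 for s in ds.subjects])
    hists = []
    for _ in range(2):
        model = build_model(tiny_spec_builder()(), seed=1)
        _, h = train(model, (X, y), (X, y), TrainConfig(epochs=3, seed=1))
        hists.append(h)
    assert hists[0]["train_loss"] == hists[1]["train_loss"]
    assert hists[0]["val_loss"] == hists[1]["val_loss"]


def test_training_learns_separable_toy_problem():
    ds = toy_dataset(effect=3.0)
    X = np.concatenate([ds.features_for(s) for s in ds.subjects])
    y = np.concatenate([[ds.label_for(s)] * 8 for s in ds.subjects])
    model = build_model(tiny_spec_builder()(), seed=0)
    _, hist = train(model, (X, y), (X, y),
                    TrainConfig(epochs=50, batch_size=16, patience=50, seed=0))
    assert hist["train_acc"][-1] >= 0.95


def test_divergence_aborts_with_diagnostic():
    ds = toy_dataset()
    X = np.concatenate([ds.features_for(s) for s in ds.subjects])
    y = np.concatenate([[ds.label_for(s)] * 8 for s in ds.subjects])
    model = build_model(tiny_spec_builder()(), seed=0)
    model.parameters()[0].data[0, 0] = np.nan
    with pytest.raises(RuntimeError, match="diverged"):
        train(model, (X, y), None, TrainConfig(epochs=2, seed=0))


def test_crossval_bookkeeping_each_subject_tested_once():
    ds = toy_dataset(effect=3.0)
    report = cross_validate(ds, tiny_spec_builder(), TrainConfig(epochs=4, seed=0),
                            k=3, level="subject")
    assert len(report["folds"]) == 3
    total = sum(f["confusion"]["tp"] + f["confusion"]["tn"]
                + f["confusion"]["fp"] + f["confusion"]["fn"]
                for f in report["folds"])
    assert total == len(ds.subjects)
    assert set(report["summary"]) >= {"accuracy", "precision", "recall",
                                      "specificity", "f1", "auc_pooled"}


def test_crossval_single_class_fold_raises():
    ds = toy_dataset(n_per_class=2)
    # 2+2 subjects with k=4 forces folds of one subject = one class
    with pytest.raises(ValueError, match="fold"):
        cross_validate(ds, tiny_spec_builder(), TrainConfig(epochs=1, seed=0),
                       k=4, level="subject")


def test_heldout_subjects_not_read_before_training(monkeypatch):
    """Guarded I/O: within each fold, the held-out subjects' features are
    not read between the fold's preparation start and the end of its
    train() call — evaluation touches them only after training."""
    ds = toy_dataset(effect=3.0)
    clock = {"t": 0}
    access_log: list[tuple[str, int]] = []
    train_windows: list[int] = []  # clock value at each train() return

    class Guarded(SubjectDataset):
        def features_for(self, sid):
            clock["t"] += 1
            access_log.append((sid, clock["t"]))
            return super().features_for(sid)

    guarded = Guarded(ds._features, ds._labels)

    real_train = traineval.train

    def spying_train(*args, **kwargs):
        out = real_train(*args, **kwargs)
        clock["t"] += 1
        train_windows.append(clock["t"])
        return out

    monkeypatch.setattr(traineval, "train", spying_train)
    k = 3
    from pdeeg.traineval import stratified_kfold

    plan = stratified_kfold(guarded.subjects, guarded.labels, k=k, seed=0)
    cross_validate(guarded, tiny_spec_builder(), TrainConfig(epochs=2, seed=0),
                   k=k, level="subject")
    assert len(train_windows) == k
    for fold in range(k):
        window_start = train_windows[fold - 1] if fold > 0 else 0
        window_end = train_windows[fold]
        held_out = set(plan.fold_members(fold))
        touched = {sid for sid, t in access_log
                   if window_start < t < window_end and sid in held_out}
        assert not touched, (
            f"fold {fold}: held-out subjects {touched} read before training")


def test_permuted_labels_destroy_subject_structure():
    ds = toy_dataset(effect=3.0, n_per_class=8)
    permuted = ds.with_permuted_labels(seed=3)
    assert sorted(permuted.labels.tolist()) == sorted(ds.labels.tolist())
    same = [permuted.label_for(s) == ds.label_for(s) for s in ds.subjects]
    assert not all(same)
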