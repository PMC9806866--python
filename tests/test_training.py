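"""Training protocol: splits, augmentation, schedulers, fit/evaluate."""

import dataclasses

import numpy as np
import pytest

from conftest import dataset_arrays
from metafuse.backbone import TinyDenseBackbone
from metafuse.fusion import make_fusion
from metafuse.metrics import balanced_accuracy, confusion
from metafuse.training import (Assembly, AugmentConfig, TrainConfig, TrainHistory,
                               augment, early_stop_check, evaluate, fit,
                               lr_schedule_step, parse_ratio, split_dataset)


class FakeSample:
    def __init__(self, label):
        self.label = label


# ------------------------------------------------------------------ split

def test_split_100_at_3_to_1():
    samples = [FakeSample(i % 4) for i in range(100)]
    train, test = split_dataset(samples, ratio="3:1", seed=0)
    assert len(train) == 75 and len(test) == 25
    assert set(id(s) for s in train).isdisjoint(id(s) for s in test)


def test_split_deterministic_under_seed():
    samples = [FakeSample(i % 3) for i in range(60)]
    a = split_dataset(samples, ratio="3:1", seed=5)
    b = split_dataset(samples, ratio="3:1", seed=5)
    assert [id(s) for s in a[0]] == [id(s) for s in b[0]]
    c = split_dataset(samples, ratio="3:1", seed=6)
    assert [id(s) for s in a[0]] != [id(s) for s in c[0]]


def test_split_stratified_proportions():
    samples = [FakeSample("A")] * 40 + [FakeSample("B")] * 20
    train, test = split_dataset(samples, ratio="3:1", seed=1)
    train_a = sum(s.label == "A" for s in train)
    test_a = sum(s.label == "A" for s in test)
    assert (train_a, len(train) - train_a) == (30, 15)
    assert (test_a, len(test) - test_a) == (10, 5)


def test_split_bad_ratio_errors():
    samples = [FakeSample(0), FakeSample(1)]
    for bad in ("0:1", "3:-1", 1.5, 0.0):
        with pytest.raises(ValueError):
            split_dataset(samples, ratio=bad)
    assert parse_ratio("1:1") == 0.5


# ---------------------------------------------------------------- augment

def test_augment_identity_when_disabled(rng):
    img = rng.random((3, 8, 8))
    out = augment(img, rng, AugmentConfig(0, 0, 0, 0, 0))
    assert out is img


def test_double_horizontal_flip_is_identity(rng):
    img = rng.random((3, 8, 8))
    assert np.array_equal(img[:, :, ::-1][:, :, ::-1], img)


def test_augment_deterministic_and_shape_preserving(rng):
    img = rng.random((3, 12, 10))
    out1 = augment(img, np.random.default_rng(3))
    out2 = augment(img, np.random.default_rng(3))
    assert np.array_equal(out1, out2)
    assert out1.shape == img.shape
    assert out1.min() >= 0.0 and out1.max() <= 1.0


def test_augment_brightness_only_scales(rng):
    img = np.full((3, 4, 4), 0.5)
    out = augment(img, np.random.default_rng(0), AugmentConfig(0, 0, 0.2, 0, 0))
    assert np.allclose(out, out.flat[0])  # uniform image stays uniform
    assert 0.4 <= out.flat[0] <= 0.6


# ------------------------------------------------------------- schedulers

def history_from(baccs, lrs=None, lr0=1e-3):
    h = TrainHistory()
    lrs = lrs if lrs is not None else [lr0] * len(baccs)
    for b, lr in zip(baccs, lrs):
        h.append(0.0, b, lr)
    return h


def test_lr_halves_after_patience_plateau():
    cfg = TrainConfig(lr=1e-3, lr_patience=10)
    h = history_from([0.6] + [0.6] * 10)  # best at epoch 0, then 10 flat epochs
    assert lr_schedule_step(h, 1e-3, cfg) == pytest.approx(5e-4)


def test_lr_unchanged_when_improvement_resets_counter():
    cfg = TrainConfig(lr=1e-3, lr_patience=10)
    h = history_from([0.6] + [0.6] * 9 + [0.7])
    assert lr_schedule_step(h, 1e-3, cfg) == 1e-3


def test_two_plateaus_quarter_lr():
    cfg = TrainConfig(lr=1e-3, lr_patience=10)
    lr = cfg.lr
    h = TrainHistory()
    h.append(0.0, 0.6, lr)
    for _ in range(25):
        h.append(0.0, 0.6, lr)
        lr = lr_schedule_step(h, lr, cfg)
    assert lr == pytest.approx(cfg.lr * 0.25)
    assert h.lr == sorted(h.lr, reverse=True)  # lr never increases


def test_lr_after_n_reductions_exact():
    cfg = TrainConfig(lr=1e-3, lr_patience=2)
    lr = cfg.lr
    h = TrainHistory()
    h.append(0.0, 0.9, lr)
    reductions = 0
    for _ in range(20):
        h.append(0.0, 0.9, lr)
        new = lr_schedule_step(h, lr, cfg)
        if new < lr:
            reductions += 1
        lr = new
    assert lr == pytest.approx(1e-3 * 0.5 ** reductions)
    assert reductions >= 3


def test_early_stop_contracts():
    cfg = TrainConfig(stop_patience=15)
    assert early_stop_check(history_from([0.6] + [0.6] * 15), cfg)
    assert not early_stop_check(history_from([0.6] + [0.6] * 13 + [0.7]), cfg)
    assert not early_stop_check(history_from(list(np.linspace(0.5, 0.9, 40))), cfg)


def test_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(lr_factor=1.5)
    with pytest.raises(ValueError):
        TrainConfig(lr_patience=0)


# ------------------------------------------------------------ fit/evaluate

def small_assembly(n_classes, d_meta, seed=0, dropout=0.0):
    rng = np.random.default_rng(seed)
    bb = TinyDenseBackbone(stem_channels=2, growth=1, num_layers=2, seed=seed)
    fu = make_fusion("none", d_meta, bb.k_img, rng=rng)
    return Assembly(bb, fu, n_classes, rng=rng, dropout=dropout)


def encoded_data(samples):
    from metafuse.encoding import build_schema, encode_batch
    images, records, labels = dataset_arrays(samples)
    schema = build_schema(records)
    return images, encode_batch(records, schema), np.array(labels)


def test_fit_reaches_perfect_training_accuracy(tiny_separable_dataset):
    # two hue-separated classes, k_img=4 backbone: separable within the cap
    X, M, y = encoded_data(tiny_separable_dataset)
    asm = small_assembly(2, M.shape[1])
    cfg = TrainConfig(max_epochs=60, batch_size=16, augment=None, dropout=0.0,
                      val_fraction=0.2, seed=0)
    state, history = fit(asm, (X, M, y), (X, M, y), cfg)
    report = evaluate(asm, (X, M, y))
    assert report.accuracy == 1.0
    assert 0 < len(history) <= 60


def test_fit_zero_epochs_returns_initial_params(tiny_separable_dataset):
    X, M, y = encoded_data(tiny_separable_dataset)
    asm = small_assembly(2, M.shape[1])
    before = asm.state_dict()
    state, history = fit(asm, (X, M, y), (X, M, y), TrainConfig(max_epochs=0))
    assert len(history) == 0
    for k in before:
        assert np.array_equal(before[k], state[k])


def test_fit_is_deterministic_for_fixed_seed(tiny_separable_dataset):
    X, M, y = encoded_data(tiny_separable_dataset)
    cfg = TrainConfig(max_epochs=4, batch_size=16, seed=11, dropout=0.5)
    runs = []
    for _ in range(2):
        asm = small_assembly(2, M.shape[1], seed=3, dropout=0.5)
        state, history = fit(asm, (X, M, y), (X, M, y), cfg)
        runs.append((state, history))
    (s1, h1), (s2, h2) = runs
    assert h1.loss == h2.loss
    assert h1.val_bacc == h2.val_bacc
    assert h1.lr == h2.lr
    for k in s1:
        assert np.array_equal(s1[k], s2[k])


def test_fit_never_exceeds_max_epochs(tiny_separable_dataset):
    X, M, y = encoded_data(tiny_separable_dataset)
    asm = small_assembly(2, M.shape[1])
    cfg = TrainConfig(max_epochs=3, batch_size=16, stop_patience=1000)
    _, history = fit(asm, (X, M, y), (X, M, y), cfg)
    assert len(history) == 3
    assert history.stopped_epoch == -1  # cap reached, not early-stopped


def test_evaluate_order_invariance_and_consistency(tiny_separable_dataset):
    X, M, y = encoded_data(tiny_separable_dataset)
    asm = small_assembly(2, M.shape[1])
    fit(asm, (X, M, y), (X, M, y), TrainConfig(max_epochs=3, batch_size=16))
    rep = evaluate(asm, (X, M, y))
    perm = np.random.default_rng(0).permutation(len(y))
    rep_shuffled = evaluate(asm, (X[perm], M[perm], y[perm]))
    assert rep.bacc == pytest.approx(rep_shuffled.bacc)
    # bacc agrees with an external confusion-matrix recomputation
    preds = asm.predict_proba(X, M).argmax(axis=1)
    cm = confusion(y.tolist(), preds.tolist(), [0, 1])
    assert rep.bacc == pytest.approx(balanced_accuracy(cm))


def test_evaluate_empty_test_set_errors(tiny_separable_dataset):
    X, M, y = encoded_data(tiny_separable_dataset)
    asm = small_assembly(2, M.shape[1])
    with pytest.raises(ValueError):
        evaluate(asm, (X[:0], M[:0], y[:0]))
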