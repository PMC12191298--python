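"""Split protocols, the metric equations, training behavior, ablation."""
import numpy as np
import pytest

from ecgmff.nn import MffNet
from ecgmff.train_eval import (
    BeatDataset,
    MetricsReport,
    SplitSpec,
    TrainConfig,
    binary_metrics,
    confusion_from_predictions,
    cross_validate,
    evaluate,
    make_folds,
    make_split,
    run_ablation,
    train,
)


def _toy_dataset(rng, n_per_class=20, n_classes=2, n_patients_per_class=4,
                 beat_len=64, img=12, signal_in=("beat", "gaf", "st"),
                 sep=2.0):
    """Small dataset with class templates injected into chosen branches."""
    n = n_per_class * n_classes
    y = np.repeat(np.arange(n_classes), n_per_class)
    tb = rng.standard_normal((n_classes, 3, beat_len)) * (
        sep if "beat" in signal_in else 0.0
    )
    tg = rng.standard_normal((n_classes, 1, img, img)) * (
        sep if "gaf" in signal_in else 0.0
    )
    ts = rng.standard_normal((n_classes, 1, img, img)) * (
        sep if "st" in signal_in else 0.0
    )
    pids = np.array([
        f"c{c}-p{i % n_patients_per_class}"
        for c, i in zip(y, np.tile(np.arange(n_per_class), n_classes))
    ])
    return BeatDataset(
        beats=tb[y] + rng.standard_normal((n, 3, beat_len)),
        gafs=tg[y] + rng.standard_normal((n, 1, img, img)),
        sts=ts[y] + rng.standard_normal((n, 1, img, img)),
        labels=y,
        patient_ids=pids,
        classes=[f"class{i}" for i in range(n_classes)],
    )


def _tiny_net(ds, branches=("beat", "gaf", "st"), seed=0):
    return MffNet(
        n_classes=len(ds.classes), branches=branches, width_multiplier=0.0625,
        beat_channels=ds.beats.shape[1], seed=seed,
    )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def test_hand_built_binary_confusion():
    m = binary_metrics(tp=90, tn=80, fp=20, fn=10)
    assert m["Acc"] == pytest.approx(85.0)
    assert m["Sen"] == pytest.approx(90.0)
    assert m["Pre"] == pytest.approx(81.8182, abs=1e-3)
    assert m["Spe"] == pytest.approx(80.0)
    assert m["F1"] == pytest.approx(85.7143, abs=1e-3)


def test_acct_three_class_hand_example():
    cm = np.array([[5, 1, 0], [1, 3, 1], [0, 1, 2]])
    assert cm.sum() == 14
    cm = np.array([[5, 0, 1], [0, 3, 1], [0, 0, 2]])
    report = MetricsReport(cm, ["a", "b", "c"])
    assert report.acc_total == pytest.approx(100 * 10 / 12, abs=1e-9)


def test_perfect_predictions_score_100():
    cm = np.diag([7, 5, 9])
    report = MetricsReport(cm, ["a", "b", "c"])
    assert report.acc_total == 100.0
    for m in ("Acc", "Sen", "Pre", "Spe", "F1"):
        assert report.macro[m] == pytest.approx(100.0)


def test_metric_equations_match_brute_force_tally(rng):
    """Per-class metrics equal a direct per-sample tally on random data."""
    for _ in range(100):
        k = int(rng.integers(2, 6))
        n = int(rng.integers(5, 200))
        y_true = rng.integers(0, k, n)
        y_pred = rng.integers(0, k, n)
        cm = confusion_from_predictions(y_true, y_pred, k)
        report = MetricsReport(cm, [str(i) for i in range(k)])
        assert cm.sum() == n
        assert report.acc_total == pytest.approx(100 * np.mean(y_true == y_pred))
        for c in range(k):
            tp = int(np.sum((y_true == c) & (y_pred == c)))
            fn = int(np.sum((y_true == c) & (y_pred != c)))
            fp = int(np.sum((y_true != c) & (y_pred == c)))
            tn = n - tp - fn - fp
            expected = binary_metrics(tp, tn, fp, fn)
            got = report.class_metrics(str(c))
            for name, v in expected.items():
                assert got[name] == pytest.approx(v, abs=1e-9)


def test_metrics_bounded_zero_to_hundred(rng):
    cm = rng.integers(0, 30, (4, 4))
    report = MetricsReport(cm, list("abcd"))
    assert ((report.per_class.values >= 0) & (report.per_class.values <= 100)).all()


# ---------------------------------------------------------------------------
# Splits and folds
# ---------------------------------------------------------------------------

def test_intra_split_sizes_70_20_10(rng):
    ds = _toy_dataset(rng, n_per_class=100, n_classes=1)
    split = make_split(ds, SplitSpec(paradigm="intra_patient", seed=0))
    assert split.train_idx.size == 70
    assert split.val_idx.size == 20
    assert split.test_idx.size == 10


def test_inter_split_shares_no_patients(rng):
    ds = _toy_dataset(rng, n_per_class=24, n_patients_per_class=6)
    split = make_split(ds, SplitSpec(paradigm="inter_patient", seed=1))
    train_p = set(ds.patient_ids[split.train_idx])
    test_p = set(ds.patient_ids[split.test_idx])
    assert not (train_p & test_p)
    assert split.val_idx.size == 0
    assert split.train_idx.size + split.test_idx.size == len(ds)


def test_split_determinism(rng):
    ds = _toy_dataset(rng)
    for paradigm in ("intra_patient", "inter_patient"):
        s1 = make_split(ds, SplitSpec(paradigm=paradigm, seed=9))
        s2 = make_split(ds, SplitSpec(paradigm=paradigm, seed=9))
        np.testing.assert_array_equal(s1.train_idx, s2.train_idx)
        np.testing.assert_array_equal(s1.test_idx, s2.test_idx)


def test_single_patient_class_kept_in_training(rng):
    ds = _toy_dataset(rng, n_per_class=6, n_patients_per_class=1)
    with pytest.warns(UserWarning):
        split = make_split(ds, SplitSpec(paradigm="inter_patient", seed=0))
    assert split.train_idx.size == len(ds)


def test_folds_partition_dataset_exactly(rng):
    ds = _toy_dataset(rng, n_per_class=50, n_classes=2,
                      n_patients_per_class=10)
    for paradigm in ("intra_patient", "inter_patient"):
        folds = make_folds(ds, SplitSpec(paradigm=paradigm, n_folds=10, seed=0))
        assert len(folds) == 10
        union = np.concatenate(folds)
        assert union.size == len(ds)
        assert np.array_equal(np.sort(union), np.arange(len(ds)))
    # intra, 100 beats, 10 folds -> each test fold holds 10 beats
    folds = make_folds(ds, SplitSpec(paradigm="intra_patient", n_folds=10,
                                     seed=0))
    assert all(f.size == 10 for f in folds)


def test_inter_folds_respect_patients(rng):
    ds = _toy_dataset(rng, n_per_class=20, n_patients_per_class=10)
    folds = make_folds(ds, SplitSpec(paradigm="inter_patient", n_folds=5,
                                     seed=3))
    for f in folds:
        others = np.setdiff1d(np.arange(len(ds)), f)
        assert not (set(ds.patient_ids[f]) & set(ds.patient_ids[others]))


def test_fold_assignment_deterministic(rng):
    ds = _toy_dataset(rng)
    a = make_folds(ds, SplitSpec(paradigm="intra_patient", n_folds=4, seed=2))
    b = make_folds(ds, SplitSpec(paradigm="intra_patient", n_folds=4, seed=2))
    for fa, fb in zip(a, b):
        np.testing.assert_array_equal(fa, fb)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def test_loss_decreases_on_separable_data(rng):
    ds = _toy_dataset(rng, n_per_class=32)
    net = _tiny_net(ds)
    trace = train(net, ds, config=TrainConfig(learning_rate=0.01,
                                              batch_size=16, epochs=5, seed=0))
    assert trace[-1] < trace[0]
    assert all(b < a * 1.5 for a, b in zip(trace, trace[1:]))  # no blow-up


def test_zero_learning_rate_leaves_parameters_unchanged(rng):
    ds = _toy_dataset(rng, n_per_class=8)
    net = _tiny_net(ds)
    before = [p.data.copy() for p in net.parameters()]
    train(net, ds, config=TrainConfig(learning_rate=0.0, batch_size=8,
                                      epochs=1, seed=0))
    for p, b in zip(net.parameters(), before):
        np.testing.assert_array_equal(p.data, b)


def test_single_class_training_collapses_predictions(rng):
    ds = _toy_dataset(rng, n_per_class=16, n_classes=2)
    only_zero = np.flatnonzero(ds.labels == 0)
    net = _tiny_net(ds)
    trace = train(net, ds, only_zero,
                  TrainConfig(learning_rate=0.01, batch_size=8, epochs=8,
                              seed=0))
    assert trace[-1] < 0.1
    preds = net.predict(ds.inputs(only_zero))
    assert np.all(preds == 0)


def test_non_finite_loss_aborts(rng):
    ds = _toy_dataset(rng, n_per_class=4)
    ds.beats[0, 0, 0] = np.inf
    net = _tiny_net(ds)
    with pytest.raises(FloatingPointError):
        train(net, ds, config=TrainConfig(learning_rate=0.01, batch_size=8,
                                          epochs=1, seed=0))


def test_empty_partition_rejected(rng):
    ds = _toy_dataset(rng, n_per_class=4)
    net = _tiny_net(ds)
    with pytest.raises(ValueError):
        train(net, ds, np.array([], dtype=int))
    with pytest.raises(ValueError):
        evaluate(net, ds, np.array([], dtype=int))


# ---------------------------------------------------------------------------
# Cross-validation and ablation
# ---------------------------------------------------------------------------

def test_cross_validate_returns_fold_reports(rng):
    ds = _toy_dataset(rng, n_per_class=12, n_patients_per_class=4)
    reports = cross_validate(
        ds,
        SplitSpec(paradigm="intra_patient", n_folds=3, seed=0),
        model_factory=lambda i: _tiny_net(ds, seed=i),
        config=TrainConfig(learning_rate=0.01, batch_size=8, epochs=2, seed=0),
    )
    assert len(reports) == 3
    assert all(r.confusion.sum() == 8 for r in reports)


def test_ablation_single_branch_head_width(rng):
    ds = _toy_dataset(rng, n_per_class=8)
    net = MffNet(n_classes=2, branches=("beat",), width_multiplier=0.0625,
                 beat_channels=3, seed=0)
    width = net.branches["beat"].feature_width
    assert net.head.weight.data.shape == (2, width)


def test_ablation_all_seven_subsets(rng):
    ds = _toy_dataset(rng, n_per_class=8, n_patients_per_class=4)
    split = make_split(ds, SplitSpec(paradigm="inter_patient", seed=0))
    results = run_ablation(
        ds, split,
        TrainConfig(learning_rate=0.01, batch_size=8, epochs=1, seed=0),
        model_kwargs={"width_multiplier": 0.0625,
                      "beat_channels": ds.beats.shape[1], "seed": 0},
    )
    assert len(results) == 7
    assert set(map(len, results)) == {1, 2, 3}


def test_st_only_signal_favors_st_branches(rng):
    """When class information lives only in the time-frequency features,
    ST-containing models beat the beat-only model."""
    ds = _toy_dataset(rng, n_per_class=24, n_patients_per_class=6,
                      signal_in=("st",), sep=3.0)
    split = make_split(ds, SplitSpec(paradigm="inter_patient", seed=0))
    cfg = TrainConfig(learning_rate=0.01, batch_size=12, epochs=6, seed=0)
    results = run_ablation(
        ds, split, cfg,
        combinations=[("beat",), ("st",)],
        model_kwargs={"width_multiplier": 0.0625,
                      "beat_channels": ds.beats.shape[1], "seed": 0},
    )
    assert results[("st",)].acc_total > results[("beat",)].acc_total
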