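"""Network architecture contracts, training loop, and gradient correctness."""

import numpy as np
import pytest

from oculocog import nn
from oculocog.models import (CNNClassifier, FCNNClassifier, build_baseline,
                             make_model)


def _toy(n=20, n_features=39, n_classes=2, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (n, n_features))
    y = np.arange(n) % n_classes
    X[:, 0] += sep * y
    return X, y.astype(str)


def test_flattened_width_arithmetic():
    # 39 -> 39 (conv, same) -> 19 (pool) -> 19 -> 9; 32 channels x 9 = 288
    assert CNNClassifier.flattened_width(39) == 288
    assert CNNClassifier.flattened_width(31) == 32 * 7
    assert CNNClassifier.flattened_width(8) == 32 * 2
    with pytest.raises(ValueError):
        CNNClassifier.flattened_width(3)


@pytest.mark.parametrize("n_features", [39, 31, 8, 29, 27, 34, 35])
def test_forward_shape_contract_all_subset_sizes(n_features):
    X, y = _toy(n=12, n_features=n_features, n_classes=3)
    model = CNNClassifier(epochs=1, random_state=0).fit(X, y)
    proba = model.predict_proba(X)
    assert proba.shape == (12, 3)
    assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)
    assert (proba >= 0).all() and (proba <= 1).all()


def test_fcnn_parameter_count_closed_form():
    X, y = _toy(n=10, n_features=39)
    model = FCNNClassifier(epochs=1, random_state=0).fit(X, y)
    expected = (39 * 4096 + 4096) + (4096 * 256 + 256) + (256 * 2 + 2)
    assert model.network_.n_parameters() == expected


def test_cnn_parameter_count_closed_form():
    X, y = _toy(n=10, n_features=39, n_classes=3)
    model = CNNClassifier(epochs=1, random_state=0).fit(X, y)
    conv = (16 * 1 * 2 + 16) + (32 * 16 * 2 + 32)
    fc = (288 * 4096 + 4096) + (4096 * 256 + 256) + (256 * 3 + 3)
    assert model.network_.n_parameters() == conv + fc


def test_cnn_overfits_separable_rows():
    X, y = _toy(n=20, sep=4.0)
    model = CNNClassifier(epochs=200, random_state=0).fit(X, y)
    assert (model.predict(X) == y).mean() == 1.0


def test_training_reproducible_under_seed():
    X, y = _toy(n=24, sep=2.0)
    a = CNNClassifier(epochs=5, random_state=7).fit(X, y)
    b = CNNClassifier(epochs=5, random_state=7).fit(X, y)
    assert a.loss_history_ == b.loss_history_
    assert np.array_equal(a.predict_proba(X), b.predict_proba(X))


def test_no_dropout_predictions_bitwise_stable():
    X, y = _toy(n=16)
    model = CNNClassifier(epochs=3, dropout=0.0, random_state=1).fit(X, y)
    p1 = model.predict_proba(X)
    p2 = model.predict_proba(X)
    assert np.array_equal(p1, p2)


def test_learning_rate_schedule_10pct_every_10_epochs():
    X, y = _toy(n=16)
    model = FCNNClassifier(epochs=21, random_state=0).fit(X, y)
    lrs = model.lr_history_
    assert lrs[0] == pytest.approx(0.001)
    assert lrs[10] == pytest.approx(0.9 * lrs[0])   # epoch 11
    assert lrs[20] == pytest.approx(0.81 * lrs[0])  # epoch 21
    assert nn.step_lr(0.001, 10) == pytest.approx(0.001)
    assert nn.step_lr(0.001, 11) == pytest.approx(0.0009)


def test_loss_decreases_early_in_training():
    drops = 0
    for seed in range(5):
        X, y = _toy(n=40, sep=2.0, seed=seed)
        model = CNNClassifier(epochs=10, random_state=seed).fit(X, y)
        drops += model.loss_history_[-1] < model.loss_history_[0]
    assert drops >= 4


def test_duplicate_rows_get_identical_probabilities():
    X, y = _toy(n=20)
    model = CNNClassifier(epochs=5, random_state=0).fit(X, y)
    X2 = np.vstack([X[:1], X[:1]])
    p = model.predict_proba(X2)
    assert np.array_equal(p[0], p[1])


def test_feature_count_mismatch_rejected():
    X, y = _toy(n=12, n_features=10)
    model = FCNNClassifier(epochs=1, random_state=0).fit(X, y)
    with pytest.raises(ValueError):
        model.predict_proba(np.zeros((2, 11)))


def test_nonfinite_loss_aborts():
    X, y = _toy(n=12, n_features=8)
    X[0, 0] = 1e30  # drive the logits to overflow
    with pytest.raises((RuntimeError, ValueError)):
        FCNNClassifier(epochs=50, lr=1e6, random_state=0).fit(X, y)


def test_baselines_fit_predict_and_probabilities():
    X, y = _toy(n=30, n_features=8, sep=8.0)
    for kind in ("svm", "rf"):
        model = build_baseline(kind, seed=0)
        model.fit(X, y)
        assert (model.predict(X) == y).mean() == 1.0
        proba = model.predict_proba(X)
        assert proba.shape == (30, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
    rf1 = build_baseline("rf", seed=5).fit(X, y).predict_proba(X)
    rf2 = build_baseline("rf", seed=5).fit(X, y).predict_proba(X)
    assert np.array_equal(rf1, rf2)
    with pytest.raises(ValueError):
        build_baseline("mlp")
    with pytest.raises(ValueError):
        make_model("transformer")


def test_gradient_matches_finite_differences():
    """Backprop through the full conv/pool/FC stack vs central differences."""
    rng = np.random.default_rng(0)
    net = nn.Network([
        nn.Conv1d(1, 2, 2, rng), nn.ReLU(), nn.MaxPool1d(),
        nn.Conv1d(2, 3, 2, rng), nn.ReLU(), nn.MaxPool1d(),
        nn.Flatten(),
        nn.Linear(6, 5, rng), nn.ReLU(),
        nn.Linear(5, 2, rng),
    ])
    X = rng.normal(size=(4, 1, 10))
    y = np.array([0, 1, 1, 0])

    def loss_of():
        return nn.cross_entropy_loss(net.forward(X, train=False), y)[0]

    _, grad = nn.cross_entropy_loss(net.forward(X, train=False), y)
    net.backward(grad)
    eps = 1e-6
    checked = 0
    for p, g in net.parameters():
        flat_p, flat_g = p.ravel(), g.ravel()
        for idx in rng.choice(p.size, size=min(5, p.size), replace=False):
            orig = flat_p[idx]
            flat_p[idx] = orig + eps
            up = loss_of()
            flat_p[idx] = orig - eps
            down = loss_of()
            flat_p[idx] = orig
            fd = (up - down) / (2 * eps)
            assert fd == pytest.approx(flat_g[idx], rel=1e-4, abs=1e-7)
            checked += 1
    assert checked >= 20


def test_checkpoint_round_trip_and_training_log(tmp_path):
    X, y = _toy(n=16, n_features=10, sep=5.0)
    model = CNNClassifier(epochs=4, random_state=3).fit(X, y)
    log = model.training_log()
    assert list(log.columns) == ["epoch", "loss", "lr"]
    assert len(log) == 4
    path = tmp_path / "ckpt.npz"
    model.save(path)
    again = CNNClassifier.load(path)
    assert np.array_equal(model.predict_proba(X), again.predict_proba(X))
    assert list(again.classes_) == list(model.classes_)
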