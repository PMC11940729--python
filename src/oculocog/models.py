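"""Classifiers: the 1D-CNN, its fully connected ablation, and baselines.

The CNN applies two kernel-2, stride-1 convolutions (16 then 32 output
channels, end-padded so output length equals input length), each followed
by ReLU and size-2 max pooling, then three fully connected layers
(flatten -> 4096 -> 256 -> n_classes) with ReLU and dropout after the first
two.  For a 39-feature input the flattened width is 32 x 9 = 288
(39 -> 39 -> 19 -> 19 -> 9 under end padding and floor pooling).  Training
minimises softmax cross-entropy with Adam (lr 0.001, beta1 0.9, beta2
0.999) and a step schedule multiplying the learning rate by 0.9 every 10
epochs.  Because the convolution couples adjacent features, the canonical
Table-order feature layout is part of the model definition.

Both neural models are scikit-learn-compatible estimators (fit /
predict / predict_proba, ``get_params``), so they plug into sklearn model
selection; the SVM and Random Forest baselines are sklearn's own
implementations at library defaults.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .nn import (Adam, Conv1d, Dropout, Flatten, Linear, MaxPool1d, Network,
                 ReLU, cross_entropy_loss, softmax, step_lr)


class _NeuralClassifier(BaseEstimator, ClassifierMixin):
    """Shared training loop for the numpy networks."""

    def __init__(self, epochs=100, batch_size=16, lr=0.001, beta1=0.9,
                 beta2=0.999, lr_step=10, lr_gamma=0.9, dropout=0.5,
                 random_state=None, dtype=np.float32):
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.lr_step = lr_step
        self.lr_gamma = lr_gamma
        self.dropout = dropout
        self.random_state = random_state
        self.dtype = dtype

    def _build_network(self, n_features, n_classes, rng) -> Network:
        raise NotImplementedError

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=self.dtype)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        self.n_features_in_ = X.shape[1]
        rng = np.random.default_rng(self.random_state)
        self.network_ = self._build_network(X.shape[1], len(self.classes_),
                                            rng)
        opt = Adam(self.network_.parameters(), lr=self.lr, beta1=self.beta1,
                   beta2=self.beta2)
        n = len(X)
        bs = min(self.batch_size, n)
        self.loss_history_, self.lr_history_ = [], []
        for epoch in range(1, self.epochs + 1):
            opt.lr = step_lr(self.lr, epoch, self.lr_step, self.lr_gamma)
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                logits = self.network_.forward(X[idx], train=True)
                loss, grad = cross_entropy_loss(logits, y_idx[idx])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}: {loss}")
                self.network_.backward(grad)
                opt.step()
                losses.append(loss)
            self.loss_history_.append(float(np.mean(losses)))
            self.lr_history_.append(opt.lr)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "network_")
        X = check_array(X, dtype=self.dtype)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; model expects "
                f"{self.n_features_in_}")
        return self.network_.forward(X, train=False)

    def predict_proba(self, X):
        return softmax(self.decision_function(X))

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def training_log(self):
        """Per-epoch training record (epoch, loss, lr) as a DataFrame."""
        import pandas as pd
        check_is_fitted(self, "network_")
        return pd.DataFrame({
            "epoch": np.arange(1, len(self.loss_history_) + 1),
            "loss": self.loss_history_, "lr": self.lr_history_})

    def save(self, path):
        """Checkpoint: fitted weights plus a config snapshot."""
        import json
        check_is_fitted(self, "network_")
        arrays = {f"param_{i}": p
                  for i, (p, _) in enumerate(self.network_.parameters())}
        meta = {"class": type(self).__name__,
                "params": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in self.get_params().items()
                           if k != "dtype"},
                "classes": [str(c) for c in self.classes_],
                "n_features_in": int(self.n_features_in_),
                "loss_history": self.loss_history_,
                "lr_history": self.lr_history_}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path):
        import json
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            params = {k: (tuple(v) if isinstance(v, list) else v)
                      for k, v in meta["params"].items()}
            model = cls(**params)
            model.classes_ = np.asarray(meta["classes"])
            model.n_features_in_ = meta["n_features_in"]
            model.loss_history_ = meta["loss_history"]
            model.lr_history_ = meta["lr_history"]
            rng = np.random.default_rng(0)
            model.network_ = model._build_network(
                model.n_features_in_, len(model.classes_), rng)
            for i, (p, _) in enumerate(model.network_.parameters()):
                p[...] = data[f"param_{i}"]
        return model


class CNNClassifier(_NeuralClassifier):
    """Two conv/pool stages over the ordered feature vector, then the FC head."""

    def __init__(self, conv_channels=(16, 32), kernel_size=2,
                 fc_dims=(4096, 256), epochs=100, batch_size=16, lr=0.001,
                 beta1=0.9, beta2=0.999, lr_step=10, lr_gamma=0.9,
                 dropout=0.5, random_state=None, dtype=np.float32):
        super().__init__(epochs=epochs, batch_size=batch_size, lr=lr,
                         beta1=beta1, beta2=beta2, lr_step=lr_step,
                         lr_gamma=lr_gamma, dropout=dropout,
                         random_state=random_state, dtype=dtype)
        self.conv_channels = conv_channels
        self.kernel_size = kernel_size
        self.fc_dims = fc_dims

    @staticmethod
    def flattened_width(n_features: int, conv_channels=(16, 32)) -> int:
        """Sequence length after the conv/pool stack times final channels."""
        length = n_features
        for _ in conv_channels:
            length = length // 2  # same-length conv, then floor pooling
        if length < 1:
            raise ValueError(
                f"{n_features} features are too few for two pooling stages")
        return conv_channels[-1] * length

    def _build_network(self, n_features, n_classes, rng):
        width = self.flattened_width(n_features, self.conv_channels)
        c1, c2 = self.conv_channels
        dt = self.dtype
        layers = [
            _AddChannel(),
            Conv1d(1, c1, self.kernel_size, rng, dt), ReLU(), MaxPool1d(),
            Conv1d(c1, c2, self.kernel_size, rng, dt), ReLU(), MaxPool1d(),
            Flatten(),
            Linear(width, self.fc_dims[0], rng, dt), ReLU(),
            Dropout(self.dropout, rng),
            Linear(self.fc_dims[0], self.fc_dims[1], rng, dt), ReLU(),
            Dropout(self.dropout, rng),
            Linear(self.fc_dims[1], n_classes, rng, dt),
        ]
        return Network(layers)


class _AddChannel:
    """(B, L) -> (B, 1, L) adapter in front of the conv stack."""

    def forward(self, x, train):
        return x[:, None, :]

    def backward(self, grad):
        return grad[:, 0, :]

    def parameters(self):
        return []


class FCNNClassifier(_NeuralClassifier):
    """The convolution-free ablation: identical FC head on the raw vector."""

    def __init__(self, fc_dims=(4096, 256), epochs=100, batch_size=16,
                 lr=0.001, beta1=0.9, beta2=0.999, lr_step=10, lr_gamma=0.9,
                 dropout=0.5, random_state=None, dtype=np.float32):
        super().__init__(epochs=epochs, batch_size=batch_size, lr=lr,
                         beta1=beta1, beta2=beta2, lr_step=lr_step,
                         lr_gamma=lr_gamma, dropout=dropout,
                         random_state=random_state, dtype=dtype)
        self.fc_dims = fc_dims

    def _build_network(self, n_features, n_classes, rng):
        dt = self.dtype
        layers = [
            Linear(n_features, self.fc_dims[0], rng, dt), ReLU(),
            Dropout(self.dropout, rng),
            Linear(self.fc_dims[0], self.fc_dims[1], rng, dt), ReLU(),
            Dropout(self.dropout, rng),
            Linear(self.fc_dims[1], n_classes, rng, dt),
        ]
        return Network(layers)


MODEL_KINDS = ("cnn", "fcnn", "svm", "rf")


def make_model(kind: str, seed: int | None = None, **overrides):
    """Factory over the four model families; neural overrides pass through."""
    if kind == "cnn":
        return CNNClassifier(random_state=seed, **overrides)
    if kind == "fcnn":
        return FCNNClassifier(random_state=seed, **overrides)
    if kind == "svm":
        return SVC(probability=True, random_state=seed, **overrides)
    if kind == "rf":
        return RandomForestClassifier(random_state=seed, **overrides)
    raise ValueError(f"unknown model kind {kind!r}; known: {MODEL_KINDS}")


def build_baseline(kind: str, seed: int | None = None):
    if kind not in ("svm", "rf"):
        raise ValueError(f"baseline kind must be 'svm' or 'rf', got {kind!r}")
    return make_model(kind, seed)
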