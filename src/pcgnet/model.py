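"""The weighted CNN classifier (WCNN) as a scikit-learn estimator.

``build_model`` turns an :class:`~pcgnet.arch.ArchitectureSpec` into a
trainable :class:`~pcgnet.nn.Network`; :class:`WCNNClassifier` wraps
construction, Adam training with the staircase learning-rate schedule, and
prediction behind the standard ``fit`` / ``predict`` / ``predict_proba``
estimator interface, so the model composes with sklearn model selection.

Inputs are MFCC feature maps shaped ``(n_samples, dims, frames)`` (a trailing
singleton channel axis is also accepted).  Training is fully deterministic
under ``random_state``.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .arch import ArchitectureSpec, LayerSpec, count_parameters, default_architecture

__all__ = ["build_model", "WCNNClassifier", "TrainingDivergedError"]


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


def build_model(
    arch: ArchitectureSpec,
    seed: int | None = None,
    bn_before_relu: bool = False,
) -> nn.Network:
    """Instantiate a trainable network from an architecture spec.

    Convolution blocks follow activation-then-normalization order
    (Conv -> ReLU -> BatchNorm) by default, with ``bn_before_relu`` flipping
    it; parameter and FLOP accounting are unaffected either way.  Hidden dense
    layers use ReLU; the output layer emits raw logits (softmax / sigmoid is
    applied by the loss and by ``predict_proba``).  Initialization is
    He-normal, deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    h, w, c = arch.input_shape
    flat: int | None = None
    n_dense_seen = 0
    n_dense_total = sum(1 for l in arch.layers if l.kind == "dense")
    for spec in arch.layers:
        if spec.kind == "conv":
            layers.append(nn.Conv2D(c, spec.out_channels, spec.kernel, spec.stride, rng=rng))
            h = (h - spec.kernel[0]) // spec.stride + 1
            w = (w - spec.kernel[1]) // spec.stride + 1
            c = spec.out_channels
            block = [nn.ReLU()]
            if spec.batch_norm:
                block.insert(0, nn.BatchNorm(c)) if bn_before_relu else block.append(
                    nn.BatchNorm(c)
                )
            layers.extend(block)
        elif spec.kind == "dropout":
            layers.append(nn.Dropout(spec.rate, rng=rng))
        elif spec.kind == "kwc":
            layers.append(nn.KWC())
        elif spec.kind == "flatten":
            flat = h * w * c
            layers.append(nn.Flatten())
        elif spec.kind == "dense":
            layers.append(nn.Dense(flat, spec.out_units, rng=rng))
            flat = spec.out_units
            n_dense_seen += 1
            if n_dense_seen < n_dense_total:
                layers.append(nn.ReLU())
    return nn.Network(layers)


class WCNNClassifier(ClassifierMixin, BaseEstimator):
    """Weighted CNN for fixed-geometry MFCC feature maps.

    Parameters
    ----------
    epochs, batch_size, learning_rate, decay_rate, decay_steps :
        Training schedule; the learning rate decays in a staircase,
        ``lr * decay_rate ** floor(iteration / decay_steps)``.
    loss : {"categorical_cross_entropy", "binary_cross_entropy"}
        Binary cross-entropy trains a single sigmoid logit and requires
        exactly two classes.
    use_kwc : bool
        Include the key-weighting-calculation channel-attention layer.
    dropout : float
        Rate at both dropout sites (after the third conv block and after the
        hidden dense layer).
    bn_before_relu : bool
        Normalization order inside conv blocks (default: activation first).
    random_state : int or None
        Seeds initialization, shuffling and dropout.

    Attributes
    ----------
    classes_ : ndarray of class labels
    network_ : the trained :class:`pcgnet.nn.Network`
    arch_ : the :class:`pcgnet.arch.ArchitectureSpec` built from the input
    history_ : dict of per-epoch lists (loss, accuracy, learning rate, and
        validation metrics when validation data was supplied)
    """

    def __init__(
        self,
        epochs: int = 100,
        batch_size: int = 16,
        learning_rate: float = 1e-3,
        decay_rate: float = 0.95,
        decay_steps: int = 10_000,
        loss: str = "categorical_cross_entropy",
        use_kwc: bool = True,
        dropout: float = 0.3,
        bn_before_relu: bool = False,
        n_filters: tuple[int, int, int] = (32, 64, 64),
        dense_units: int = 128,
        random_state: int | None = None,
        verbose: int = 0,
    ):
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.decay_rate = decay_rate
        self.decay_steps = decay_steps
        self.loss = loss
        self.use_kwc = use_kwc
        self.dropout = dropout
        self.bn_before_relu = bn_before_relu
        self.n_filters = n_filters
        self.dense_units = dense_units
        self.random_state = random_state
        self.verbose = verbose

    # -- helpers ---------------------------------------------------------

    def _validate_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 4 and X.shape[-1] == 1:
            X = X[..., 0]
        if X.ndim != 3:
            raise ValueError("X must be (n_samples, dims, frames)")
        return X[:, None, :, :]  # NCHW with one input channel

    def _build_arch(self, dims: int, frames: int, n_out: int) -> ArchitectureSpec:
        arch = default_architecture(
            dims=dims, frames=frames, n_classes=n_out, use_kwc=self.use_kwc,
            dropout=self.dropout,
        )
        f1, f2, f3 = self.n_filters
        convs = [l for l in arch.layers if l.kind == "conv"]
        convs[0].out_channels, convs[1].out_channels, convs[2].out_channels = f1, f2, f3
        for l in arch.layers:
            if l.kind == "dense" and l.out_units == 128:
                l.out_units = self.dense_units
        return arch

    # -- estimator API ---------------------------------------------------

    def fit(self, X, y, validation_data=None):
        X = self._validate_X(X)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y are misaligned")
        self.classes_ = np.unique(y)
        n_classes = self.classes_.size
        if self.loss == "binary_cross_entropy":
            if n_classes != 2:
                raise ValueError("binary_cross_entropy requires exactly 2 classes")
            n_out = 1
        elif self.loss == "categorical_cross_entropy":
            n_out = n_classes
        else:
            raise ValueError(f"unknown loss {self.loss!r}")

        dims, frames = X.shape[2], X.shape[3]
        self.arch_ = self._build_arch(dims, frames, n_out)
        self.network_ = build_model(
            self.arch_, seed=self.random_state, bn_before_relu=self.bn_before_relu
        )
        self.n_features_in_ = dims * frames

        y_idx = np.searchsorted(self.classes_, y)
        opt = nn.Adam(
            self.network_.params(),
            lr=self.learning_rate,
            decay_rate=self.decay_rate,
            decay_steps=self.decay_steps,
        )
        rng = np.random.default_rng(
            None if self.random_state is None else self.random_state + 1
        )
        n = X.shape[0]
        history: dict[str, list] = {
            "epoch": [], "lr": [], "train_loss": [], "train_accuracy": []
        }
        if validation_data is not None:
            history["val_loss"] = []
            history["val_accuracy"] = []

        for epoch in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            correct = 0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = X[idx], y_idx[idx]
                logits = self.network_.forward(xb, training=True)
                if n_out == 1:
                    loss, dlogits = nn.sigmoid_binary_cross_entropy(logits, yb)
                    pred = (logits.ravel() > 0).astype(int)
                else:
                    onehot = np.eye(n_out)[yb]
                    loss, dlogits = nn.softmax_cross_entropy(logits, onehot)
                    pred = logits.argmax(axis=1)
                if not np.isfinite(loss):
                    raise TrainingDivergedError(
                        f"non-finite loss at epoch {epoch}, iteration {opt.t} "
                        f"(lr={opt.current_lr():.2e}); lower the learning rate"
                    )
                correct += int((pred == yb).sum())
                losses.append(loss)
                self.network_.backward(dlogits)
                opt.step(self.network_.grads())
            history["epoch"].append(epoch)
            history["lr"].append(opt.current_lr())
            history["train_loss"].append(float(np.mean(losses)))
            history["train_accuracy"].append(correct / n)
            if validation_data is not None:
                Xv, yv = validation_data
                vloss, vacc = self._evaluate(Xv, yv)
                history["val_loss"].append(vloss)
                history["val_accuracy"].append(vacc)
            if self.verbose:
                msg = (f"epoch {epoch + 1}/{self.epochs} "
                       f"loss={history['train_loss'][-1]:.4f} "
                       f"acc={history['train_accuracy'][-1]:.4f}")
                if validation_data is not None:
                    msg += f" val_acc={history['val_accuracy'][-1]:.4f}"
                print(msg)
        self.history_ = history
        return self

    def _evaluate(self, X, y) -> tuple[float, float]:
        proba = self.predict_proba(X)
        y_idx = np.searchsorted(self.classes_, np.asarray(y))
        eps = 1e-12
        loss = float(-np.mean(np.log(np.maximum(proba[np.arange(len(y_idx)), y_idx], eps))))
        acc = float((proba.argmax(axis=1) == y_idx).mean())
        return loss, acc

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "network_")
        X = self._validate_X(X)
        outs = []
        for start in range(0, X.shape[0], 256):
            outs.append(self.network_.forward(X[start : start + 256], training=False))
        return np.concatenate(outs)

    def predict_proba(self, X) -> np.ndarray:
        logits = self.decision_function(X)
        if logits.shape[1] == 1:
            p = 1.0 / (1.0 + np.exp(-logits.ravel()))
            return np.column_stack([1.0 - p, p])
        return nn.softmax(logits)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[proba.argmax(axis=1)]

    def n_parameters(self, include_batchnorm: bool = False) -> int:
        """Trainable parameters of the fitted network (batch norm excluded by
        default, matching the analytic count)."""
        check_is_fitted(self, "network_")
        return self.network_.n_parameters(include_batchnorm=include_batchnorm)

    # -- persistence -----------------------------------------------------

    def save(self, path: str) -> None:
        """Save weights (.npz) plus a JSON sidecar with the architecture."""
        check_is_fitted(self, "network_")
        arrays = {f"p{i}": p for i, p in enumerate(self.network_.params())}
        bn_state = {}
        for i, layer in enumerate(self.network_.layers):
            if isinstance(layer, nn.BatchNorm):
                arrays[f"bn{i}_mean"] = layer.running_mean
                arrays[f"bn{i}_var"] = layer.running_var
                bn_state[str(i)] = True
        np.savez(path, **arrays)
        sidecar = {
            "params": self.get_params(),
            "classes": [str(c) for c in self.classes_],
            "input_shape": list(self.arch_.input_shape),
            "bn_layers": sorted(int(i) for i in bn_state),
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, path: str) -> "WCNNClassifier":
        with open(str(path) + ".json") as fh:
            sidecar = json.load(fh)
        params = sidecar["params"]
        params["n_filters"] = tuple(params["n_filters"])
        clf = cls(**params)
        dims, frames, _ = sidecar["input_shape"]
        clf.classes_ = np.array(sidecar["classes"])
        n_out = 1 if clf.loss == "binary_cross_entropy" else len(clf.classes_)
        clf.arch_ = clf._build_arch(dims, frames, n_out)
        clf.network_ = build_model(clf.arch_, seed=clf.random_state,
                                   bn_before_relu=clf.bn_before_relu)
        clf.n_features_in_ = dims * frames
        data = np.load(path if str(path).endswith(".npz") else str(path) + ".npz")
        for i, p in enumerate(clf.network_.params()):
            p[...] = data[f"p{i}"]
        for i in sidecar["bn_layers"]:
            layer = clf.network_.layers[i]
            layer.running_mean = data[f"bn{i}_mean"]
            layer.running_var = data[f"bn{i}_var"]
        clf.history_ = {}
        return clf
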