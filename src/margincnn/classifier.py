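"""AlexNet-style patch classifier as a scikit-learn estimator.

The reference architecture (``channel_scale=1``) is five 3x3 convolutions
(16, 256, 512, 2048, 4096 channels), two 2x2/2 max pools, and three dense
layers (512, 256 with dropout 0.5, and a 2-unit softmax output):

    Conv 3x3x16 - Conv 3x3x256 - Pool - Conv 3x3x512 - Conv 3x3x2048 -
    Conv 3x3x4096 - Pool - FC 512 - FC 256 (dropout) - FC 2 softmax

At full width this stack has on the order of 3e8 parameters;
``channel_scale`` divides every convolution channel count and hidden dense
width (never the 2-unit output) so the same topology can be trained at desk
scale. Training is plain SGD on softmax cross-entropy, epoch-shuffled
batches, all seeded.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass
from io import BytesIO
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import nn

#: Table of reference widths: conv channels and hidden dense units.
CONV_CHANNELS = (16, 256, 512, 2048, 4096)
DENSE_UNITS = (512, 256)
N_CLASSES = 2
KERNEL = 3
POOL_AFTER = (1, 4)  # pool follows conv layers at these indices
PREDICT_CHUNK = 64


@dataclass(frozen=True)
class LayerSpec:
    """One architecture row: kind, kernel size, width, activation, notes."""

    kind: str  # "conv" | "maxpool" | "dense"
    kernel: int | None
    width: int | None
    activation: str  # "relu" | "softmax" | "none"
    dropout: float = 0.0
    stride: int | None = None

    def describe(self) -> str:
        if self.kind == "conv":
            return f"Conv. ({self.kernel}x{self.kernel})x{self.width} ReLU"
        if self.kind == "maxpool":
            return f"Max-Pooling ({self.kernel}x{self.kernel}) stride {self.stride}"
        row = f"Fully-Conn. {self.width} " + ("Softmax" if self.activation == "softmax" else "ReLU")
        if self.dropout:
            row += f" (dropout {self.dropout:g})"
        return row


def scaled_width(width: int, channel_scale: float) -> int:
    w = int(width // channel_scale)
    if w < 1:
        raise ValueError(
            f"channel_scale {channel_scale} reduces a width of {width} below 1"
        )
    return w


def layer_specs(channel_scale: float = 1.0, dropout_rate: float = 0.5) -> list[LayerSpec]:
    """The architecture row list at a given width scale."""
    rows: list[LayerSpec] = []
    for i, ch in enumerate(CONV_CHANNELS):
        rows.append(LayerSpec("conv", KERNEL, scaled_width(ch, channel_scale), "relu"))
        if i in POOL_AFTER:
            rows.append(LayerSpec("maxpool", 2, None, "none", stride=2))
    for units in DENSE_UNITS[:-1]:
        rows.append(LayerSpec("dense", None, scaled_width(units, channel_scale), "relu"))
    rows.append(
        LayerSpec(
            "dense",
            None,
            scaled_width(DENSE_UNITS[-1], channel_scale),
            "relu",
            dropout=dropout_rate,
        )
    )
    rows.append(LayerSpec("dense", None, N_CLASSES, "softmax"))
    return rows


def architecture_summary(channel_scale: float = 1.0, dropout_rate: float = 0.5) -> list[str]:
    """Human-readable architecture rows (one string per layer)."""
    return [spec.describe() for spec in layer_specs(channel_scale, dropout_rate)]


@dataclass
class PatchPrediction:
    """Two-class posterior for one margin patch."""

    p_adenoma: float
    p_carcinoma: float
    hard_label: str

    def __post_init__(self) -> None:
        s = self.p_adenoma + self.p_carcinoma
        if not (0 <= self.p_adenoma <= 1 and 0 <= self.p_carcinoma <= 1 and abs(s - 1) < 1e-6):
            raise ValueError("posteriors must lie in [0,1] and sum to 1")


class CNNPatchClassifier(ClassifierMixin, BaseEstimator):
    """Small CNN over normalized margin patches.

    Parameters
    ----------
    patch_size : int, default 50
        Side length of the square input patches.
    channel_scale : float, default 1.0
        Divisor on all convolution channel counts and hidden dense widths
        (output layer excepted); must leave every width >= 1.
    epochs, batch_size, learning_rate, dropout_rate :
        Training hyperparameters; defaults are 380 epochs, batch 400,
        learning rate 1e-4, dropout 0.5.
    random_state : int or None
        Seeds initialization, epoch shuffling and dropout masks.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels seen in ``fit``.
    loss_history_ : ndarray
        Mean cross-entropy per epoch.
    network_ : Sequential
        The fitted layer stack.
    """

    def __init__(
        self,
        patch_size: int = 50,
        channel_scale: float = 1.0,
        epochs: int = 380,
        batch_size: int = 400,
        learning_rate: float = 1e-4,
        dropout_rate: float = 0.5,
        random_state: int | None = None,
    ):
        self.patch_size = patch_size
        self.channel_scale = channel_scale
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.dropout_rate = dropout_rate
        self.random_state = random_state

    # -- architecture ------------------------------------------------------

    def architecture(self) -> list[LayerSpec]:
        return layer_specs(self.channel_scale, self.dropout_rate)

    def summary(self) -> str:
        return "\n".join(s.describe() for s in self.architecture())

    def _build(self, init_rng, dropout_rng) -> nn.Sequential:
        size = self.patch_size
        layers: list[nn.Layer] = []
        cin = 1
        for i, ch in enumerate(CONV_CHANNELS):
            cout = scaled_width(ch, self.channel_scale)
            layers += [nn.Conv2D(cin, cout, init_rng, KERNEL), nn.ReLU()]
            cin = cout
            if i in POOL_AFTER:
                layers.append(nn.MaxPool2())
                size //= 2
        layers.append(nn.Flatten())
        n_in = size * size * cin
        for units in DENSE_UNITS[:-1]:
            w = scaled_width(units, self.channel_scale)
            layers += [nn.Dense(n_in, w, init_rng), nn.ReLU()]
            n_in = w
        w = scaled_width(DENSE_UNITS[-1], self.channel_scale)
        layers += [
            nn.Dense(n_in, w, init_rng),
            nn.ReLU(),
            nn.Dropout(self.dropout_rate, dropout_rng),
        ]
        layers.append(nn.Dense(w, N_CLASSES, init_rng))
        return nn.Sequential(layers)

    # -- estimator API -----------------------------------------------------

    @staticmethod
    def _validate_X(X, patch_size) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 3:
            X = X[..., None]
        if X.ndim != 4 or X.shape[1] != patch_size or X.shape[2] != patch_size or X.shape[3] != 1:
            raise ValueError(
                f"expected patches of shape (n, {patch_size}, {patch_size}[, 1]), got {X.shape}"
            )
        return X

    def fit(self, X, y):
        """Train on normalized patches ``X`` (n, size, size) with labels ``y``."""
        X = self._validate_X(X, self.patch_size)
        y = np.asarray(y)
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training set must contain both classes")
        if len(self.classes_) > N_CLASSES:
            raise ValueError("binary classifier: more than 2 classes in y")
        y_idx = np.searchsorted(self.classes_, y)

        ss = np.random.SeedSequence(self.random_state)
        init_s, shuffle_s, dropout_s = ss.spawn(3)
        init_rng = np.random.default_rng(init_s)
        shuffle_rng = np.random.default_rng(shuffle_s)
        dropout_rng = np.random.default_rng(dropout_s)
        self.network_ = self._build(init_rng, dropout_rng)

        n = len(X)
        losses = []
        for epoch in range(self.epochs):
            order = shuffle_rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                logits = self.network_.forward(X[idx], train=True)
                loss, grad = nn.softmax_cross_entropy(logits, y_idx[idx])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, batch starting {start} "
                        f"(lr={self.learning_rate}); aborting"
                    )
                self.network_.backward(grad)
                self.network_.sgd_step(self.learning_rate)
                epoch_loss += loss * len(idx)
            losses.append(epoch_loss / n)
        self.loss_history_ = np.asarray(losses)
        self.n_features_in_ = self.patch_size * self.patch_size
        return self

    def decision_logits(self, X) -> np.ndarray:
        check_is_fitted(self, "network_")
        X = self._validate_X(X, self.patch_size)
        chunks = [
            self.network_.forward(X[i : i + PREDICT_CHUNK], train=False)
            for i in range(0, len(X), PREDICT_CHUNK)
        ]
        return np.concatenate(chunks, axis=0) if chunks else np.empty((0, N_CLASSES))

    def predict_proba(self, X) -> np.ndarray:
        """Per-patch class posteriors, columns ordered as ``classes_``."""
        return nn.softmax(self.decision_logits(X).astype(np.float64))

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def predict_patches(self, X) -> list[PatchPrediction]:
        """Posteriors as :class:`PatchPrediction` records (adenoma = benign)."""
        proba = self.predict_proba(X)
        cls = list(self.classes_)
        ia = cls.index("adenoma") if "adenoma" in cls else 0
        ic = 1 - ia
        return [
            PatchPrediction(float(p[ia]), float(p[ic]), str(self.classes_[np.argmax(p)]))
            for p in proba
        ]

    # -- checkpointing -----------------------------------------------------

    def save(self, path) -> None:
        """Write a single-archive checkpoint (weights + config + fingerprint)."""
        check_is_fitted(self, "network_")
        buf = BytesIO()
        np.savez(buf, **{f"w{i}": w for i, w in enumerate(self.network_.weights())})
        meta = {
            "params": self.get_params(),
            "classes": [str(c) for c in self.classes_],
            "loss_history": [float(v) for v in self.loss_history_],
            "architecture": architecture_summary(self.channel_scale, self.dropout_rate),
        }
        with zipfile.ZipFile(Path(path), "w") as zf:
            zf.writestr("weights.npz", buf.getvalue())
            zf.writestr("meta.json", json.dumps(meta))

    @classmethod
    def load(cls, path) -> "CNNPatchClassifier":
        with zipfile.ZipFile(Path(path)) as zf:
            meta = json.loads(zf.read("meta.json"))
            with zf.open("weights.npz") as f:
                npz = np.load(BytesIO(f.read()))
                weights = [npz[k] for k in sorted(npz.files, key=lambda s: int(s[1:]))]
        est = cls(**meta["params"])
        fingerprint = architecture_summary(est.channel_scale, est.dropout_rate)
        if fingerprint != meta["architecture"]:
            raise ValueError("checkpoint architecture fingerprint mismatch")
        ss = np.random.SeedSequence(est.random_state)
        _, _, dropout_s = ss.spawn(3)
        est.network_ = est._build(np.random.default_rng(0), np.random.default_rng(dropout_s))
        est.network_.set_weights(weights)
        est.classes_ = np.asarray(meta["classes"])
        est.loss_history_ = np.asarray(meta["loss_history"])
        est.n_features_in_ = est.patch_size * est.patch_size
        return est


def build_model(**train_config) -> CNNPatchClassifier:
    """Thin functional wrapper: configure an (unfitted) patch classifier."""
    return CNNPatchClassifier(**train_config)


def train(model: CNNPatchClassifier, X, y) -> tuple[CNNPatchClassifier, np.ndarray]:
    """Fit ``model`` and return it with its per-epoch loss history."""
    model.fit(X, y)
    return model, model.loss_history_


def predict(model: CNNPatchClassifier, X) -> list[PatchPrediction]:
    return model.predict_patches(X)
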