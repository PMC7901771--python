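"""The multi-channel convolutional classifier.

Architecture: the one-hot input (rows x cols) enters ``n_channels`` parallel
branches; each branch is a convolution whose filters span the full alphabet
width (so each filter is a 1-D scan over sequence positions) with ReLU,
followed by global max-over-positions pooling.  The pooled branch outputs
are concatenated, passed through a 1024-unit ReLU layer, dropout, and a
2-unit softmax that yields the class probability distribution (index 0 =
non-site, index 1 = pseudouridine site).  Training minimizes categorical
cross-entropy with Adam and stops early when the validation loss has not
improved for a configured number of epochs, restoring the best weights.

The implementation is self-contained numpy: forward, backward and the Adam
update are written out explicitly, which keeps runs bit-reproducible from a
single integer seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ModelConfig", "MultiChannelCNN", "TrainedModel", "build_model", "train", "predict"]


@dataclass
class ModelConfig:
    """Hyperparameter bundle for the classifier.

    ``filter_heights`` holds one filter height per channel; the common case
    of a single tuned height replicated across channels is built with
    :meth:`uniform`.  ``filters_per_channel`` and ``early_stop_patience``
    are package defaults (32 and 10) — they are configurable knobs of this
    implementation, tuned values for everything else come from the staged
    cross-validated grid search.
    """

    n_channels: int = 9
    filter_heights: list[int] = field(default_factory=lambda: [5] * 9)
    filters_per_channel: int = 32
    input_rows: int = 21
    input_cols: int = 12
    dense_units: int = 1024
    dropout_p: float = 0.5
    learning_rate: float = 0.0005
    batch_size: int = 16
    max_epochs: int = 50
    early_stop_patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.filter_heights) != self.n_channels:
            raise ValueError(
                f"{len(self.filter_heights)} filter heights for {self.n_channels} channels"
            )
        for h in self.filter_heights:
            if not 1 <= h <= self.input_rows:
                raise ValueError(f"filter height {h} outside [1, {self.input_rows}]")
        if not 0 <= self.dropout_p < 1:
            raise ValueError(f"dropout_p {self.dropout_p} outside [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    @classmethod
    def uniform(cls, height: int = 5, **kwargs) -> "ModelConfig":
        """Config with every channel sharing one filter height."""
        n = kwargs.pop("n_channels", 9)
        return cls(n_channels=n, filter_heights=[height] * n, **kwargs)

    def replace(self, **kwargs) -> "ModelConfig":
        d = asdict(self)
        d.update(kwargs)
        if "n_channels" in kwargs and "filter_heights" not in kwargs:
            d["filter_heights"] = [self.filter_heights[0]] * kwargs["n_channels"]
        return ModelConfig(**d)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _to_onehot_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if y.ndim == 2 and y.shape[1] == 2:
        return y.astype(np.float64)
    out = np.zeros((len(y), 2), dtype=np.float64)
    out[np.arange(len(y)), y.astype(int)] = 1.0
    return out


class MultiChannelCNN:
    """Weights plus forward/backward machinery for one :class:`ModelConfig`."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.training_history: list[dict] = []
        self.stopped_epoch: int | None = None
        rng = np.random.default_rng(config.seed)
        cfg = config
        self.conv_w: list[np.ndarray] = []
        self.conv_b: list[np.ndarray] = []
        for h in cfg.filter_heights:
            fan_in = h * cfg.input_cols
            limit = np.sqrt(6.0 / (fan_in + cfg.filters_per_channel))
            self.conv_w.append(
                rng.uniform(-limit, limit, size=(cfg.filters_per_channel, h, cfg.input_cols))
            )
            self.conv_b.append(np.zeros(cfg.filters_per_channel))
        concat = cfg.n_channels * cfg.filters_per_channel
        limit = np.sqrt(6.0 / (concat + cfg.dense_units))
        self.w1 = rng.uniform(-limit, limit, size=(concat, cfg.dense_units))
        self.b1 = np.zeros(cfg.dense_units)
        limit = np.sqrt(6.0 / (cfg.dense_units + 2))
        self.w2 = rng.uniform(-limit, limit, size=(cfg.dense_units, 2))
        self.b2 = np.zeros(2)

    # ---- parameter bookkeeping -------------------------------------------------
    def _params(self) -> list[np.ndarray]:
        return [*self.conv_w, *self.conv_b, self.w1, self.b1, self.w2, self.b2]

    def _set_params(self, values: list[np.ndarray]) -> None:
        n = self.config.n_channels
        self.conv_w = [v.copy() for v in values[:n]]
        self.conv_b = [v.copy() for v in values[n : 2 * n]]
        self.w1, self.b1, self.w2, self.b2 = (v.copy() for v in values[2 * n :])

    def count_parameters(self) -> int:
        return sum(p.size for p in self._params())

    def conv_layer_parameter_count(self, channel: int) -> int:
        return self.conv_w[channel].size + self.conv_b[channel].size

    # ---- forward ---------------------------------------------------------------
    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        cfg = self.config
        if X.ndim != 3 or X.shape[1:] != (cfg.input_rows, cfg.input_cols):
            raise ValueError(
                f"expected input of shape (n, {cfg.input_rows}, {cfg.input_cols}), got {X.shape}"
            )
        return X

    def conv_activations(self, X: np.ndarray) -> list[np.ndarray]:
        """Per-channel post-ReLU conv maps, each of shape (n, positions, filters).

        This is the surface the motif extractor reads.
        """
        X = self._check_input(X)
        out = []
        for w, b in zip(self.conv_w, self.conv_b):
            h = w.shape[1]
            win = sliding_window_view(X, h, axis=1)  # (n, P, cols, h)
            z = np.einsum("npch,fhc->npf", win, w, optimize=True) + b
            out.append(np.maximum(z, 0.0))
        return out

    def _forward(self, X: np.ndarray, rng: np.random.Generator | None = None):
        """Full forward pass; returns probabilities and a cache for backprop.

        ``rng`` enables dropout (training mode)."""
        cfg = self.config
        pooled_parts, caches = [], []
        for w, b in zip(self.conv_w, self.conv_b):
            h = w.shape[1]
            win = sliding_window_view(X, h, axis=1)  # (n, P, cols, h)
            z = np.einsum("npch,fhc->npf", win, w, optimize=True) + b
            a = np.maximum(z, 0.0)
            arg = a.argmax(axis=1)  # (n, F) position of the max per filter
            pooled = np.take_along_axis(a, arg[:, None, :], axis=1)[:, 0, :]
            pooled_parts.append(pooled)
            caches.append((win, arg, pooled))
        feats = np.concatenate(pooled_parts, axis=1)  # (n, channels*F)
        z1 = feats @ self.w1 + self.b1
        a1 = np.maximum(z1, 0.0)
        if rng is not None and cfg.dropout_p > 0:
            mask = (rng.random(a1.shape) >= cfg.dropout_p) / (1.0 - cfg.dropout_p)
            a1d = a1 * mask
        else:
            mask = None
            a1d = a1
        probs = _softmax(a1d @ self.w2 + self.b2)
        return probs, (caches, feats, z1, a1d, mask)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities, shape (n, 2); each row sums to 1."""
        X = self._check_input(X)
        if len(X) == 0:
            return np.zeros((0, 2))
        probs, _ = self._forward(X, rng=None)
        return probs

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(probabilities, hard labels). A 0.5/0.5 tie resolves to the positive class."""
        probs = self.predict_proba(X)
        labels = (probs[:, 1] >= probs[:, 0]).astype(int)
        return probs, labels

    # ---- backward --------------------------------------------------------------
    def _backward(self, X, y_onehot, probs, cache):
        caches, feats, z1, a1d, mask = cache
        n = len(X)
        dz2 = (probs - y_onehot) / n
        g_w2 = a1d.T @ dz2
        g_b2 = dz2.sum(axis=0)
        da1 = dz2 @ self.w2.T
        if mask is not None:
            da1 = da1 * mask
        dz1 = da1 * (z1 > 0)
        g_w1 = feats.T @ dz1
        g_b1 = dz1.sum(axis=0)
        dfeats = dz1 @ self.w1.T
        F = self.config.filters_per_channel
        g_cw, g_cb = [], []
        for c, (win, arg, pooled) in enumerate(caches):
            g = dfeats[:, c * F : (c + 1) * F] * (pooled > 0)  # (n, F)
            # windows under each filter's max position: (n, F, cols, h)
            sel = np.take_along_axis(
                win, arg[:, :, None, None], axis=1
            )
            g_cw.append(np.einsum("nf,nfch->fhc", g, sel, optimize=True))
            g_cb.append(g.sum(axis=0))
        return [*g_cw, *g_cb, g_w1, g_b1, g_w2, g_b2]

    # ---- training --------------------------------------------------------------
    def fit(
        self,
        X_train: np.ndarray,
        y_train: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
    ) -> "MultiChannelCNN":
        """Train with Adam + early stopping; appends per-epoch records to
        ``training_history`` and restores the best-validation-loss weights."""
        cfg = self.config
        X_train = self._check_input(X_train)
        if len(X_train) == 0:
            raise ValueError("empty training set")
        y_train = _to_onehot_labels(y_train)
        if len(np.unique(y_train.argmax(axis=1))) < 2:
            warnings.warn(
                "training labels contain a single class; the classifier is degenerate",
                stacklevel=2,
            )
        has_val = X_val is not None and len(X_val) > 0
        if has_val:
            X_val = self._check_input(X_val)
            y_val = _to_onehot_labels(y_val)

        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
        params = self._params()
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        best_loss, best_params, best_epoch, wait = np.inf, None, -1, 0

        for epoch in range(cfg.max_epochs):
            order = rng.permutation(len(X_train))
            ep_loss, ep_correct = 0.0, 0
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                Xb, yb = X_train[idx], y_train[idx]
                probs, cache = self._forward(Xb, rng=rng)
                grads = self._backward(Xb, yb, probs, cache)
                t += 1
                params = self._params()
                for i, (p, g) in enumerate(zip(params, grads)):
                    m[i] = beta1 * m[i] + (1 - beta1) * g
                    v[i] = beta2 * v[i] + (1 - beta2) * g * g
                    mh = m[i] / (1 - beta1**t)
                    vh = v[i] / (1 - beta2**t)
                    p -= cfg.learning_rate * mh / (np.sqrt(vh) + eps)
                ep_loss += -np.sum(yb * np.log(np.clip(probs, 1e-12, None)))
                ep_correct += int((probs.argmax(1) == yb.argmax(1)).sum())
            record = {
                "epoch": epoch,
                "train_loss": ep_loss / len(X_train),
                "train_acc": ep_correct / len(X_train),
            }
            if has_val:
                val_probs = self.predict_proba(X_val)
                val_loss = -np.mean(
                    np.sum(y_val * np.log(np.clip(val_probs, 1e-12, None)), axis=1)
                )
                record["val_loss"] = float(val_loss)
                record["val_acc"] = float((val_probs.argmax(1) == y_val.argmax(1)).mean())
                if val_loss < best_loss - 1e-12:
                    best_loss, best_epoch, wait = val_loss, epoch, 0
                    best_params = [p.copy() for p in self._params()]
                else:
                    wait += 1
            self.training_history.append(record)
            if has_val and wait >= cfg.early_stop_patience:
                break
        if best_params is not None:
            self._set_params(best_params)
            self.stopped_epoch = best_epoch
        return self

    # ---- persistence -----------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Single-archive save: config JSON + all weight arrays (.npz)."""
        arrays = {f"p{i}": p for i, p in enumerate(self._params())}
        np.savez(
            Path(path),
            __config__=np.frombuffer(
                json.dumps(asdict(self.config)).encode(), dtype=np.uint8
            ),
            **arrays,
        )

    @classmethod
    def load(cls, path: str | Path) -> "MultiChannelCNN":
        data = np.load(Path(path))
        cfg = ModelConfig(**json.loads(bytes(data["__config__"]).decode()))
        model = cls(cfg)
        n_params = len(model._params())
        model._set_params([data[f"p{i}"] for i in range(n_params)])
        return model


#: Alias used in type hints: a fitted MultiChannelCNN.
TrainedModel = MultiChannelCNN


def build_model(cfg: ModelConfig) -> MultiChannelCNN:
    """Instantiate an untrained model (weights seeded from ``cfg.seed``)."""
    return MultiChannelCNN(cfg)


def train(
    model: MultiChannelCNN,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> MultiChannelCNN:
    """Functional wrapper around :meth:`MultiChannelCNN.fit`."""
    return model.fit(X_train, y_train, X_val, y_val)


def predict(model: MultiChannelCNN, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Functional wrapper around :meth:`MultiChannelCNN.predict`."""
    return model.predict(X)
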