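"""Feature-learning feedforward classifier for calcium traces.

Architecture (the trace is the input vector, one frame per dimension):

    z1 = ReLU(W1 x + b1)            (512 units, dropout p = 0.5 in training)
    z2 = W2 z1 + b2                 (128-dim pre-activation feature)
    h  = ReLU(z2)                   (dropout p = 0.2 in training)
    y  = W3 h + b3,   p = Softmax(y)

Training minimizes cross-entropy with Adam (lr 0.001), mini-batches of 32,
and early stopping on validation accuracy with a patience of 30 epochs;
the best-validation weights are retained.  Implemented directly in NumPy
so the hidden activations and gradients needed for feature extraction and
Grad-CAM-style saliency are explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class FeatureNetConfig:
    input_dim: int = 1500
    hidden1: int = 512
    hidden2: int = 128
    output_dim: int = 2
    dropout1: float = 0.5
    dropout2: float = 0.2
    lr: float = 0.001
    batch_size: int = 32
    patience: int = 30
    max_epochs: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("input_dim", "hidden1", "hidden2", "output_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("dropout1", "dropout2"):
            p = getattr(self, name)
            if not 0.0 <= p < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")


def softmax(y: np.ndarray) -> np.ndarray:
    z = y - y.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1


class FeatureNet:
    """NumPy implementation of the two-hidden-layer trace classifier."""

    def __init__(self, config: FeatureNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config
        # He initialization for the ReLU layers
        self.W1 = rng.normal(0.0, np.sqrt(2.0 / c.input_dim), (c.hidden1, c.input_dim))
        self.b1 = np.zeros(c.hidden1)
        self.W2 = rng.normal(0.0, np.sqrt(2.0 / c.hidden1), (c.hidden2, c.hidden1))
        self.b2 = np.zeros(c.hidden2)
        self.W3 = rng.normal(0.0, np.sqrt(2.0 / c.hidden2), (c.output_dim, c.hidden2))
        self.b3 = np.zeros(c.output_dim)
        self._rng = rng
        self.history = TrainingHistory()

    # ---- forward ---------------------------------------------------------

    def _forward(self, x: np.ndarray, train: bool = False) -> dict:
        c = self.config
        z1 = x @ self.W1.T + self.b1
        a1 = np.maximum(z1, 0.0)
        if train and c.dropout1 > 0:
            mask1 = (self._rng.random(a1.shape) >= c.dropout1) / (1.0 - c.dropout1)
            a1d = a1 * mask1
        else:
            mask1 = None
            a1d = a1
        z2 = a1d @ self.W2.T + self.b2
        h = np.maximum(z2, 0.0)
        if train and c.dropout2 > 0:
            mask2 = (self._rng.random(h.shape) >= c.dropout2) / (1.0 - c.dropout2)
            hd = h * mask2
        else:
            mask2 = None
            hd = h
        y = hd @ self.W3.T + self.b3
        return {"x": x, "z1": z1, "a1": a1, "a1d": a1d, "mask1": mask1,
                "z2": z2, "h": h, "hd": hd, "mask2": mask2, "y": y,
                "p": softmax(y)}

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities with dropout disabled (deterministic)."""
        return self._forward(np.asarray(x, dtype=float))["p"]

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Argmax class; ties resolve to the lower class index."""
        return np.argmax(self.predict_proba(x), axis=1)

    def features(self, x: np.ndarray) -> np.ndarray:
        """128-dim z2 pre-activation features, dropout disabled."""
        x = np.asarray(x, dtype=float)
        if x.shape[1] != self.config.input_dim:
            raise ValueError(
                f"input dim {x.shape[1]} does not match model input_dim "
                f"{self.config.input_dim}")
        return self._forward(x)["z2"]

    def hidden_activations(self, x: np.ndarray) -> np.ndarray:
        """First hidden layer activations a1 = ReLU(z1), dropout disabled."""
        return self._forward(np.asarray(x, dtype=float))["a1"]

    # ---- backward --------------------------------------------------------

    def _backward(self, cache: dict, labels: np.ndarray) -> dict:
        n = labels.shape[0]
        dy = cache["p"].copy()
        dy[np.arange(n), labels] -= 1.0
        dy /= n
        grads = {}
        grads["W3"] = dy.T @ cache["hd"]
        grads["b3"] = dy.sum(axis=0)
        dhd = dy @ self.W3
        dh = dhd * cache["mask2"] if cache["mask2"] is not None else dhd
        dz2 = dh * (cache["z2"] > 0)
        grads["W2"] = dz2.T @ cache["a1d"]
        grads["b2"] = dz2.sum(axis=0)
        da1d = dz2 @ self.W2
        da1 = da1d * cache["mask1"] if cache["mask1"] is not None else da1d
        dz1 = da1 * (cache["z1"] > 0)
        grads["W1"] = dz1.T @ cache["x"]
        grads["b1"] = dz1.sum(axis=0)
        return grads

    def class_input_gradient(self, x: np.ndarray, target_class: np.ndarray) -> np.ndarray:
        """∂y_c/∂x per cell (dropout disabled) for saliency variants."""
        x = np.asarray(x, dtype=float)
        cache = self._forward(x)
        n = x.shape[0]
        dy = np.zeros_like(cache["y"])
        dy[np.arange(n), target_class] = 1.0
        dh = dy @ self.W3
        dz2 = dh * (cache["z2"] > 0)
        da1 = dz2 @ self.W2
        dz1 = da1 * (cache["z1"] > 0)
        return dz1 @ self.W1

    def class_hidden_gradient(self, x: np.ndarray, target_class: np.ndarray) -> np.ndarray:
        """α = ∂y_c/∂a1 per cell at the first hidden layer (dropout disabled)."""
        x = np.asarray(x, dtype=float)
        cache = self._forward(x)
        n = x.shape[0]
        dy = np.zeros_like(cache["y"])
        dy[np.arange(n), target_class] = 1.0
        dh = dy @ self.W3
        dz2 = dh * (cache["z2"] > 0)
        return dz2 @ self.W2

    # ---- training --------------------------------------------------------

    def _params(self) -> dict:
        return {"W1": self.W1, "b1": self.b1, "W2": self.W2, "b2": self.b2,
                "W3": self.W3, "b3": self.b3}

    def _snapshot(self) -> dict:
        return {k: v.copy() for k, v in self._params().items()}

    def _restore(self, snap: dict) -> None:
        for k, v in snap.items():
            setattr(self, k, v.copy())

    def fit(self, x: np.ndarray, labels: np.ndarray,
            x_val: np.ndarray, labels_val: np.ndarray) -> TrainingHistory:
        """Mini-batch Adam training with early stopping on validation accuracy."""
        c = self.config
        x = np.asarray(x, dtype=float)
        labels = np.asarray(labels, dtype=int)
        if x.shape[1] != c.input_dim:
            raise ValueError(f"input dim {x.shape[1]} != config input_dim {c.input_dim}")
        m = {k: np.zeros_like(v) for k, v in self._params().items()}
        v = {k: np.zeros_like(p) for k, p in self._params().items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        best_acc, best_snap, since_best = -1.0, self._snapshot(), 0
        n = x.shape[0]
        for epoch in range(c.max_epochs):
            order = self._rng.permutation(n)
            losses = []
            for start in range(0, n, c.batch_size):
                idx = order[start:start + c.batch_size]
                cache = self._forward(x[idx], train=True)
                p = cache["p"]
                loss = -np.mean(np.log(np.maximum(
                    p[np.arange(idx.size), labels[idx]], 1e-12)))
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}")
                losses.append(loss)
                grads = self._backward(cache, labels[idx])
                t += 1
                params = self._params()
                for k in params:
                    m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                    v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                    m_hat = m[k] / (1 - beta1 ** t)
                    v_hat = v[k] / (1 - beta2 ** t)
                    params[k] -= c.lr * m_hat / (np.sqrt(v_hat) + eps)
            val_acc = float(np.mean(self.predict(x_val) == labels_val))
            self.history.train_loss.append(float(np.mean(losses)))
            self.history.val_accuracy.append(val_acc)
            if val_acc >= best_acc:
                # ties keep the later (more-trained, lower-loss) weights;
                # patience counts only strict improvements
                if val_acc > best_acc:
                    since_best = 0
                else:
                    since_best += 1
                best_acc, best_snap = val_acc, self._snapshot()
                self.history.best_epoch = epoch
            else:
                since_best += 1
            if since_best >= c.patience:
                break
        self.history.stopped_epoch = epoch
        self._restore(best_snap)
        return self.history
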