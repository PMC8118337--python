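"""Dual-stage shape recognition network.

Stage 1 is a 544-54-7 softmax classifier (cross-entropy); any cell whose
top probability does not exceed the 75% confidence threshold is assigned
to "unknown".  Cells recognised as SDE shapes are forwarded to stage 2,
a 544-544-1 bounded regressor (tanh output, MSE) that places them on the
continuous [-1, +1] scale.

The networks are small enough that a self-contained numpy implementation
with an Adam optimizer (step-size 1e-3, beta1 0.9, beta2 0.999) trains
them in seconds and keeps every run bit-deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .sde import STAGE1_LABELS


class ModelFormatError(ValueError):
    """Raised for unreadable or incompatible model files."""


class CompatibilityError(ValueError):
    """Raised when a model is applied to descriptors of a different config."""


@dataclass
class Stage1Config:
    input_dim: int = 544
    hidden_dim: int = 54
    output_dim: int = 7
    epochs: int = 100
    batch_size: int = 100
    restarts: int = 100
    confidence_threshold: float = 0.75
    learning_rate: float = 1e-3
    labels: tuple[str, ...] = STAGE1_LABELS

    loss: str = "crossentropy"

    def __post_init__(self) -> None:
        if not 0.0 < self.confidence_threshold < 1.0:
            raise ValueError("confidence_threshold must lie in (0, 1)")
        if len(self.labels) != self.output_dim:
            raise ValueError("labels must match output_dim")


@dataclass
class Stage2Config:
    input_dim: int = 544
    hidden_dim: int = 544
    output_dim: int = 1
    epochs: int = 40
    batch_size: int = 100
    restarts: int = 100
    learning_rate: float = 1e-3
    output_activation: str = "tanh"  # bounded in [-1, 1]; "linear" clips instead

    loss: str = "mse"


@dataclass
class CellResult:
    cell_id: str
    class_probabilities: np.ndarray  # length-7 simplex over STAGE1_LABELS
    predicted_class: str
    sde_score: float | None = None


# ------------------------------------------------------------------ the network


def _he_init(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    return rng.normal(scale=np.sqrt(2.0 / n_in), size=(n_in, n_out))


class MLP:
    """One-hidden-layer perceptron with a ReLU hidden layer.

    kind = "softmax" (cross-entropy loss) or "tanh"/"linear" scalar
    output (MSE loss).
    """

    def __init__(self, n_in: int, n_hidden: int, n_out: int, kind: str, seed: int = 0):
        if kind not in ("softmax", "tanh", "linear"):
            raise ValueError(f"bad output kind {kind!r}")
        rng = np.random.default_rng(np.random.SeedSequence([0x4D4C50, seed]))
        self.kind = kind
        self.seed = seed
        self.W1 = _he_init(rng, n_in, n_hidden)
        self.b1 = np.zeros(n_hidden)
        self.W2 = _he_init(rng, n_hidden, n_out)
        self.b2 = np.zeros(n_out)
        self.meta: dict = {}

    # forward -----------------------------------------------------------

    def _hidden(self, X: np.ndarray) -> np.ndarray:
        return np.maximum(X @ self.W1 + self.b1, 0.0)

    def forward(self, X: np.ndarray) -> np.ndarray:
        z = self._hidden(X) @ self.W2 + self.b2
        if self.kind == "softmax":
            z = z - z.max(axis=1, keepdims=True)
            e = np.exp(z)
            return e / e.sum(axis=1, keepdims=True)
        if self.kind == "tanh":
            return np.tanh(z)
        return z

    def loss(self, X: np.ndarray, y: np.ndarray) -> float:
        p = self.forward(X)
        if self.kind == "softmax":
            eps = 1e-12
            return float(-np.mean(np.log(p[np.arange(len(y)), y] + eps)))
        return float(np.mean((p.ravel() - y) ** 2))

    def accuracy(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.forward(X).argmax(axis=1) == y))

    # training ----------------------------------------------------------

    def _gradients(self, X: np.ndarray, y: np.ndarray):
        h_lin = X @ self.W1 + self.b1
        h = np.maximum(h_lin, 0.0)
        z = h @ self.W2 + self.b2
        B = len(X)
        if self.kind == "softmax":
            z = z - z.max(axis=1, keepdims=True)
            e = np.exp(z)
            p = e / e.sum(axis=1, keepdims=True)
            delta = p
            delta[np.arange(B), y] -= 1.0
            delta /= B
        elif self.kind == "tanh":
            a = np.tanh(z).ravel()
            delta = (2.0 * (a - y) * (1.0 - a * a) / B)[:, None]
        else:
            delta = (2.0 * (z.ravel() - y) / B)[:, None]
        gW2 = h.T @ delta
        gb2 = delta.sum(axis=0)
        dh = (delta @ self.W2.T) * (h_lin > 0)
        gW1 = X.T @ dh
        gb1 = dh.sum(axis=0)
        return gW1, gb1, gW2, gb2

    def params(self):
        return [self.W1, self.b1, self.W2, self.b2]


def train_stage(
    config: Stage1Config | Stage2Config,
    train_X: np.ndarray,
    train_y: np.ndarray,
    val_X: np.ndarray,
    val_y: np.ndarray,
    seed: int = 0,
) -> tuple[MLP, dict]:
    """Train one stage with Adam; returns the model and per-epoch history.

    History records train/validation loss (and categorical accuracy for
    the classification stage).  Deterministic for a fixed seed.
    """
    train_X = np.asarray(train_X, dtype=np.float64)
    val_X = np.asarray(val_X, dtype=np.float64)
    is_classifier = isinstance(config, Stage1Config)
    if train_X.shape[1] != config.input_dim:
        raise ValueError(f"descriptor dimension {train_X.shape[1]} != {config.input_dim}")
    if len(train_X) == 0 or len(val_X) == 0:
        raise ValueError("empty partition")
    if is_classifier:
        train_y = np.asarray(train_y, dtype=np.int64)
        val_y = np.asarray(val_y, dtype=np.int64)
        kind = "softmax"
        n_out = config.output_dim
    else:
        train_y = np.asarray(train_y, dtype=np.float64)
        val_y = np.asarray(val_y, dtype=np.float64)
        kind = config.output_activation
        n_out = 1
    model = MLP(config.input_dim, config.hidden_dim, n_out, kind, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([0x414441, seed]))
    lr, b1, b2, eps = config.learning_rate, 0.9, 0.999, 1e-8
    ms = [np.zeros_like(p) for p in model.params()]
    vs = [np.zeros_like(p) for p in model.params()]
    t = 0
    history = {"train_loss": [], "val_loss": [], "train_acc": [], "val_acc": []}
    n = len(train_X)
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            grads = model._gradients(train_X[sel], train_y[sel])
            t += 1
            params = model.params()
            for i, g in enumerate(grads):
                ms[i] = b1 * ms[i] + (1 - b1) * g
                vs[i] = b2 * vs[i] + (1 - b2) * g * g
                mhat = ms[i] / (1 - b1**t)
                vhat = vs[i] / (1 - b2**t)
                params[i] -= lr * mhat / (np.sqrt(vhat) + eps)
        history["train_loss"].append(model.loss(train_X, train_y))
        history["val_loss"].append(model.loss(val_X, val_y))
        if is_classifier:
            history["train_acc"].append(model.accuracy(train_X, train_y))
            history["val_acc"].append(model.accuracy(val_X, val_y))
    model.meta = {"stage": 1 if is_classifier else 2, "seed": seed}
    return model, history


def multi_restart_select(
    config: Stage1Config | Stage2Config,
    train_X: np.ndarray,
    train_y: np.ndarray,
    val_X: np.ndarray,
    val_y: np.ndarray,
    n_restarts: int | None = None,
    base_seed: int = 0,
) -> tuple[MLP, list[dict]]:
    """Train with several random starting conditions; keep the model with
    the lowest final validation loss (ties broken by validation accuracy
    for the classifier).  Returns the winner and the selection log."""
    n_restarts = n_restarts if n_restarts is not None else config.restarts
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    best = None
    log = []
    for k in range(n_restarts):
        seed = base_seed + k
        model, history = train_stage(config, train_X, train_y, val_X, val_y, seed=seed)
        entry = {
            "seed": seed,
            "val_loss": history["val_loss"][-1],
            "val_acc": history["val_acc"][-1] if history["val_acc"] else None,
        }
        log.append(entry)
        key = (entry["val_loss"], -(entry["val_acc"] or 0.0))
        if best is None or key < best[0]:
            best = (key, model, history)
    model = best[1]
    model.meta["selection_log"] = log
    model.meta["history"] = best[2]
    return model, log


# ------------------------------------------------------------------ inference


def classify_with_threshold(
    model: MLP, vector: np.ndarray, labels: tuple[str, ...] = STAGE1_LABELS, threshold: float = 0.75
) -> tuple[np.ndarray, str]:
    """Probabilities plus the thresholded label: argmax if its probability
    exceeds *threshold*, otherwise (or if argmax is the unknown slot)
    "unknown"."""
    vector = np.asarray(vector, dtype=np.float64).ravel()
    if vector.shape[0] != model.W1.shape[0]:
        raise ValueError(f"descriptor length {vector.shape[0]} != {model.W1.shape[0]}")
    probs = model.forward(vector[None, :])[0]
    top = int(probs.argmax())
    label = labels[top] if probs[top] > threshold else "unknown"
    return probs, label


def predict_pipeline(
    stage1: MLP,
    stage2: MLP | None,
    descriptors: np.ndarray,
    cell_ids: list[str] | None = None,
    labels: tuple[str, ...] = STAGE1_LABELS,
    threshold: float = 0.75,
) -> list[CellResult]:
    """Full verdict for each cell: thresholded class, and an SDE score
    (clipped to [-1, 1]) for cells routed to the regression stage."""
    descriptors = np.atleast_2d(np.asarray(descriptors, dtype=np.float64))
    if descriptors.shape[0] == 0 or descriptors.size == 0:
        return []
    cell_ids = cell_ids or [f"cell{k}" for k in range(len(descriptors))]
    probs = stage1.forward(descriptors)
    results = []
    for k, cid in enumerate(cell_ids):
        top = int(probs[k].argmax())
        label = labels[top] if probs[k, top] > threshold else "unknown"
        score = None
        if label == "sde" and stage2 is not None:
            raw = float(stage2.forward(descriptors[k : k + 1]).ravel()[0])
            score = float(np.clip(raw, -1.0, 1.0))
        results.append(CellResult(cid, probs[k], label, score))
    return results


# ------------------------------------------------------------------ persistence


def save_model(model: MLP, path, descriptor_hash: str = "") -> None:
    """Portable archive: architecture JSON plus weight arrays (npz)."""
    path = Path(path)
    arch = {
        "kind": model.kind,
        "n_in": int(model.W1.shape[0]),
        "n_hidden": int(model.W1.shape[1]),
        "n_out": int(model.W2.shape[1]),
        "descriptor_hash": descriptor_hash,
        "meta": {k: v for k, v in model.meta.items() if k in ("stage", "seed")},
    }
    np.savez(
        path,
        arch=np.frombuffer(json.dumps(arch).encode(), dtype=np.uint8),
        W1=model.W1, b1=model.b1, W2=model.W2, b2=model.b2,
    )


def load_model(path, descriptor_hash: str | None = None) -> MLP:
    path = Path(path)
    if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
        path = path.with_suffix(path.suffix + ".npz")
    try:
        data = np.load(path)
        arch = json.loads(bytes(data["arch"]).decode())
        W1, b1, W2, b2 = data["W1"], data["b1"], data["W2"], data["b2"]
    except Exception as exc:  # noqa: BLE001 - normalise file errors
        raise ModelFormatError(f"cannot read model {path}: {exc}") from exc
    if descriptor_hash is not None and arch.get("descriptor_hash") and arch["descriptor_hash"] != descriptor_hash:
        raise CompatibilityError(
            f"model was trained on descriptor config {arch['descriptor_hash']}, "
            f"but {descriptor_hash} was supplied"
        )
    model = MLP(arch["n_in"], arch["n_hidden"], arch["n_out"], arch["kind"])
    model.W1, model.b1, model.W2, model.b2 = W1, b1, W2, b2
    model.meta = arch.get("meta", {})
    model.meta["descriptor_hash"] = arch.get("descriptor_hash", "")
    return model
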