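"""Training loop: AdamW, one-cycle schedule, CE / BCE-with-logits losses.

Defaults follow the reference recipe: AdamW with weight decay 1e-5 and a
one-cycle learning-rate schedule peaking at the configured rate; loss is
cross-entropy for single-label tasks and binary cross-entropy with
logits for multi-label ones.  Training is bit-reproducible for a fixed
seed (NumPy only, deterministic shuffling and initialization).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Network

__all__ = [
    "TrainConfig", "train", "evaluate",
    "cross_entropy_loss", "bce_with_logits_loss",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 10
    batch_size: int = 64
    learning_rate: float = 1e-3
    weight_decay: float = 1e-5
    schedule: str = "one_cycle"  # or "constant"
    seed: int = 0

    def __post_init__(self):
        if min(self.epochs, self.batch_size) < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch size and learning rate must be positive")


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_loss(logits: np.ndarray, labels: np.ndarray):
    """Mean softmax cross-entropy; returns (loss, dlogits)."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = -np.mean(np.log(p[np.arange(n), labels] + 1e-300))
    d = p
    d[np.arange(n), labels] -= 1.0
    return float(loss), (d / n).astype(np.float32)


def bce_with_logits_loss(logits: np.ndarray, targets: np.ndarray):
    """Mean elementwise binary cross-entropy on logits (multi-label)."""
    z = logits.astype(np.float64)
    t = targets.astype(np.float64)
    loss = np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z))))
    sig = 1.0 / (1.0 + np.exp(-z))
    return float(loss), ((sig - t) / z.size).astype(np.float32)


class AdamW:
    def __init__(self, params, lr, weight_decay=1e-5, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            if p.decay and self.wd:
                p.value *= 1.0 - self.lr * self.wd  # decoupled decay
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def one_cycle_lr(step: int, total_steps: int, max_lr: float,
                 pct_start: float = 0.3, div_factor: float = 25.0,
                 final_div_factor: float = 1e4) -> float:
    """Cosine one-cycle schedule: warm up to max_lr, anneal to max_lr/1e4/25."""
    initial = max_lr / div_factor
    final = initial / final_div_factor
    up = max(int(pct_start * total_steps), 1)
    if step < up:
        frac = step / up
        return initial + (max_lr - initial) * (1 - np.cos(np.pi * frac)) / 2
    frac = (step - up) / max(total_steps - up, 1)
    return final + (max_lr - final) * (1 + np.cos(np.pi * frac)) / 2


def _auc_score(labels: np.ndarray, probs: np.ndarray) -> float:
    from sklearn.metrics import roc_auc_score

    try:
        if probs.ndim == 2 and probs.shape[1] == 2:
            return float(roc_auc_score(labels, probs[:, 1]))
        if probs.ndim == 2 and probs.shape[1] > 2:
            return float(roc_auc_score(labels, probs, multi_class="ovr"))
        return float(roc_auc_score(labels, probs))
    except ValueError:  # a split with a single class present
        return float("nan")


def evaluate(model: Network, X: np.ndarray, y: np.ndarray,
             batch_size: int = 64, loss: str = "cross_entropy") -> dict:
    """Loss / accuracy / AUC of a model in inference mode."""
    logits = predict_logits(model, X, batch_size)
    if loss == "cross_entropy":
        val, _ = cross_entropy_loss(logits, y)
        probs = softmax(logits.astype(np.float64))
        acc = float(np.mean(np.argmax(logits, axis=1) == y))
    else:
        val, _ = bce_with_logits_loss(logits, y)
        probs = 1.0 / (1.0 + np.exp(-logits.astype(np.float64)))
        acc = float(np.mean((probs > 0.5) == (y > 0.5)))
    return {"loss": val, "acc": acc, "auc": _auc_score(y, probs)}


def predict_logits(model: Network, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
    outs = []
    for i in range(0, X.shape[0], batch_size):
        outs.append(model.forward(X[i : i + batch_size], training=False))
    return np.concatenate(outs, axis=0)


def train(
    model: Network,
    X_train: np.ndarray,
    y_train: np.ndarray,
    config: TrainConfig,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    verbose: bool = False,
) -> list[dict]:
    """Optimize in place; returns the per-epoch metric log.

    Each record holds epoch index, split name, loss, ACC and AUC, so the
    log can be dumped directly as CSV rows.
    """
    loss_kind = model.config.loss
    loss_fn = cross_entropy_loss if loss_kind == "cross_entropy" else bce_with_logits_loss
    if loss_kind == "cross_entropy" and y_train.ndim != 1:
        raise ValueError("cross-entropy expects integer class labels")
    if loss_kind == "bce_with_logits" and y_train.ndim != 2:
        raise ValueError("bce-with-logits expects a (n, classes) multi-label target")
    rng = np.random.default_rng(config.seed)
    n = X_train.shape[0]
    steps_per_epoch = -(-n // config.batch_size)
    total_steps = steps_per_epoch * config.epochs
    opt = AdamW(model.parameters(), config.learning_rate, config.weight_decay)
    history: list[dict] = []
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            if config.schedule == "one_cycle":
                opt.lr = one_cycle_lr(step, total_steps, config.learning_rate)
            opt.zero_grad()
            logits = model.forward(X_train[idx], training=True)
            loss, dlogits = loss_fn(logits, y_train[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss {loss} at epoch {epoch} step {step}; "
                    f"lr={opt.lr:.3g}"
                )
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss * idx.size
            step += 1
        rec = {"epoch": epoch, "split": "train", "loss": epoch_loss / n}
        tr_eval = evaluate(model, X_train, y_train, config.batch_size, loss_kind)
        rec.update(acc=tr_eval["acc"], auc=tr_eval["auc"])
        history.append(rec)
        if X_val is not None and len(X_val):
            ev = evaluate(model, X_val, y_val, config.batch_size, loss_kind)
            history.append({"epoch": epoch, "split": "val", **ev})
        if verbose:
            print(history[-1])
    return history
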