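"""Classifier training with plain, statically smoothed, or dynamically
smoothed labels.

The loss is binary cross-entropy on sigmoid probabilities,
``L = -sum_i [t_i log p_i + (1 - t_i) log(1 - p_i)]``, where the target t is
the hard label y, the static smooth label ``(1 - eps) y + eps/2``, or the
dynamic smooth label whose per-sample weight ``eps' = 0.2 * sigmoid(head(f))``
comes from the context-tile features f of each patch. In dynamic mode the
fully connected head is optimized jointly with the classifier through the
classification loss (the frozen context encoder only supplies features).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .models import EPSILON_PRIME_FACTOR

__all__ = ["TrainConfig", "smooth_label", "bce_loss", "train_classifier"]

log = logging.getLogger(__name__)

P_CLAMP = 1e-7  # numerical clamp of probabilities inside the loss


def smooth_label(y: np.ndarray | float, eps: np.ndarray | float) -> np.ndarray | float:
    """Smooth target (1 - eps) * y + eps / 2; eps in [0, 1]."""
    eps_arr = np.asarray(eps, dtype=np.float64)
    if np.any(eps_arr < 0) or np.any(eps_arr > 1):
        raise ValueError("smoothing weight eps must lie in [0, 1]")
    out = (1.0 - eps_arr) * np.asarray(y, dtype=np.float64) + eps_arr / 2.0
    return float(out) if out.ndim == 0 else out


def bce_loss(p: np.ndarray, t: np.ndarray, reduction: str = "sum") -> float:
    """Cross-entropy -sum t log p + (1-t) log(1-p); supports smooth targets.

    Probabilities at exactly 0 or 1 are clamped to [P_CLAMP, 1 - P_CLAMP]
    (logged), keeping the loss finite.
    """
    p = np.asarray(p, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        log.info("clamping %d saturated probabilities in bce_loss",
                 int(np.sum((p <= 0) | (p >= 1))))
        p = np.clip(p, P_CLAMP, 1.0 - P_CLAMP)
    terms = -(t * np.log(p) + (1.0 - t) * np.log(1.0 - p))
    if reduction == "sum":
        return float(terms.sum())
    if reduction == "mean":
        return float(terms.mean())
    raise ValueError(f"unknown reduction {reduction!r}")


@dataclass
class TrainConfig:
    """Training defaults: Adam, batch 32, learning rate 1e-4."""

    batch_size: int = 32
    learning_rate: float = 1e-4
    epochs: int = 30
    loss_mode: str = "hard"  # hard | static_smooth | dynamic_smooth
    static_eps: float = 0.2
    seed: int = 0
    select_by_val: bool = True
    augment: bool = False  # random dihedral (flip/rot90) views per sample

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.learning_rate <= 0 or self.epochs < 1:
            raise ValueError("hyperparameters must be positive")
        if self.loss_mode not in ("hard", "static_smooth", "dynamic_smooth"):
            raise ValueError(f"unknown loss_mode {self.loss_mode!r}")
        if not 0.0 <= self.static_eps <= 1.0:
            raise ValueError("static_eps must lie in [0, 1]")


def _dihedral(x: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Apply one of the 8 square symmetries per sample (code 0..7)."""
    out = np.empty_like(x)
    for i, c in enumerate(codes):
        v = np.rot90(x[i], k=c % 4, axes=(1, 2))
        if c >= 4:
            v = v[:, :, ::-1]
        out[i] = v
    return out


def _accuracy(model: nn.Sequential, x: np.ndarray, y: np.ndarray, bs: int = 64) -> float:
    from .models import predict_proba

    p = predict_proba(model, x, batch_size=bs)
    return float(np.mean((p >= 0.5).astype(int) == y))


def train_classifier(
    model: nn.Sequential,
    x: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    polymer_features: np.ndarray | None = None,
    epsilon_head: nn.Sequential | None = None,
) -> tuple[nn.Sequential, pd.DataFrame, dict]:
    """Train the patch classifier; returns (model, history, extras).

    ``x``: (N,3,S,S) float32, ``y``: (N,) hard {0,1} labels. In
    ``dynamic_smooth`` mode, ``polymer_features`` holds the frozen context
    features of each training sample (row-aligned with x) and
    ``epsilon_head`` the trainable fully connected head. ``extras`` carries
    the per-sample eps' values observed in the final epoch and, when a
    validation set is given and ``select_by_val`` is set, the model is rolled
    back to the epoch with the best validation accuracy.
    """
    y = np.asarray(y, dtype=np.float64)
    if len(x) == 0:
        raise ValueError("empty training set")
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    dynamic = config.loss_mode == "dynamic_smooth"
    if dynamic and (polymer_features is None or epsilon_head is None):
        raise ValueError("dynamic_smooth needs polymer_features and epsilon_head")

    params = model.params() + (epsilon_head.params() if dynamic else [])
    opt = nn.Adam(params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history: list[dict] = []
    best_val, best_state = -1.0, None
    eps_prime_last: np.ndarray | None = None

    for epoch in range(config.epochs):
        order = rng.permutation(len(x))
        losses = []
        correct = 0
        eps_primes_epoch = np.empty(len(x), dtype=np.float64)
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            xb, yb = x[idx], y[idx]
            if config.augment:
                xb = _dihedral(xb, rng.integers(0, 8, size=len(idx)))
            b = len(idx)
            opt.zero_grad()
            z = model.forward(xb)[:, 0]
            p = nn.sigmoid(z)

            if config.loss_mode == "hard":
                t = yb
            elif config.loss_mode == "static_smooth":
                t = smooth_label(yb, config.static_eps)
            else:
                fb = polymer_features[idx]
                u = epsilon_head.forward(fb)[:, 0]
                eps = np.asarray(nn.sigmoid(u))
                epsp = EPSILON_PRIME_FACTOR * eps
                eps_primes_epoch[idx] = epsp
                t = smooth_label(yb, epsp)

            loss = bce_loss(p, t, reduction="mean")
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"loss diverged to {loss} at epoch {epoch}, batch {i // config.batch_size}"
                )
            losses.append(loss)
            correct += int(np.sum((p >= 0.5).astype(int) == yb))

            dz = ((p - t) / b).astype(np.float32)[:, None]
            model.backward(dz)
            if dynamic:
                # dL/dt = log((1-p)/p) = -z ; dt/deps' = 0.5 - y ;
                # deps'/du = 0.2 * eps * (1 - eps)
                du = (-z / b) * (0.5 - yb) * EPSILON_PRIME_FACTOR * eps * (1.0 - eps)
                epsilon_head.backward(du.astype(np.float32)[:, None])
            opt.step()

        row = {
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "train_acc": correct / len(x),
        }
        if dynamic:
            eps_prime_last = eps_primes_epoch
            row["eps_prime_mean"] = float(eps_primes_epoch.mean())
            row["eps_prime_min"] = float(eps_primes_epoch.min())
            row["eps_prime_max"] = float(eps_primes_epoch.max())
        if x_val is not None and y_val is not None and len(x_val):
            val_acc = _accuracy(model, x_val, np.asarray(y_val, dtype=np.float64))
            row["val_acc"] = val_acc
            if config.select_by_val and val_acc > best_val:
                best_val = val_acc
                best_state = [p_.value.copy() for p_ in model.params()]
        history.append(row)

    if best_state is not None:
        for p_, saved in zip(model.params(), best_state):
            p_.value[...] = saved

    extras = {"eps_prime_last_epoch": eps_prime_last, "best_val_acc": best_val}
    return model, pd.DataFrame(history), extras
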