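"""Training loop with validation-based early stopping."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import Adam, mse_loss
from .data import TilePairSet
from .model import MultiScaleNet

logger = logging.getLogger("holorec.nnet")

__all__ = ["TrainingState", "train", "to_channels", "from_channels"]


def to_channels(arr: np.ndarray) -> np.ndarray:
    """Complex (H, W) -> real (2, H, W): channel 0 real, channel 1 imaginary."""
    return np.stack([arr.real, arr.imag]).astype(np.float64)


def from_channels(arr: np.ndarray) -> np.ndarray:
    """Real (2, H, W) -> complex (H, W)."""
    return arr[0] + 1j * arr[1]


@dataclass
class TrainingState:
    """Outcome of a training run."""

    epoch: int = 0
    train_loss_history: list = field(default_factory=list)
    val_metric_history: list = field(default_factory=list)
    best_epoch: int = -1
    best_val: float = np.inf
    stop_reason: str = "max_epochs"


def _batch(tiles: TilePairSet, idx: list[int]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([to_channels(tiles.inputs[i]) for i in idx])
    y = np.stack([to_channels(tiles.targets[i]) for i in idx])
    return x, y


def _validation_loss(model: MultiScaleNet, tiles: TilePairSet, idx: list[int], bs: int) -> float:
    total, count = 0.0, 0
    for k in range(0, len(idx), bs):
        x, y = _batch(tiles, idx[k : k + bs])
        loss, _ = mse_loss(model(x), y)
        total += loss * len(idx[k : k + bs])
        count += len(idx[k : k + bs])
    return total / count


def train(
    model: MultiScaleNet,
    tiles: TilePairSet,
    lr: float = 1e-4,
    batch_size: int = 4,
    max_epochs: int = 100,
    patience: int = 5,
    seed: int = 0,
) -> TrainingState:
    """Train ``model`` on the train split, early-stopping on validation loss.

    Minimizes pixelwise MSE over both (real, imaginary) channels with Adam.
    The best-validation parameters are checkpointed in memory and restored
    before returning. Stops when the validation metric fails to improve for
    ``patience`` consecutive epochs (``stop_reason = "validation_decline"``)
    or at ``max_epochs``.
    """
    train_idx = tiles.indices("train")
    val_idx = tiles.indices("validation")
    if not train_idx:
        raise ValueError("empty training split")
    if not val_idx:
        raise ValueError("empty validation split: early stopping undefined")

    rng = np.random.default_rng(seed)
    opt = Adam(model.parameters(), lr=lr)
    state = TrainingState()
    best_params = model.get_state()
    since_best = 0

    for epoch in range(max_epochs):
        order = np.array(train_idx)
        rng.shuffle(order)
        epoch_loss, seen = 0.0, 0
        for k in range(0, len(order), batch_size):
            x, y = _batch(tiles, list(order[k : k + batch_size]))
            pred = model(x)
            loss, grad = mse_loss(pred, y)
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            epoch_loss += loss * x.shape[0]
            seen += x.shape[0]
        train_loss = epoch_loss / seen
        val_loss = _validation_loss(model, tiles, val_idx, batch_size)

        state.epoch = epoch + 1
        state.train_loss_history.append(train_loss)
        state.val_metric_history.append(val_loss)
        logger.info("epoch %d: train %.3e, val %.3e", epoch + 1, train_loss, val_loss)

        if val_loss < state.best_val:
            state.best_val = val_loss
            state.best_epoch = epoch + 1
            best_params = model.get_state()
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                state.stop_reason = "validation_decline"
                break

    model.set_state(best_params)
    return state
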