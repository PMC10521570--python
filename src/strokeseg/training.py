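"""Lesion-focused training: per-image soft-Dice objective and the fit loop.

Lesions occupy a small fraction of each slice, so a pixel-wise cross-entropy
is dominated by background; the objective here is instead the mean over the
batch of per-image soft Dice,

    S(t, p) = 1 - (2 * sum(t*p) + eps) / (sum(t) + sum(p) + eps)

which scores foreground overlap directly and is flat in the background. The
smoothing constant ``eps`` keeps empty-mask images well-defined (an empty
target with an empty prediction scores a loss of 0).

Optimisation is Adam on all trainable parameters with an L2 penalty on
convolution kernels only; weights start from the He-normal initialisation
the layer library applies at construction.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ShapeError, TrainingError
from .io import SlicePair
from .models import CNNRes, Network, UNet
from .models.convention import BlockConvention
from .nn import Adam

__all__ = [
    "TrainingConfig", "TrainingResult", "soft_dice_loss", "batch_loss",
    "soft_dice_loss_and_grad", "train", "stack_slices",
    "save_checkpoint", "load_checkpoint", "DESK_SCALE_OVERRIDES",
]

# Overrides for quick CPU-scale runs on phantom cohorts. The stated batch
# size of 128 targets GPU training of thousands of augmented slices; a
# desk-scale run has ~10^2 slices and a budget of a few hundred steps, so it
# uses small batches and a higher learning rate reached through a linear
# warmup (Adam's early steps swing wide-layer outputs hard; ramping the rate
# avoids saturating the sigmoid head before features exist).
DESK_SCALE_OVERRIDES = dict(batch_size=8, learning_rate=3e-4, warmup_steps=32)


@dataclass
class TrainingConfig:
    learning_rate: float = 1e-4
    batch_size: int = 128
    epochs: int = 10
    l2_coefficient: float = 1e-5
    dropout_rate: float = 0.5
    seed: int = 0
    initializer: str = "he_normal"
    smooth_epsilon: float = 1.0
    threshold: float = 0.5
    early_stopping_patience: int = 10
    val_dice_target: float | None = None  # stop once held-out Dice reaches this
    warmup_steps: int = 0  # linear learning-rate ramp over the first steps

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be at least 1")
        if self.smooth_epsilon <= 0:
            raise ValueError("smooth_epsilon must be positive")
        if self.warmup_steps < 0:
            raise ValueError("warmup_steps must be non-negative")
        if self.initializer != "he_normal":
            raise ValueError(f"only the he_normal initializer is supported, "
                             f"got {self.initializer!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainingResult:
    history: pd.DataFrame          # one row per epoch
    best_epoch: int
    best_val_dice: float
    best_state: dict = field(repr=False)
    config: TrainingConfig = None


# ------------------------------------------------------------------ losses

def soft_dice_loss(true_mask: np.ndarray, predicted_map: np.ndarray,
                   eps: float = 1.0) -> float:
    """Per-image soft Dice loss, in [0, 1]; 0 iff prediction equals the mask."""
    t = np.asarray(true_mask, dtype=np.float64)
    p = np.asarray(predicted_map, dtype=np.float64)
    if t.shape != p.shape:
        raise ShapeError(f"mask {t.shape} vs prediction {p.shape}")
    num = 2.0 * float((t * p).sum()) + eps
    den = float(t.sum()) + float(p.sum()) + eps
    return 1.0 - num / den


def batch_loss(true_masks, predicted_maps, eps: float = 1.0) -> float:
    """Arithmetic mean of per-image soft Dice losses."""
    ts, ps = list(true_masks), list(predicted_maps)
    if len(ts) != len(ps):
        raise ShapeError(f"{len(ts)} masks vs {len(ps)} predictions")
    if not ts:
        raise ValueError("batch_loss of an empty batch is undefined")
    return float(np.mean([soft_dice_loss(t, p, eps) for t, p in zip(ts, ps)]))


def soft_dice_loss_and_grad(t: np.ndarray, p: np.ndarray,
                            eps: float = 1.0) -> tuple[float, np.ndarray]:
    """Batch mean soft-Dice loss and its gradient w.r.t. the predictions.

    ``t``/``p`` are (B, H, W, 1); the per-image sums run over each image.
    """
    if t.shape != p.shape:
        raise ShapeError(f"mask {t.shape} vs prediction {p.shape}")
    B = t.shape[0]
    axes = tuple(range(1, t.ndim))
    tf = t.astype(np.float32)
    inter = (tf * p).sum(axis=axes)
    tsum = tf.sum(axis=axes)
    psum = p.sum(axis=axes)
    num = 2.0 * inter + eps
    den = tsum + psum + eps
    loss = float(np.mean(1.0 - num / den))
    shape = (B,) + (1,) * (t.ndim - 1)
    grad = (num.reshape(shape) / den.reshape(shape) ** 2
            - 2.0 * tf / den.reshape(shape)) / B
    return loss, grad.astype(np.float32)


# ------------------------------------------------------------------- loop

def stack_slices(slices: list[SlicePair]) -> tuple[np.ndarray, np.ndarray]:
    """Stack SlicePairs into (B, H, W, 1) image and mask tensors."""
    x = np.stack([p.image for p in slices])[..., None].astype(np.float32)
    t = np.stack([p.mask for p in slices])[..., None].astype(np.float32)
    return x, t


def _mean_dice(model: Network, x: np.ndarray, t: np.ndarray,
               threshold: float, batch_size: int) -> tuple[float, float]:
    """(mean hard Dice, mean soft-Dice loss) over an evaluation tensor."""
    from .evaluation import dice_coefficient  # local import to avoid a cycle
    probs = model.predict(x, batch_size=batch_size)
    losses, dices = [], []
    for i in range(len(x)):
        losses.append(soft_dice_loss(t[i], probs[i]))
        pred = (probs[i] > threshold).astype(np.uint8)
        dices.append(dice_coefficient(t[i].astype(np.uint8), pred))
    return float(np.mean(dices)), float(np.mean(losses))


def train(model: Network, train_slices: list[SlicePair],
          val_slices: list[SlicePair], config: TrainingConfig) -> TrainingResult:
    """Fit ``model`` on the prepared slices; returns per-epoch history and
    leaves the best-validation-Dice weights loaded in the model.

    Deterministic given ``config.seed`` (shuffling and dropout both derive
    from it). Raises :class:`TrainingError` if the loss goes non-finite.
    """
    if not train_slices:
        raise ValueError("no training slices")
    x_tr, t_tr = stack_slices(train_slices)
    has_val = bool(val_slices)
    if has_val:
        x_va, t_va = stack_slices(val_slices)
    rng = np.random.default_rng(config.seed)
    model.rng = np.random.default_rng(rng.integers(2 ** 31))  # dropout stream
    opt = Adam(model.params(), lr=config.learning_rate,
               l2=config.l2_coefficient, l2_param_names=model.conv_kernel_names())

    rows = []
    best = {"epoch": -1, "dice": -1.0, "state": model.state_dict()}
    since_best = 0
    n = len(x_tr)
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            if config.warmup_steps:
                opt.lr = config.learning_rate * min(1.0, (opt.t + 1) / config.warmup_steps)
            idx = perm[start:start + config.batch_size]
            xb, tb = x_tr[idx], t_tr[idx]
            probs = model.forward(xb, training=True)
            loss, dprobs = soft_dice_loss_and_grad(tb, probs, config.smooth_epsilon)
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}, step {start // config.batch_size}: "
                    f"loss={loss}, |probs| in [{np.abs(probs).min()}, {np.abs(probs).max()}]")
            opt.zero_grad()
            model.backward(dprobs)
            opt.step()
            losses.append(loss + opt.penalty())
        row = {"epoch": epoch, "train_loss": float(np.mean(losses)),
               "val_loss": np.nan, "val_dice": np.nan}
        if has_val:
            val_dice, val_loss = _mean_dice(model, x_va, t_va,
                                            config.threshold, config.batch_size)
            row["val_loss"], row["val_dice"] = val_loss, val_dice
            if val_dice > best["dice"]:
                best = {"epoch": epoch, "dice": val_dice, "state": model.state_dict()}
                since_best = 0
            else:
                since_best += 1
        rows.append(row)
        if has_val and config.val_dice_target is not None \
                and row["val_dice"] >= config.val_dice_target:
            break
        if has_val and since_best > config.early_stopping_patience:
            break

    if has_val and best["epoch"] >= 0:
        model.load_state_dict(best["state"])
    else:
        best = {"epoch": len(rows) - 1, "dice": float("nan"), "state": model.state_dict()}
    history = pd.DataFrame(rows)
    return TrainingResult(history=history, best_epoch=best["epoch"],
                          best_val_dice=best["dice"], best_state=best["state"],
                          config=config)


# ------------------------------------------------------------- checkpoints

def save_checkpoint(model: Network, path) -> Path:
    """Weights as .npz plus a JSON sidecar describing how to rebuild."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    model.save(path)
    if isinstance(model, CNNRes):
        meta = {"arch": "cnnres", "convention": model.convention.to_dict(),
                "input_size": model.input_size, "in_channels": model.in_channels,
                "levels": model.levels, "base_filters": model.base_filters}
    elif isinstance(model, UNet):
        meta = {"arch": "unet", "input_size": model.input_size}
    else:
        raise TypeError(f"cannot describe model of type {type(model).__name__}")
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def load_checkpoint(path) -> Network:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    if meta["arch"] == "cnnres":
        model = CNNRes(BlockConvention.from_dict(meta["convention"]),
                       input_size=meta["input_size"], in_channels=meta["in_channels"],
                       levels=meta["levels"], base_filters=meta["base_filters"])
    elif meta["arch"] == "unet":
        model = UNet(meta["input_size"])
    else:
        raise ValueError(f"unknown architecture {meta['arch']!r}")
    model.load(path)
    return model
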