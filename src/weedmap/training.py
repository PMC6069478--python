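"""Training loop, optimizers and checkpoint/transfer interface.

Training minimizes mean per-pixel cross-entropy.  By default the loss is
computed at full resolution — the coarse score map is bilinearly upsampled to
the tile size and compared against the ground truth, matching the inference
path — with an optional faster mode that downsamples the ground truth to the
score grid instead (nearest pixel).

Checkpoints are flat name -> array mappings saved as ``.npz``;
:func:`load_weights` copies matching tensors and reports what it skipped,
which is the warm-start (transfer) interface: a backbone trained on one
distribution can initialize a model with a fresh head.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dfcn import SegmentationModel
from .nn import functional as F


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes NaN/inf."""


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 4
    learning_rate: float = 1e-3
    optimizer: str = "sgd_momentum"  # or "adam"
    momentum: float = 0.9
    seed: int = 0
    loss_resolution: str = "full"  # or "score"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer not in ("sgd_momentum", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.loss_resolution not in ("full", "score"):
            raise ValueError(f"unknown loss_resolution {self.loss_resolution!r}")


class _SGDMomentum:
    def __init__(self, lr: float, momentum: float) -> None:
        self.lr, self.mu = lr, momentum
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict, grads: dict) -> dict:
        out = {}
        for name, p in params.items():
            v = self.v.get(name, np.zeros_like(p))
            v = self.mu * v - self.lr * grads[name]
            self.v[name] = v
            out[name] = p + v
        return out


class _Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict, grads: dict) -> dict:
        self.t += 1
        out = {}
        for name, p in params.items():
            g = grads[name]
            m = self.b1 * self.m.get(name, np.zeros_like(p)) + (1 - self.b1) * g
            v = self.b2 * self.v.get(name, np.zeros_like(p)) + (1 - self.b2) * g * g
            self.m[name], self.v[name] = m, v
            mh = m / (1 - self.b1**self.t)
            vh = v / (1 - self.b2**self.t)
            out[name] = p - self.lr * mh / (np.sqrt(vh) + self.eps)
        return out


def _make_optimizer(config: TrainConfig):
    if config.optimizer == "adam":
        return _Adam(config.learning_rate)
    return _SGDMomentum(config.learning_rate, config.momentum)


def _as_batch(samples) -> tuple[np.ndarray, np.ndarray]:
    """Stack SceneSamples or (image, gt) pairs into NCHW floats + labels."""
    xs, ys = [], []
    for s in samples:
        image, gt = (s.image, s.gt) if hasattr(s, "image") else s
        x = image.astype(np.float64)
        if image.dtype == np.uint8:
            x /= 255.0
        xs.append(x.transpose(2, 0, 1))
        ys.append(np.asarray(gt, dtype=np.int64))
    return np.stack(xs), np.stack(ys)


def _downsample_labels(labels: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Nearest-pixel label downsampling to the score grid."""
    ri = ((np.arange(out_h) + 0.5) * labels.shape[1] / out_h - 0.5).round().astype(int)
    ci = ((np.arange(out_w) + 0.5) * labels.shape[2] / out_w - 0.5).round().astype(int)
    ri = np.clip(ri, 0, labels.shape[1] - 1)
    ci = np.clip(ci, 0, labels.shape[2] - 1)
    return labels[:, ri[:, None], ci[None, :]]


@dataclass
class TrainResult:
    checkpoint: dict
    loss_trace: list  # mean loss per epoch


def train(model: SegmentationModel, dataset, config: TrainConfig) -> TrainResult:
    """Fine-tune ``model`` on SceneSamples/tiles; deterministic given the seed.

    Returns the final weights and the per-epoch mean loss.  Raises
    :class:`TrainingDivergedError` on NaN/inf loss.
    """
    samples = list(dataset)
    if not samples:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(config.seed)
    opt = _make_optimizer(config)
    trace: list[float] = []
    n = len(samples)
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            batch = [samples[i] for i in order[start : start + config.batch_size]]
            x, labels = _as_batch(batch)
            model.zero_grad()
            try:
                scores = model.forward(x)
                if config.loss_resolution == "full" and scores.shape[2:] != labels.shape[1:]:
                    up, up_cache = F.bilinear_upsample_forward(scores, labels.shape[1], labels.shape[2])
                    loss, dlogits = F.cross_entropy_forward(up, labels)
                    dscores = F.bilinear_upsample_backward(dlogits, up_cache)
                else:
                    tgt = labels
                    if scores.shape[2:] != labels.shape[1:]:
                        tgt = _downsample_labels(labels, scores.shape[2], scores.shape[3])
                    loss, dscores = F.cross_entropy_forward(scores, tgt)
            except (ValueError, FloatingPointError) as err:
                raise TrainingDivergedError(
                    f"loss diverged at epoch {_epoch} ({err}); lower the learning rate"
                ) from err
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"loss diverged at epoch {_epoch}: {loss!r}; lower the learning rate"
                )
            model.backward(dscores)
            new = opt.step(model.named_parameters(), model.named_grads())
            for name, value in new.items():
                model.set_parameter(name, value)
            epoch_losses.append(loss)
        trace.append(float(np.mean(epoch_losses)))
    return TrainResult(checkpoint=model.named_parameters(), loss_trace=trace)


# ---------------------------------------------------------------------------
# checkpoints and transfer
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, params: dict) -> None:
    np.savez(str(path), **params)


def load_checkpoint(path: str | Path) -> dict:
    with np.load(str(path)) as data:
        return {k: data[k].copy() for k in data.files}


def load_weights(model: SegmentationModel, checkpoint: dict, strict: bool = True) -> dict:
    """Copy matching tensors from a checkpoint into a model.

    Returns a report ``{"loaded": [...], "skipped": [...], "missing": [...]}``
    where ``skipped`` lists checkpoint entries that do not match the model
    (unknown name or wrong shape — e.g. a classification head with a
    different class count) and ``missing`` lists model parameters the
    checkpoint did not provide.  Under ``strict=True`` any mismatch raises,
    naming the offending layers.
    """
    params = model.named_parameters()
    loaded, skipped = [], []
    for name, value in checkpoint.items():
        if name in params and params[name].shape == value.shape:
            model.set_parameter(name, value)
            loaded.append(name)
        else:
            skipped.append(name)
    missing = [n for n in params if n not in checkpoint]
    if strict and (skipped or missing):
        raise ValueError(f"checkpoint mismatch: skipped={skipped}, missing={missing}")
    return {"loaded": loaded, "skipped": skipped, "missing": missing}
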