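"""Training utilities: Adam, the training loop, deep-feature extraction
and single-file checkpoints.

Defaults follow the published configuration: Adam at learning rate 1e-4,
at most 150 epochs, cross-entropy loss, and weights initialized from
N(0, 0.01) (standard deviation 0.1) with zero biases.  Early stopping
(patience on the monitored loss) bounds desk-scale runs; the epoch cap is
the hard limit.  Runs are bit-reproducible for a fixed seed: data order,
init and all arithmetic are driven by numpy with no threading.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import asdict, dataclass

import numpy as np

from .autograd import Tensor, softmax_cross_entropy
from .blocks import FusionNet, FusionNetConfig
from .layers import Module, init_normal

__all__ = ["TrainConfig", "Adam", "train", "extract_deep_features",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4
    max_epochs: int = 150
    batch_size: int = 16
    init_std: float = 0.1  # variance 0.01
    patience: int = 15
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


class Adam:
    """Adaptive-moment estimation with the standard bias correction."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


def _epoch_batches(n, batch_size, rng):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def train(model: FusionNet, images: np.ndarray, labels: np.ndarray,
          cfg: TrainConfig | None = None,
          val_images: np.ndarray | None = None,
          val_labels: np.ndarray | None = None,
          initialize: bool = True) -> dict:
    """Train in place; returns a history dict with per-epoch loss/accuracy.

    ``images``: (N, C, H, W); ``labels``: (N,) in {0, 1}.  Early stopping
    monitors the validation loss when a validation set is given, else the
    training loss, with ``cfg.patience``; the best-epoch weights are
    restored at the end.
    """
    cfg = cfg or TrainConfig()
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("training set must contain both classes")
    rng = np.random.default_rng(cfg.seed)
    if initialize:
        init_normal(model, rng, std=cfg.init_std)
    opt = Adam(model.parameters(), lr=cfg.lr)
    history = {"loss": [], "accuracy": [], "val_loss": []}
    best = (np.inf, None, -1)  # (monitored loss, state, epoch)
    for epoch in range(cfg.max_epochs):
        model.train()
        losses, correct = [], 0
        for idx in _epoch_batches(len(labels), cfg.batch_size, rng):
            xb, yb = images[idx], labels[idx]
            logits, _ = model(Tensor(xb))
            loss = softmax_cross_entropy(logits, yb)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data) * len(idx))
            correct += int((logits.data.argmax(axis=1) == yb).sum())
        epoch_loss = sum(losses) / len(labels)
        history["loss"].append(epoch_loss)
        history["accuracy"].append(correct / len(labels))
        monitored = epoch_loss
        if val_images is not None:
            val_loss = _eval_loss(model, val_images, val_labels, cfg.batch_size)
            history["val_loss"].append(val_loss)
            monitored = val_loss
        if monitored < best[0] - 1e-12:
            best = (monitored, model.state_dict(), epoch)
        elif epoch - best[2] >= cfg.patience:
            break
    if best[1] is not None:
        model.load_state_dict(best[1])
    history["best_epoch"] = best[2]
    model.trained_ = True
    model.eval()
    return history


def _eval_loss(model: Module, images, labels, batch_size) -> float:
    model.eval()
    total = 0.0
    for i in range(0, len(labels), batch_size):
        logits, _ = model(Tensor(images[i : i + batch_size]))
        loss = softmax_cross_entropy(logits, labels[i : i + batch_size])
        total += float(loss.data) * len(labels[i : i + batch_size])
    return total / len(labels)


def extract_deep_features(model: FusionNet, images: np.ndarray,
                          batch_size: int = 16,
                          warn_untrained: bool = True) -> np.ndarray:
    """Penultimate-FC activations per sample, eval mode (running BN stats,
    no updates); shape (N, fc_dim)."""
    import warnings

    if warn_untrained and not getattr(model, "trained_", False):
        warnings.warn("extracting features from an untrained model", stacklevel=2)
    was_training = model.training
    model.eval()
    feats = []
    for i in range(0, len(images), batch_size):
        _, f = model(Tensor(images[i : i + batch_size]))
        feats.append(f.data)
    if was_training:
        model.train()
    return np.vstack(feats)


def save_checkpoint(model: FusionNet, path: str) -> None:
    """Single-file archive: npz weights + architecture config JSON."""
    state = model.state_dict()
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("config.json", json.dumps(asdict(model.config)))
        import io

        buf = io.BytesIO()
        np.savez(buf, **state)
        zf.writestr("weights.npz", buf.getvalue())


def load_checkpoint(path: str) -> FusionNet:
    import io

    with zipfile.ZipFile(path) as zf:
        raw = json.loads(zf.read("config.json"))
        for key in ("stage_blocks", "stage_channels"):
            raw[key] = tuple(raw[key])
        model = FusionNet(FusionNetConfig(**raw))
        with np.load(io.BytesIO(zf.read("weights.npz"))) as npz:
            model.load_state_dict({k: npz[k] for k in npz.files})
    model.eval()
    return model
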