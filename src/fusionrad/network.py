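"""scikit-learn style estimator facade over the FusionNet CNN.

``FusionNetClassifier`` fits the Seq-ResNet fusion network on channel-first
image arrays (or sample objects carrying ``.image``) and exposes

* ``predict`` / ``predict_proba`` — the classification head,
* ``transform`` — the penultimate deep feature vectors (``fc_dim`` wide),

so it drops into sklearn pipelines and model selection, and pairs with
:class:`fusionrad.radiomics.RadiomicsExtractor` for feature fusion.
"""

from __future__ import annotations

import numpy as np

from .nn import (FusionNet, FusionNetConfig, TrainConfig,
                 extract_deep_features, train)

__all__ = ["FusionNetClassifier"]


def _to_array(X) -> np.ndarray:
    if isinstance(X, np.ndarray):
        arr = X
    else:
        arr = np.stack([np.asarray(getattr(s, "image", s)) for s in X])
    if arr.ndim != 4:
        raise ValueError(f"expected (N, C, H, W) input, got shape {arr.shape}")
    return arr.astype(np.float64)


class FusionNetClassifier:
    """Binary CNN classifier with deep-feature extraction.

    Parameters mirror the architecture plan (stage blocks/widths, fc_dim,
    depth_scale) and training configuration (Adam lr 1e-4, epoch cap,
    N(0, 0.01) init).  The fitted model lives in ``model_`` and the
    training history in ``history_``.
    """

    def __init__(self, stage_blocks=(6, 8, 12, 8, 3),
                 stage_channels=(32, 64, 96, 96, 64), fc_dim=256,
                 depth_scale=1.0, lr=1e-4, max_epochs=150, batch_size=16,
                 patience=15, seed=0):
        self.stage_blocks = stage_blocks
        self.stage_channels = stage_channels
        self.fc_dim = fc_dim
        self.depth_scale = depth_scale
        self.lr = lr
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.patience = patience
        self.seed = seed

    # -- sklearn protocol ---------------------------------------------------
    _param_names = ("stage_blocks", "stage_channels", "fc_dim", "depth_scale",
                    "lr", "max_epochs", "batch_size", "patience", "seed")

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- fitting ------------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        images = _to_array(X)
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("FusionNetClassifier is a binary classifier")
        cfg = FusionNetConfig(
            in_channels=images.shape[1],
            stage_blocks=tuple(self.stage_blocks),
            stage_channels=tuple(self.stage_channels),
            fc_dim=self.fc_dim,
            depth_scale=self.depth_scale,
        )
        self.model_ = FusionNet(cfg)
        tcfg = TrainConfig(lr=self.lr, max_epochs=self.max_epochs,
                           batch_size=self.batch_size, patience=self.patience,
                           seed=self.seed)
        self.history_ = train(
            self.model_, images, y, tcfg,
            val_images=None if X_val is None else _to_array(X_val),
            val_labels=None if y_val is None else np.asarray(y_val, dtype=int),
        )
        self.n_features_in_ = int(np.prod(images.shape[1:]))
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("FusionNetClassifier is not fitted")

    def decision_scores(self, X) -> np.ndarray:
        """Logit difference (malignant minus benign) per sample."""
        self._check_fitted()
        images = _to_array(X)
        self.model_.eval()
        out = []
        for i in range(0, len(images), self.batch_size):
            logits, _ = self.model_(images[i : i + self.batch_size])
            out.append(logits.data[:, 1] - logits.data[:, 0])
        return np.concatenate(out)

    def predict_proba(self, X) -> np.ndarray:
        s = self.decision_scores(X)
        p1 = 1.0 / (1.0 + np.exp(-s))
        return np.column_stack([1 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.decision_scores(X) > 0).astype(int)

    def transform(self, X) -> np.ndarray:
        """Deep feature vectors (N, fc_dim) from the penultimate FC layer."""
        self._check_fitted()
        return extract_deep_features(self.model_, _to_array(X),
                                     batch_size=self.batch_size)

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y, dtype=int)))
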