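"""scikit-learn style front end for the attention U-Net."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import metrics as M
from .nn.model import AttentionUNet, NetworkCfg
from .phantom import PhantomPair, PhantomSpec
from .postprocess import PostprocessCfg, postprocess_probs
from .training import TrainCfg, train


class AttentionUNetSegmenter(BaseEstimator):
    """Binary image segmenter: spatial-attention U-Net + BCE training.

    Parameters
    ----------
    base_width, width_multiplier : network capacity; the product (rounded)
        is the first block's channel count, all other widths scale with it.
    epochs, batch_size, lr, optimizer : training loop settings.
    threshold : probability cut for ``predict``.
    min_component_size : components smaller than this (pixels, at the
        input resolution) are dropped in ``predict``; 0 disables cleaning.
    random_state : seeds both weight init and batch shuffling.

    Fitted attributes: ``model_`` (the network), ``history_`` (per-epoch
    loss table), ``in_channels_``, ``image_shape_``.
    """

    def __init__(
        self,
        base_width: int = 16,
        width_multiplier: float = 0.25,
        out_channels: int = 1,
        epochs: int = 20,
        batch_size: int = 8,
        lr: float = 1e-3,
        optimizer: str = "adam",
        threshold: float = 0.5,
        min_component_size: int = 0,
        connectivity: int = 8,
        residual: bool = False,
        random_state: int = 0,
    ):
        self.base_width = base_width
        self.width_multiplier = width_multiplier
        self.out_channels = out_channels
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.optimizer = optimizer
        self.threshold = threshold
        self.min_component_size = min_component_size
        self.connectivity = connectivity
        self.residual = residual
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def _coerce_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 3:  # (n, H, W) grayscale
            X = X[:, None]
        elif X.ndim == 4:  # (n, H, W, C) channels-last
            X = X.transpose(0, 3, 1, 2)
        else:
            raise ValueError("X must be (n, H, W) or (n, H, W, C)")
        return X

    def fit(self, X: np.ndarray, y: np.ndarray) -> "AttentionUNetSegmenter":
        """Train on images X (n,H,W) or (n,H,W,C) and binary masks y (n,H,W)."""
        X = self._coerce_X(X)
        y = np.asarray(y)
        if y.shape != (X.shape[0], X.shape[2], X.shape[3]):
            raise ValueError("y must be (n, H, W) masks aligned with X")
        if not np.all(np.isin(np.unique(y), (0, 1))):
            raise ValueError("y must be binary")
        self.in_channels_ = X.shape[1]
        self.image_shape_ = X.shape[2:]
        self.model_ = AttentionUNet(
            NetworkCfg(
                in_channels=self.in_channels_,
                out_channels=self.out_channels,
                base_width=self.base_width,
                width_multiplier=self.width_multiplier,
                residual=self.residual,
                seed=self.random_state,
            )
        )
        # wrap as pairs so the training loop (and its access logging) is reused
        spec = PhantomSpec(
            image_size=max(X.shape[2], 4), n_lesions=0,
            lesion_radius_range=(1, 1), noise_sd=0.0,
        )
        pairs = [
            PhantomPair(
                image=np.moveaxis(X[i], 0, -1) if self.in_channels_ > 1 else X[i, 0],
                mask=y[i].astype(np.uint8),
                patient_id=f"sample_{i}",
                spec=spec,
            )
            for i in range(X.shape[0])
        ]
        cfg = TrainCfg(
            epochs=self.epochs,
            batch_size=self.batch_size,
            optimizer=self.optimizer,
            lr=self.lr,
            seed=self.random_state,
        )
        self.history_, state = train(self.model_, pairs, cfg=cfg)
        self.model_.load_state_dict(state)
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit first")

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Per-pixel foreground probabilities, shape (n, H, W)."""
        self._check_fitted()
        X = self._coerce_X(X)
        out = np.empty((X.shape[0],) + X.shape[2:])
        for i in range(X.shape[0]):
            out[i] = self.model_.predict_proba(X[i][None])[0, 0]
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Binary masks after thresholding and component cleaning."""
        probs = self.predict_proba(X)
        cfg = PostprocessCfg(
            threshold=self.threshold,
            connectivity=self.connectivity,
            min_size=self.min_component_size,
            reference_size=probs.shape[1],
        )
        return np.stack([postprocess_probs(p, cfg) for p in probs])

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        """Mean Dice similarity coefficient over the given images."""
        y = np.asarray(y)
        preds = self.predict(X)
        return float(np.mean([M.dsc(p, t) for p, t in zip(preds, y)]))
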