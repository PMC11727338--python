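"""BCE loss, patient-wise splitting, and the seeded training/validation loop.

The loop is fully deterministic given (model seed, TrainCfg.seed): batch
order comes from a dedicated generator, and the engine is single-threaded
NumPy.  Validation metrics are computed each epoch on the held-out fold and
the best checkpoint is selected by validation DSC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import metrics as M
from .nn import autodiff as ad
from .nn.model import AttentionUNet
from .nn.optim import Adam, SGD
from .phantom import PhantomPair
from .postprocess import PostprocessCfg, postprocess_probs

BCE_EPS = 1e-7


def bce_loss(y_true: np.ndarray, y_pred: np.ndarray, eps: float = BCE_EPS) -> float:
    """Mean binary cross-entropy; predictions clipped to [eps, 1-eps]."""
    t = np.asarray(y_true, dtype=np.float64)
    p = np.asarray(y_pred, dtype=np.float64)
    if t.shape != p.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {p.shape}")
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(t * np.log(p) + (1.0 - t) * np.log1p(-p)))


def patient_split(
    patient_ids: Iterable[str], train_fraction: float = 0.8, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Disjoint train/test partition at patient granularity.

    The train side gets round(fraction * n_patients) patients, clamped so
    both sides are nonempty.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    unique = sorted(set(patient_ids))
    n = len(unique)
    if n < 2:
        raise ValueError("patient-wise split requires >= 2 patients")
    n_train = int(np.clip(round(train_fraction * n), 1, n - 1))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train = sorted(unique[i] for i in order[:n_train])
    test = sorted(unique[i] for i in order[n_train:])
    return train, test


@dataclass
class TrainCfg:
    epochs: int = 200
    batch_size: int = 8
    optimizer: str = "adam"
    lr: float = 1e-4
    train_fraction: float = 0.8
    seed: int = 0
    bce_eps: float = BCE_EPS

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")


class LoggedDataset:
    """Pair container that records which patients' images were read.

    ``access_log`` lets tests assert that training never touched a held-out
    patient.
    """

    def __init__(self, pairs: Sequence[PhantomPair]):
        self.pairs = list(pairs)
        self.access_log: list[str] = []

    def __len__(self) -> int:
        return len(self.pairs)

    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.pairs]

    def indices_for(self, patients: Iterable[str]) -> list[int]:
        wanted = set(patients)
        return [i for i, p in enumerate(self.pairs) if p.patient_id in wanted]

    def fetch(self, index: int) -> PhantomPair:
        pair = self.pairs[index]
        self.access_log.append(pair.patient_id)
        return pair


def _to_input(image: np.ndarray, in_channels: int) -> np.ndarray:
    """(H,W) or (H,W,C) image -> (C,H,W), replicating grayscale if needed."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        img = img[None]
    elif img.ndim == 3:
        img = img.transpose(2, 0, 1)
    else:
        raise ValueError("image must be (H,W) or (H,W,C)")
    if img.shape[0] == in_channels:
        return img
    if img.shape[0] == 1:
        return np.repeat(img, in_channels, axis=0)
    raise ValueError(f"cannot map {img.shape[0]}-channel image to {in_channels} channels")


def pairs_to_arrays(
    pairs: Sequence[PhantomPair], in_channels: int
) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([_to_input(p.image, in_channels) for p in pairs])
    y = np.stack([p.mask.astype(np.float64)[None] for p in pairs])
    return x, y


def _mean_val_dsc(
    model: AttentionUNet, dataset: LoggedDataset, indices: list[int], threshold: float
) -> float:
    scores = []
    for i in indices:
        pair = dataset.pairs[i]  # validation reads bypass the training access log
        x = _to_input(pair.image, model.cfg.in_channels)[None]
        probs = model.predict_proba(x)[0, 0]
        scores.append(M.dsc((probs >= threshold).astype(np.uint8), pair.mask))
    return float(np.mean(scores))


def train(
    model: AttentionUNet,
    dataset: LoggedDataset | Sequence[PhantomPair],
    train_patients: Iterable[str] | None = None,
    cfg: TrainCfg | None = None,
    val_patients: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Run the BCE training loop; returns (history, best weight state).

    ``train_patients`` restricts the loop to those patients' slices (all
    slices when None).  If ``val_patients`` is given, held-out mean DSC is
    computed each epoch and the returned state is the best-DSC checkpoint;
    otherwise the final weights are returned.
    """
    cfg = cfg or TrainCfg()
    if not isinstance(dataset, LoggedDataset):
        dataset = LoggedDataset(dataset)
    if train_patients is None:
        train_idx = list(range(len(dataset)))
    else:
        train_idx = dataset.indices_for(train_patients)
    if not train_idx:
        raise ValueError("no training images selected")
    val_idx = dataset.indices_for(val_patients) if val_patients is not None else []

    opt_cls = Adam if cfg.optimizer == "adam" else SGD
    opt = opt_cls(model.parameters(), lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    history: list[dict] = []
    best_dsc = -1.0
    best_state = model.state_dict()

    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(train_idx))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = [train_idx[j] for j in order[start : start + cfg.batch_size]]
            pairs = [dataset.fetch(i) for i in batch]
            x, y = pairs_to_arrays(pairs, model.cfg.in_channels)
            probs = model.forward(x)
            loss = ad.bce(probs, y, eps=cfg.bce_eps)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss.data!r}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        row = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if val_idx:
            val_dsc = _mean_val_dsc(model, dataset, val_idx, threshold=0.5)
            row["val_dsc"] = val_dsc
            if val_dsc > best_dsc:
                best_dsc = val_dsc
                best_state = model.state_dict()
        history.append(row)

    if not val_idx:
        best_state = model.state_dict()
    return pd.DataFrame(history), best_state


def evaluate_run(
    model: AttentionUNet,
    dataset: LoggedDataset | Sequence[PhantomPair],
    patients: Iterable[str] | None = None,
    post_cfg: PostprocessCfg | None = None,
) -> dict:
    """Forward + postprocess + metrics per image, then averages.

    Returns ``{"per_image": DataFrame, "summary": dict, "n_hd95_excluded": int}``;
    images where HD95 is undefined (an empty mask) are excluded from its mean.
    """
    if not isinstance(dataset, LoggedDataset):
        dataset = LoggedDataset(dataset)
    idx = (
        dataset.indices_for(patients) if patients is not None else list(range(len(dataset)))
    )
    if not idx:
        raise ValueError("no images selected for evaluation")
    post_cfg = post_cfg or PostprocessCfg()
    rows = []
    for i in idx:
        pair = dataset.pairs[i]
        x = _to_input(pair.image, model.cfg.in_channels)[None]
        probs = model.predict_proba(x)[0, 0]
        pred = postprocess_probs(probs, post_cfg)
        row = M.evaluate_masks(pred, pair.mask, probs=probs)
        row["patient_id"] = pair.patient_id
        rows.append(row)
    per_image = pd.DataFrame(rows)
    numeric = per_image.drop(columns="patient_id")
    summary = {k: float(v) for k, v in numeric.mean(skipna=True).items()}
    return {
        "per_image": per_image,
        "summary": summary,
        "n_hd95_excluded": int(per_image["hd95"].isna().sum()),
    }
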