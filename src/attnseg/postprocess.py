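"""Probability-map to final-mask conversion: thresholding, connected-component
labeling, and small-component removal."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class ComponentLabeling:
    labels: np.ndarray  # int raster, 0 = background, 1..k components
    sizes: np.ndarray  # pixel count per component, index i -> label i+1

    @property
    def n_components(self) -> int:
        return len(self.sizes)


@dataclass
class PostprocessCfg:
    threshold: float = 0.5
    connectivity: int = 8
    min_size: int = 10  # pixels at the 512x512 reference resolution
    reference_size: int = 512
    mode: str = "filter"  # or "largest"

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.min_size < 0:
            raise ValueError("min_size must be >= 0")
        if self.mode not in ("filter", "largest"):
            raise ValueError("mode must be 'filter' or 'largest'")


def binarize(probs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Pixel = 1 iff probability >= threshold (boundary counts as foreground)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return (np.asarray(probs, dtype=np.float64) >= threshold).astype(np.uint8)


def label_components(mask: np.ndarray, connectivity: int = 8) -> ComponentLabeling:
    """Label maximal connected foreground groups (labels contiguous 1..k)."""
    mask = np.asarray(mask)
    if not np.all(np.isin(np.unique(mask), (0, 1))):
        raise ValueError("mask must be binary")
    if connectivity == 4:
        structure = ndimage.generate_binary_structure(2, 1)
    elif connectivity == 8:
        structure = ndimage.generate_binary_structure(2, 2)
    else:
        raise ValueError("connectivity must be 4 or 8")
    labels, k = ndimage.label(mask, structure=structure)
    sizes = np.bincount(labels.ravel(), minlength=k + 1)[1:]
    return ComponentLabeling(labels=labels, sizes=sizes)


def filter_small(labeling: ComponentLabeling, min_size: int) -> np.ndarray:
    """Remove components smaller than min_size pixels; keep the rest intact."""
    if min_size < 0:
        raise ValueError("min_size must be >= 0")
    if labeling.n_components == 0:
        return np.zeros_like(labeling.labels, dtype=np.uint8)
    keep = np.r_[False, labeling.sizes >= min_size]  # index by label
    return keep[labeling.labels].astype(np.uint8)


def largest_component(labeling: ComponentLabeling) -> np.ndarray:
    """Keep only the largest component (ties broken by lowest label)."""
    if labeling.n_components == 0:
        return np.zeros_like(labeling.labels, dtype=np.uint8)
    best = int(np.argmax(labeling.sizes)) + 1
    return (labeling.labels == best).astype(np.uint8)


def scaled_min_size(shape: tuple[int, int], base: int = 10, reference: int = 512) -> int:
    """Scale the reference min component size by image area."""
    area_ratio = (shape[0] * shape[1]) / (reference * reference)
    return int(round(base * area_ratio))


def postprocess_probs(probs: np.ndarray, cfg: PostprocessCfg | None = None) -> np.ndarray:
    """Threshold, label, and clean a probability map into a final mask."""
    cfg = cfg or PostprocessCfg()
    mask = binarize(probs, cfg.threshold)
    labeling = label_components(mask, cfg.connectivity)
    if cfg.mode == "largest":
        return largest_component(labeling)
    min_size = scaled_min_size(mask.shape, cfg.min_size, cfg.reference_size)
    return filter_small(labeling, min_size)
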