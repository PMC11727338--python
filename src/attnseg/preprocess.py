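"""Image/mask preprocessing: normalization, resizing, histogram equalization,
denoising, and paired geometric augmentation.

Every operation that touches a mask uses nearest-neighbour interpolation so
masks stay strictly binary; images use bilinear interpolation.  The pipeline
stage order is fixed: normalize -> resize -> equalize -> denoise, with
augmentation (rotation, translation, flips) applied jointly to image and
mask in training mode only.  Out-of-bounds pixels created by rotation or
translation are filled with background (0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import exposure, transform
from skimage.filters import gaussian

NORMALIZE_MODES = ("minmax", "zscore")
EQUALIZE_MODES = ("global", "adaptive", "off")
DENOISE_MODES = ("gaussian", "median", "off")


@dataclass
class AugmentCfg:
    rotate: float = 15.0  # max |angle| in degrees
    translate: float = 0.05  # max |shift| as fraction of image size
    flip_horizontal: bool = True
    flip_vertical: bool = True

    def __post_init__(self):
        if not 0 <= self.rotate <= 180:
            raise ValueError("rotation range must lie within [0, 180] degrees")
        if not 0 <= self.translate < 1:
            raise ValueError("translation fraction must lie in [0, 1)")


@dataclass
class PreprocessCfg:
    target_size: int = 512
    normalize: str = "minmax"
    equalize: str = "global"
    denoise: str = "gaussian"
    denoise_strength: float = 0.5  # sigma in px (gaussian) / window radius (median)
    augment: AugmentCfg = field(default_factory=AugmentCfg)
    seed: int = 0

    def __post_init__(self):
        if self.target_size <= 0:
            raise ValueError("target_size must be positive")
        if self.normalize not in NORMALIZE_MODES:
            raise ValueError(f"normalize must be one of {NORMALIZE_MODES}")
        if self.equalize not in EQUALIZE_MODES:
            raise ValueError(f"equalize must be one of {EQUALIZE_MODES}")
        if self.denoise not in DENOISE_MODES:
            raise ValueError(f"denoise must be one of {DENOISE_MODES}")
        if isinstance(self.augment, dict):
            self.augment = AugmentCfg(**self.augment)


def _check_binary(mask: np.ndarray) -> np.ndarray:
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("mask is not binary")
    return mask


def normalize_intensity(img: np.ndarray, mode: str = "minmax") -> np.ndarray:
    """Rescale intensities; constant images map to all zeros."""
    if mode not in NORMALIZE_MODES:
        raise ValueError(f"normalize mode must be one of {NORMALIZE_MODES}")
    img = np.asarray(img, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros_like(img)
    if mode == "minmax":
        return (img - lo) / (hi - lo)
    if mode == "zscore":
        return (img - img.mean()) / img.std()
    raise ValueError(f"normalize mode must be one of {NORMALIZE_MODES}")


def resize_pair(
    img: np.ndarray, mask: np.ndarray, target_size: int
) -> tuple[np.ndarray, np.ndarray]:
    """Resize both to target_size x target_size; bilinear image, nearest mask."""
    if img.shape != mask.shape:
        raise ValueError(f"image shape {img.shape} != mask shape {mask.shape}")
    _check_binary(mask)
    if img.shape == (target_size, target_size):
        return img.copy(), mask.copy()
    out_shape = (target_size, target_size)
    img_r = transform.resize(
        img.astype(np.float64), out_shape, order=1, anti_aliasing=img.shape[0] > target_size,
        preserve_range=True, mode="reflect",
    )
    mask_r = transform.resize(
        mask.astype(np.float64), out_shape, order=0, anti_aliasing=False,
        preserve_range=True, mode="constant",
    )
    return img_r, _check_binary(mask_r.round().astype(np.uint8))


def equalize_histogram(img: np.ndarray, mode: str = "global") -> np.ndarray:
    """Histogram equalization on a [0,1] image; output stays in [0,1]."""
    img = np.asarray(img, dtype=np.float64)
    if mode == "off":
        return img.copy()
    if img.max() == img.min():
        return img.copy()
    if mode == "global":
        return exposure.equalize_hist(img)
    if mode == "adaptive":
        return exposure.equalize_adapthist(np.clip(img, 0, 1))
    raise ValueError(f"equalize mode must be one of {EQUALIZE_MODES}")


def denoise(img: np.ndarray, mode: str = "gaussian", strength: float = 0.5) -> np.ndarray:
    if mode == "off" or strength <= 0:
        return np.asarray(img, dtype=np.float64).copy()
    if mode == "gaussian":
        return gaussian(img, sigma=strength, preserve_range=True)
    if mode == "median":
        size = 2 * int(round(strength)) + 1
        return ndimage.median_filter(np.asarray(img, dtype=np.float64), size=size)
    raise ValueError(f"denoise mode must be one of {DENOISE_MODES}")


# ------------------------------------------------------ paired augmentation

def flip_pair(img, mask, horizontal: bool = True):
    axis = 1 if horizontal else 0
    return np.flip(img, axis=axis).copy(), np.flip(mask, axis=axis).copy()


def rotate_pair(img, mask, angle_deg: float):
    """Rotate both about the image center; zero fill outside the frame."""
    if angle_deg == 0:
        return np.asarray(img).copy(), np.asarray(mask).copy()
    img_r = ndimage.rotate(img, angle_deg, reshape=False, order=1, mode="constant", cval=0.0)
    mask_r = ndimage.rotate(
        mask.astype(np.uint8), angle_deg, reshape=False, order=0, mode="constant", cval=0
    )
    return img_r, _check_binary(mask_r)


def translate_pair(img, mask, shift: tuple[int, int]):
    """Integer (row, col) translation with zero fill; exact index shift."""
    dy, dx = int(shift[0]), int(shift[1])
    out_i = np.zeros_like(np.asarray(img, dtype=np.float64))
    out_m = np.zeros_like(mask)
    h, w = img.shape
    ys = slice(max(dy, 0), min(h, h + dy))
    xs = slice(max(dx, 0), min(w, w + dx))
    ys_src = slice(max(-dy, 0), min(h, h - dy))
    xs_src = slice(max(-dx, 0), min(w, w - dx))
    out_i[ys, xs] = np.asarray(img, dtype=np.float64)[ys_src, xs_src]
    out_m[ys, xs] = mask[ys_src, xs_src]
    return out_i, out_m


def augment_pair(
    img: np.ndarray,
    mask: np.ndarray,
    cfg: AugmentCfg,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one randomly sampled geometric transform set to image and mask.

    The same parameters (flip decisions, rotation angle, integer translation)
    are applied to both, so alignment is preserved; sampling is reproducible
    from the seed.
    """
    if img.shape != mask.shape:
        raise ValueError("image/mask shape mismatch")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if cfg.flip_horizontal and rng.random() < 0.5:
        img, mask = flip_pair(img, mask, horizontal=True)
    if cfg.flip_vertical and rng.random() < 0.5:
        img, mask = flip_pair(img, mask, horizontal=False)
    if cfg.rotate > 0:
        angle = rng.uniform(-cfg.rotate, cfg.rotate)
        img, mask = rotate_pair(img, mask, angle)
    if cfg.translate > 0:
        max_px = int(cfg.translate * img.shape[0])
        if max_px > 0:
            shift = (
                int(rng.integers(-max_px, max_px + 1)),
                int(rng.integers(-max_px, max_px + 1)),
            )
            img, mask = translate_pair(img, mask, shift)
    return img, _check_binary(np.asarray(mask))


class PreprocessPipeline:
    """Composed transform: normalize -> resize -> equalize -> denoise (+ augment).

    Deterministic given (cfg, seed): the augmentation stream is re-seeded at
    construction and advanced once per call, so two pipelines built from the
    same config produce identical output sequences.
    """

    def __init__(self, cfg: PreprocessCfg):
        self.cfg = cfg
        self._rng = np.random.default_rng(cfg.seed)

    def reset(self) -> None:
        self._rng = np.random.default_rng(self.cfg.seed)

    def __call__(
        self, img: np.ndarray, mask: np.ndarray | None = None, train: bool = False
    ):
        cfg = self.cfg
        img = normalize_intensity(img, cfg.normalize)
        if mask is not None:
            _check_binary(mask)
            img, mask = resize_pair(img, mask, cfg.target_size)
        elif img.shape != (cfg.target_size, cfg.target_size):
            img = transform.resize(
                img, (cfg.target_size, cfg.target_size), order=1,
                anti_aliasing=img.shape[0] > cfg.target_size, preserve_range=True,
                mode="reflect",
            )
        if cfg.normalize == "minmax":
            img = equalize_histogram(img, cfg.equalize)
        img = denoise(img, cfg.denoise, cfg.denoise_strength)
        if cfg.normalize == "minmax":
            # equalization/denoising shift the range; restore the exact [0,1] span
            img = normalize_intensity(img, "minmax")
        if train and mask is not None:
            img, mask = augment_pair(img, mask, cfg.augment, self._rng)
        if mask is None:
            return img
        return img, _check_binary(mask)


def build_pipeline(cfg: PreprocessCfg) -> PreprocessPipeline:
    """Validate the config and return the composed transform."""
    if not isinstance(cfg, PreprocessCfg):
        raise TypeError("build_pipeline expects a PreprocessCfg")
    return PreprocessPipeline(cfg)
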