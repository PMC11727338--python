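"""Synthetic MRI-like phantoms with known tumor masks.

Each phantom is a smooth low-frequency background field plus one or more
irregular elliptical lesions (an ellipse whose radius is modulated by a
seeded low-order Fourier perturbation), an additive intensity offset of
``contrast`` inside the lesion, and optional Gaussian (or Rician) noise.
Scenario presets mirror the failure regimes a segmentation model faces in
practice: low-contrast boundaries, small lesions, and overlapping lesions.

All randomness flows from ``numpy.random.SeedSequence`` children of the
spec seed, so the same spec always produces bit-identical output, and
per-patient style parameters (background level, texture scale) are shared
across a patient's slices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

SCENARIOS = ("default", "low_contrast", "small_tumor", "overlapping")

# scenario presets: field overrides applied by PhantomSpec.for_scenario
_SCENARIO_PRESETS: dict[str, dict] = {
    "default": {},
    "low_contrast": {"contrast": 0.12},
    "small_tumor": {"lesion_radius_range": (2, 4)},
    "overlapping": {"n_lesions": 2},
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a single phantom image/mask pair.

    contrast is the mean foreground-background intensity gap on [0,1];
    noise_sd the additive noise SD in the same intensity units.
    """

    image_size: int = 64
    n_lesions: int = 1
    lesion_radius_range: tuple[int, int] = (6, 14)
    contrast: float = 0.4
    noise_sd: float = 0.03
    scenario: str = "default"
    noise_model: str = "gaussian"  # or "rician"
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.lesion_radius_range
        if lo < 1:
            raise ValueError("minimum lesion radius must be >= 1 pixel")
        if hi < lo:
            raise ValueError("lesion_radius_range must be (min, max) with min <= max")
        if hi > self.image_size / 2:
            raise ValueError(
                f"maximum lesion radius {hi} exceeds image_size/2 = "
                f"{self.image_size / 2}; lesion cannot be placed"
            )
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError("contrast must lie in [0, 1]")
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")

    @classmethod
    def for_scenario(cls, scenario: str, **overrides) -> "PhantomSpec":
        """Spec with the named scenario's preset parameters applied."""
        if scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        kwargs = dict(_SCENARIO_PRESETS[scenario])
        kwargs.update(overrides)
        return cls(scenario=scenario, **kwargs)


@dataclass
class PhantomPair:
    """An image, its ground-truth mask, and provenance."""

    image: np.ndarray  # float64 (H, W) or (H, W, C) in [0, 1]
    mask: np.ndarray  # uint8 (H, W) in {0, 1}
    patient_id: str
    spec: PhantomSpec

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("image and mask spatial shapes differ")


def _background(rng: np.random.Generator, size: int, base: float, texture_sigma: float) -> np.ndarray:
    field = rng.standard_normal((size, size))
    field = gaussian_filter(field, sigma=texture_sigma, mode="reflect")
    sd = field.std()
    if sd > 0:
        field = field / sd * 0.03
    return base + field


def _lesion_mask(
    rng: np.random.Generator, size: int, center: tuple[float, float], radius: float
) -> np.ndarray:
    """Irregular elliptical blob: ellipse radius modulated by Fourier noise.

    Axis ratio in [0.92, 1.08] and perturbation amplitude <= 0.12 bound the
    effective radius within [0.81 r, 1.21 r], so area stays close to pi r^2.
    """
    ecc = rng.uniform(0.92, 1.08)
    rx, ry = radius * ecc, radius / ecc
    phase = rng.uniform(0, 2 * np.pi, size=3)
    amp = rng.uniform(0.02, 0.12) / np.array([1.0, 1.5, 2.0])
    rows, cols = np.mgrid[0:size, 0:size].astype(np.float64)
    dy, dx = rows - center[0], cols - center[1]
    theta = np.arctan2(dy, dx)
    d = np.hypot(dy, dx)
    # ellipse boundary radius along theta
    r_ell = (rx * ry) / np.sqrt((ry * np.cos(theta)) ** 2 + (rx * np.sin(theta)) ** 2)
    perturb = sum(
        a * np.cos((k + 2) * theta + p) for k, (a, p) in enumerate(zip(amp, phase))
    )
    return (d <= r_ell * (1.0 + perturb)).astype(np.uint8)


def _add_noise(rng: np.random.Generator, image: np.ndarray, sd: float, model: str) -> np.ndarray:
    if sd == 0:
        return image
    if model == "rician":
        re = image + rng.normal(0.0, sd, image.shape)
        im = rng.normal(0.0, sd, image.shape)
        return np.hypot(re, im)
    return image + rng.normal(0.0, sd, image.shape)


def _generate_single(
    spec: PhantomSpec,
    rng: np.random.Generator,
    patient_id: str = "P000",
    base: float | None = None,
    texture_sigma: float | None = None,
) -> PhantomPair:
    s = spec.image_size
    if base is None:
        base = rng.uniform(0.22, 0.38)
    if texture_sigma is None:
        texture_sigma = rng.uniform(s / 10, s / 6)
    image = _background(rng, s, base, texture_sigma)

    lo, hi = spec.lesion_radius_range
    mask = np.zeros((s, s), dtype=np.uint8)
    prev_center: tuple[float, float] | None = None
    prev_radius = 0.0
    for i in range(spec.n_lesions):
        radius = rng.uniform(lo, hi)
        margin = min(radius + 2, s / 2 - 1)
        if spec.scenario == "overlapping" and prev_center is not None:
            # place close enough that the blobs touch or overlap
            dist = rng.uniform(0.4, 0.75) * (radius + prev_radius)
            angle = rng.uniform(0, 2 * np.pi)
            cy = float(np.clip(prev_center[0] + dist * np.sin(angle), margin, s - 1 - margin))
            cx = float(np.clip(prev_center[1] + dist * np.cos(angle), margin, s - 1 - margin))
        else:
            cy = rng.uniform(margin, s - 1 - margin)
            cx = rng.uniform(margin, s - 1 - margin)
        mask |= _lesion_mask(rng, s, (cy, cx), radius)
        prev_center, prev_radius = (cy, cx), radius

    image = image + spec.contrast * mask
    image = _add_noise(rng, image, spec.noise_sd, spec.noise_model)
    if spec.noise_sd > 0:
        image = np.clip(image, 0.0, 1.0)
    return PhantomPair(image=image, mask=mask, patient_id=patient_id, spec=spec)


def generate_phantom(spec: PhantomSpec) -> PhantomPair:
    """Generate one phantom pair; deterministic in ``spec`` (incl. seed)."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    return _generate_single(spec, rng)


def generate_dataset(
    spec: PhantomSpec, n_patients: int, slices_per_patient: int
) -> tuple[list[PhantomPair], pd.DataFrame]:
    """Generate a multi-patient dataset plus its manifest.

    Per-patient style (background level, texture scale) is drawn once per
    patient and shared across that patient's slices, so patient identity is
    a real statistical signal and split leakage is detectable.
    """
    if n_patients < 2:
        raise ValueError("n_patients must be >= 2 (patient-wise split untestable)")
    if slices_per_patient < 1:
        raise ValueError("slices_per_patient must be >= 1")
    pairs: list[PhantomPair] = []
    rows = []
    for p in range(n_patients):
        pid = f"P{p:03d}"
        style_rng = np.random.default_rng(np.random.SeedSequence((spec.seed, p)))
        base = style_rng.uniform(0.22, 0.38)
        texture_sigma = style_rng.uniform(spec.image_size / 10, spec.image_size / 6)
        for sl in range(slices_per_patient):
            rng = np.random.default_rng(np.random.SeedSequence((spec.seed, p, sl)))
            pair = _generate_single(
                spec, rng, patient_id=pid, base=base, texture_sigma=texture_sigma
            )
            pairs.append(pair)
            rows.append(
                {
                    "patient_id": pid,
                    "slice": sl,
                    "image_path": f"{pid}_s{sl:02d}_img.png",
                    "mask_path": f"{pid}_s{sl:02d}_mask.png",
                    "split": "",
                }
            )
    return pairs, pd.DataFrame(rows)
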