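"""File I/O: images (PNG/TIFF/NIfTI), masks, and dataset manifests.

Conventions: images load as float64 in [0, 1] (scaled by dtype range);
masks binarize at half their dynamic range; image origin is top-left with
(row, col) indexing throughout the package.  NIfTI volumes are consumed
slice-wise along the last axis.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .phantom import PhantomPair

IMAGE_SUFFIXES = (".png", ".tif", ".tiff", ".nii", ".nii.gz")


def _dtype_max(arr: np.ndarray) -> float:
    if np.issubdtype(arr.dtype, np.integer):
        return float(np.iinfo(arr.dtype).max)
    return 1.0


def _read_raw(path: Path, slice_index: int | None) -> np.ndarray:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        vol = np.asanyarray(nib.load(str(path)).dataobj)
        if vol.ndim == 3:
            if slice_index is None:
                raise ValueError(
                    f"{path} is a 3-D NIfTI volume; pass slice_index to pick a slice"
                )
            vol = vol[..., slice_index]
        if vol.ndim != 2:
            raise ValueError(f"{path}: expected a 2-D slice, got shape {vol.shape}")
        arr = np.asarray(vol, dtype=np.float64)
        lo, hi = arr.min(), arr.max()
        return (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    if name.endswith((".tif", ".tiff")):
        arr = tifffile.imread(str(path))
    elif name.endswith(".png"):
        arr = iio.imread(path)
    else:
        raise ValueError(f"unsupported image format: {path}")
    return np.asarray(arr, dtype=np.float64) / _dtype_max(np.asarray(arr))


def read_image(
    path, in_channels: int = 1, slice_index: int | None = None
) -> np.ndarray:
    """Load an image as float [0,1]; grayscale replicated to ``in_channels``."""
    arr = _read_raw(Path(path), slice_index)
    if arr.ndim == 3:  # drop alpha, keep RGB
        arr = arr[..., :3]
        if in_channels == 1:
            arr = arr.mean(axis=-1)
    if arr.ndim == 2 and in_channels > 1:
        arr = np.repeat(arr[..., None], in_channels, axis=-1)
    return arr


def read_mask(path, slice_index: int | None = None) -> np.ndarray:
    """Load a mask, binarized at half its dynamic range."""
    arr = _read_raw(Path(path), slice_index)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    return (arr >= 0.5).astype(np.uint8)


def write_image(path, img: np.ndarray) -> None:
    """Write a [0,1] float image as 8-bit PNG (or TIFF by suffix)."""
    arr = (np.clip(np.asarray(img, dtype=np.float64), 0, 1) * 255).round().astype(np.uint8)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), arr)
    else:
        iio.imwrite(path, arr)


def write_mask(path, mask: np.ndarray) -> None:
    write_image(path, np.asarray(mask, dtype=np.float64))


# ------------------------------------------------------------------ manifests

MANIFEST_COLUMNS = ["patient_id", "image_path", "mask_path", "split"]


def save_dataset(pairs: Sequence[PhantomPair], out_dir) -> pd.DataFrame:
    """Write phantom pairs as PNGs plus a manifest.csv; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    per_patient_counter: dict[str, int] = {}
    rows = []
    for pair in pairs:
        k = per_patient_counter.get(pair.patient_id, 0)
        per_patient_counter[pair.patient_id] = k + 1
        img_name = f"{pair.patient_id}_s{k:02d}_img.png"
        mask_name = f"{pair.patient_id}_s{k:02d}_mask.png"
        write_image(out / img_name, pair.image)
        write_mask(out / mask_name, pair.mask)
        rows.append(
            {
                "patient_id": pair.patient_id,
                "image_path": img_name,
                "mask_path": mask_name,
                "split": "",
            }
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def load_manifest(path, check_paths: bool = True) -> pd.DataFrame:
    """Read and validate a manifest CSV.

    Rejects missing columns, nonexistent files (when check_paths), and any
    patient whose rows carry more than one split tag (leakage).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    if check_paths:
        base = path.parent
        for col in ("image_path", "mask_path"):
            for rel in df[col]:
                if not (base / rel).exists():
                    raise FileNotFoundError(f"manifest references missing file: {rel}")
    tagged = df[df["split"] != ""]
    leaky = tagged.groupby("patient_id")["split"].nunique()
    bad = leaky[leaky > 1]
    if len(bad):
        raise ValueError(
            f"patient leakage: patients with multiple split tags: {list(bad.index)}"
        )
    return df


def load_pairs_from_manifest(manifest: pd.DataFrame, base_dir) -> list[PhantomPair]:
    """Materialise image/mask pairs referenced by a manifest."""
    from .phantom import PhantomSpec

    base = Path(base_dir)
    pairs = []
    for _, row in manifest.iterrows():
        img = read_image(base / row["image_path"])
        mask = read_mask(base / row["mask_path"])
        spec = PhantomSpec(
            image_size=max(img.shape[0], 4), n_lesions=0,
            lesion_radius_range=(1, 1), noise_sd=0.0,
        )
        pairs.append(
            PhantomPair(image=img, mask=mask, patient_id=row["patient_id"], spec=spec)
        )
    return pairs
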