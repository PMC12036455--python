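"""Reading and writing images, masks, and channel bundles.

2D masks/images: PNG via imageio; 3D: NIfTI via nibabel or NPZ; plain
NPY/NPZ bundles everywhere.  MedMNIST-layout NPZ archives (train/val/
test image and label arrays) are supported for dataset loading.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = [
    "read_image", "write_mask", "read_mask",
    "write_channels", "load_npz_dataset",
]


def read_image(path) -> np.ndarray:
    """Scalar image from PNG/TIFF (2D), NIfTI (3D), NPY or NPZ."""
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if path.suffix in (".png", ".tif", ".tiff", ".bmp"):
        import imageio.v3 as iio

        img = np.asarray(iio.imread(path), dtype=np.float64)
        if img.ndim == 3:  # channel-last RGB(A): unweighted mean
            img = img[..., :3].mean(axis=-1)
        return img
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        return np.asarray(nib.load(path).get_fdata(), dtype=np.float64)
    if path.suffix == ".npy":
        return np.load(path).astype(np.float64)
    if path.suffix == ".npz":
        data = np.load(path)
        key = "image" if "image" in data else list(data.keys())[0]
        return data[key].astype(np.float64)
    raise ValueError(f"unsupported image format: {path}")


def write_mask(mask: np.ndarray, path) -> None:
    path = Path(path)
    mask = np.asarray(mask, dtype=bool)
    if path.suffix == ".png":
        if mask.ndim != 2:
            raise ValueError("PNG masks must be 2D")
        import imageio.v3 as iio

        iio.imwrite(path, (mask * 255).astype(np.uint8))
    elif "".join(path.suffixes).endswith((".nii", ".nii.gz")):
        import nibabel as nib

        nib.save(nib.Nifti1Image(mask.astype(np.uint8), np.eye(4)), path)
    elif path.suffix == ".npz":
        np.savez(path, mask=mask)
    else:
        raise ValueError(f"unsupported mask format: {path}")


def read_mask(path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".npz":
        return np.load(path)["mask"].astype(bool)
    return read_image(path) > 0


def write_channels(channels: np.ndarray, path, names: list[str], meta: dict | None = None) -> None:
    """NPZ with key ``channels`` plus a JSON sidecar recording the order."""
    path = Path(path)
    np.savez(path, channels=channels)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"channel_order": names, **(meta or {})}, indent=2))


def load_npz_dataset(path) -> dict:
    """MedMNIST-layout NPZ: train/val/test ``*_images`` and ``*_labels``."""
    data = np.load(path)
    out = {}
    for split in ("train", "val", "test"):
        out[f"{split}_images"] = data[f"{split}_images"]
        out[f"{split}_labels"] = data[f"{split}_labels"]
    return out
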