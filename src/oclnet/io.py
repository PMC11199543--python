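"""Reading, writing, and resampling of MetaImage (.mhd/.mha) and NIfTI volumes.

File access goes through SimpleITK; arrays come back in (z, y, x) order,
which is the package-wide index convention.  SimpleITK reports spacing and
origin in (x, y, z) order, so both are reversed at the boundary.
"""

from __future__ import annotations

import os
from typing import Literal

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .volume import FormatError, GeometryError, MaskVolume, Volume

__all__ = [
    "read_volume",
    "write_volume",
    "resample_volume",
    "load_pair",
    "normalize_intensity",
]

_EXTENSIONS = (".mhd", ".mha", ".nii", ".nii.gz")


def _check_extension(path: str) -> None:
    low = path.lower()
    if not any(low.endswith(ext) for ext in _EXTENSIONS):
        raise FormatError(f"unsupported volume format: {path}")


def read_volume(path: str, kind: Literal["image", "mask"] = "image") -> Volume:
    """Load a volume; ``kind='mask'`` binarizes with the rule value > 0 -> 1."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    _check_extension(path)
    try:
        img = sitk.ReadImage(path)
        arr = sitk.GetArrayFromImage(img)
    except RuntimeError as exc:  # header/payload mismatch, truncated raw, ...
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got {arr.ndim} axes")
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    if kind == "mask":
        return MaskVolume((arr > 0).astype(np.uint8), spacing, origin)
    if not np.isfinite(arr).all():
        raise FormatError(f"{path}: non-finite voxel values")
    return Volume(arr, spacing, origin)


def write_volume(v: Volume, path: str) -> str:
    _check_extension(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(v.data))
    img.SetSpacing(tuple(reversed(v.spacing)))
    img.SetOrigin(tuple(reversed(v.origin)))
    try:
        sitk.WriteImage(img, path)
    except RuntimeError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc
    return path


def resample_volume(
    v: Volume,
    target_shape: tuple[int, int, int],
    mode: Literal["trilinear", "nearest"] = "trilinear",
) -> Volume:
    """Resample to ``target_shape`` with cell-centred per-axis rescaling.

    Masks must use ``mode='nearest'`` so the output stays binary; spacing is
    rescaled to preserve each axis's physical extent.
    """
    if any(n < 1 for n in target_shape):
        raise ValueError(f"invalid target shape {target_shape}")
    is_mask = isinstance(v, MaskVolume)
    if is_mask and mode != "nearest":
        raise ValueError("masks must be resampled with mode='nearest'")
    if tuple(target_shape) == v.shape:
        out_data = v.data.copy()
    else:
        factors = [t / s for t, s in zip(target_shape, v.shape)]
        order = 0 if mode == "nearest" else 1
        out_data = ndimage.zoom(
            v.data.astype(np.float32) if not is_mask else v.data,
            factors,
            order=order,
            grid_mode=True,
            mode="grid-constant",
        )
        # zoom can be off by one voxel on awkward ratios; enforce the contract
        if out_data.shape != tuple(target_shape):
            out_data = out_data[tuple(slice(0, n) for n in target_shape)]
    spacing = tuple(
        sp * old / new for sp, old, new in zip(v.spacing, v.shape, target_shape)
    )
    cls = MaskVolume if is_mask else Volume
    if is_mask:
        out_data = (out_data > 0).astype(np.uint8)
    return cls(out_data, spacing, v.origin)


def load_pair(image_path: str, label_path: str) -> tuple[Volume, MaskVolume]:
    """Load a matched image/label pair, validating their shared geometry."""
    image = read_volume(image_path, kind="image")
    label = read_volume(label_path, kind="mask")
    if image.shape != label.shape:
        raise GeometryError(
            f"shape mismatch: image {image.shape} vs label {label.shape}"
        )
    if not np.allclose(image.spacing, label.spacing, rtol=1e-3, atol=0.0):
        raise GeometryError(
            f"spacing mismatch: image {image.spacing} vs label {label.spacing}"
        )
    assert isinstance(label, MaskVolume)
    return image, label


def normalize_intensity(data: np.ndarray) -> np.ndarray:
    """Min–max scale a volume to [0, 1]; constant volumes map to zeros."""
    data = data.astype(np.float32)
    lo, hi = float(data.min()), float(data.max())
    if hi - lo < 1e-12:
        return np.zeros_like(data)
    return (data - lo) / (hi - lo)
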