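"""Auto-adapting crop schema: lesion-centred input regeneration.

After a preliminary training phase the model's own predicted masks locate
the lesion; each mask is nearest-upsampled to a working resolution, its
bounding box extracted, and a fixed-size window centred on the box is
cropped from the correspondingly upsampled image.  The crop keeps the
network input size unchanged (mode ``S``) while the lesion occupies a much
larger fraction of it, stripping irrelevant background.  Mode ``D`` crops
at the native resolution without the upsampling step (ablation variant).

Predictions that are empty or nearly so fall back to a centre crop of the
whole grid; every volume's outcome is recorded in an :class:`AdaptReport`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .io import resample_volume
from .volume import MaskVolume, Volume

__all__ = [
    "BBox3D",
    "AdaptConfig",
    "AdaptRecord",
    "AdaptReport",
    "mask_bounding_box",
    "upscale_mask",
    "crop_centered",
    "crop_window_origin",
    "adapt_dataset",
    "restore_to_native",
]


@dataclass(frozen=True)
class BBox3D:
    """Axis-aligned integer box; ``lower`` inclusive, ``upper`` exclusive."""

    lower: tuple[int, int, int]
    upper: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(l >= u for l, u in zip(self.lower, self.upper)):
            raise ValueError(f"degenerate box {self.lower}..{self.upper}")

    @property
    def centroid(self) -> tuple[int, int, int]:
        """Centre voxel, rounded toward the lower index on ties."""
        return tuple((l + u - 1) // 2 for l, u in zip(self.lower, self.upper))

    @property
    def size(self) -> tuple[int, int, int]:
        return tuple(u - l for l, u in zip(self.lower, self.upper))


@dataclass(frozen=True)
class AdaptConfig:
    upscale_shape: tuple[int, int, int] = (256, 256, 256)
    crop_shape: tuple[int, int, int] = (128, 128, 128)
    mode: Literal["S", "D"] = "S"
    min_fg_voxels: int = 10


@dataclass
class AdaptRecord:
    index: int
    bbox: BBox3D | None
    fallback: bool
    lesion_retention: float
    # coordinate of crop voxel (0,0,0) on the grid the crop was taken from
    # (may be negative when the window was padded); None on the fallback
    # and oversized-lesion paths
    crop_origin: tuple[int, int, int] | None = None


@dataclass
class AdaptReport:
    records: list[AdaptRecord] = field(default_factory=list)

    @property
    def fallback_fraction(self) -> float:
        if not self.records:
            return 0.0
        return sum(r.fallback for r in self.records) / len(self.records)

    @property
    def mean_retention(self) -> float:
        vals = [r.lesion_retention for r in self.records if not np.isnan(r.lesion_retention)]
        return float(np.mean(vals)) if vals else float("nan")

    def write_csv(self, path: str) -> str:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["index", "bbox_lower", "bbox_upper", "fallback", "lesion_retention"])
            for r in self.records:
                lo = " ".join(map(str, r.bbox.lower)) if r.bbox else ""
                hi = " ".join(map(str, r.bbox.upper)) if r.bbox else ""
                w.writerow([r.index, lo, hi, int(r.fallback), f"{r.lesion_retention:.4f}"])
        return path


def mask_bounding_box(mask: MaskVolume | np.ndarray) -> BBox3D | None:
    """Tightest box containing all foreground voxels; None when empty."""
    arr = mask.data if isinstance(mask, MaskVolume) else np.asarray(mask)
    idx = np.nonzero(arr)
    if idx[0].size == 0:
        return None
    return BBox3D(
        lower=tuple(int(a.min()) for a in idx),
        upper=tuple(int(a.max()) + 1 for a in idx),
    )


def upscale_mask(mask: MaskVolume, target_shape: tuple[int, int, int]) -> MaskVolume:
    """Nearest-neighbour upscaling; counts scale exactly for integer factors."""
    if any(t < s for t, s in zip(target_shape, mask.shape)):
        raise ValueError(
            f"upscale target {target_shape} smaller than mask {mask.shape}"
        )
    return resample_volume(mask, target_shape, mode="nearest")


def _window(c: int, size: int, n: int) -> tuple[int, int, int, int]:
    """Crop window [lo, hi) of ``size`` centred on c in a grid of length n,
    clamped; returns (lo, hi, pad_before, pad_after).  The start rounds up
    on even sizes so a box of exactly ``size`` voxels centred at its own
    centroid stays fully inside the window."""
    lo = c - (size - 1) // 2
    hi = lo + size
    pad_lo = max(0, -lo)
    pad_hi = max(0, hi - n)
    return max(lo, 0), min(hi, n), pad_lo, pad_hi


def crop_window_origin(
    bbox: BBox3D, crop_shape: tuple[int, int, int]
) -> tuple[int, int, int]:
    """Grid coordinate of crop voxel (0,0,0) for a centred window (may be
    negative where the window overruns the grid and is padded)."""
    return tuple(c - (s - 1) // 2 for c, s in zip(bbox.centroid, crop_shape))


def crop_centered(
    image: Volume,
    label: MaskVolume,
    bbox: BBox3D | None,
    config: AdaptConfig,
) -> tuple[Volume, MaskVolume]:
    """Extract a ``crop_shape`` window centred on the box centroid.

    Mode ``S``: image and label are first resampled to ``upscale_shape``
    (image trilinear, label nearest) and the box must refer to that grid.
    Mode ``D``: crop at native resolution.  Windows overrunning the grid
    are clamped and padded with the image minimum (labels with zero).
    A ``None`` box triggers the whole-grid fallback: the original
    (pre-upscale) volumes resampled to ``crop_shape``, so the full field
    of view — and any lesion in it — is preserved.  A box larger than the
    crop window is resampled down to it instead of cropped.
    """
    cs = tuple(config.crop_shape)
    if bbox is None:
        return (
            resample_volume(image, cs, mode="trilinear"),
            resample_volume(label, cs, mode="nearest"),
        )
    if config.mode == "S":
        image = resample_volume(image, config.upscale_shape, mode="trilinear")
        label = resample_volume(label, config.upscale_shape, mode="nearest")
    shape = image.shape

    if any(b > c for b, c in zip(bbox.size, cs)):
        # oversized lesion: take the box region and resample it down
        region_img = Volume(
            image.data[tuple(slice(l, u) for l, u in zip(bbox.lower, bbox.upper))],
            image.spacing,
            image.origin,
        )
        region_lab = MaskVolume(
            label.data[tuple(slice(l, u) for l, u in zip(bbox.lower, bbox.upper))],
            label.spacing,
            label.origin,
        )
        return (
            resample_volume(region_img, cs, mode="trilinear"),
            resample_volume(region_lab, cs, mode="nearest"),
        )
    center = bbox.centroid

    fill = float(image.data.min())
    img_out = np.full(cs, fill, dtype=np.float32)
    lab_out = np.zeros(cs, dtype=np.uint8)
    src, dst = [], []
    for c, size, n in zip(center, cs, shape):
        lo, hi, pad_lo, _ = _window(c, size, n)
        src.append(slice(lo, hi))
        dst.append(slice(pad_lo, pad_lo + (hi - lo)))
    img_out[tuple(dst)] = image.data[tuple(src)]
    lab_out[tuple(dst)] = label.data[tuple(src)]
    return (
        Volume(img_out, image.spacing, image.origin),
        MaskVolume(lab_out, label.spacing, label.origin),
    )


def adapt_dataset(
    model,
    dataset: list[tuple[Volume, MaskVolume]],
    config: AdaptConfig,
    threshold: float = 0.5,
) -> tuple[list[tuple[Volume, MaskVolume]], AdaptReport]:
    """Regenerate lesion-centred inputs from the model's own predictions.

    For each pair: predict → binarize → (mode S) upsample the predicted
    mask to ``upscale_shape`` → bounding box → centred crop of image and
    ground-truth label with the identical transform.  Predictions with
    fewer than ``min_fg_voxels`` foreground voxels use the whole-grid
    fallback.  ``model`` may be any object with a
    ``predict_mask(image_volume, threshold) -> MaskVolume`` method or a
    plain callable returning a predicted MaskVolume; ground-truth masks can
    be passed directly by wrapping them in an oracle callable.
    """
    adapted: list[tuple[Volume, MaskVolume]] = []
    report = AdaptReport()
    for i, (image, label) in enumerate(dataset):
        pred = model(image) if callable(model) else model.predict_mask(image, threshold)
        fallback = pred.num_foreground < config.min_fg_voxels
        bbox = None
        if not fallback:
            if config.mode == "S":
                pred_up = upscale_mask(pred, config.upscale_shape)
                bbox = mask_bounding_box(pred_up)
            else:
                bbox = mask_bounding_box(pred)
            fallback = bbox is None
        img_c, lab_c = crop_centered(image, label, bbox, config)
        # retention is measured on the grid the crop was taken from, so the
        # mode-S upsampling factor cancels out; the whole-grid fallback
        # keeps the full field of view and thus retains everything
        if bbox is None:
            retention = 1.0 if label.num_foreground else float("nan")
        else:
            if config.mode == "S":
                total = resample_volume(
                    label, config.upscale_shape, mode="nearest"
                ).num_foreground
            else:
                total = label.num_foreground
            retention = lab_c.num_foreground / total if total else float("nan")
        origin = (
            crop_window_origin(bbox, tuple(config.crop_shape))
            if bbox is not None
            and all(b <= c for b, c in zip(bbox.size, config.crop_shape))
            else None
        )
        adapted.append((img_c, lab_c))
        report.records.append(
            AdaptRecord(i, bbox, bool(fallback), float(retention), origin)
        )
    return adapted, report


def restore_to_native(
    crop: Volume | MaskVolume,
    record: AdaptRecord,
    config: AdaptConfig,
    native_shape: tuple[int, int, int],
) -> Volume | MaskVolume:
    """Map a crop-space grid back onto the original volume's grid.

    Inverts the geometry of :func:`adapt_dataset` for one volume: the crop
    is pasted into a zero canvas at its recorded window position (on the
    upscaled grid in mode S) and resampled back to ``native_shape``
    (nearest for masks, trilinear for scalar grids).  Voxels outside the
    crop come back as zero.  Fallback crops cover the whole field of view
    and are simply resampled; oversized-box crops are resampled up into
    their recorded box.
    """
    is_mask = isinstance(crop, MaskVolume)
    mode = "nearest" if is_mask else "trilinear"
    cls = MaskVolume if is_mask else Volume
    grid_shape = tuple(config.upscale_shape) if config.mode == "S" else tuple(native_shape)

    if record.bbox is None:  # whole-grid fallback
        return resample_volume(crop, tuple(native_shape), mode=mode)

    canvas = np.zeros(grid_shape, dtype=crop.data.dtype)
    if record.crop_origin is None:  # oversized box: crop was the box region
        region = resample_volume(crop, record.bbox.size, mode=mode)
        sl = tuple(slice(l, u) for l, u in zip(record.bbox.lower, record.bbox.upper))
        canvas[sl] = region.data
    else:
        src, dst = [], []
        for o, size, n in zip(record.crop_origin, crop.shape, grid_shape):
            lo, hi = max(o, 0), min(o + size, n)
            dst.append(slice(lo, hi))
            src.append(slice(lo - o, hi - o))
        canvas[tuple(dst)] = crop.data[tuple(src)]
    out = cls(canvas)
    if grid_shape == tuple(native_shape):
        return out
    return resample_volume(out, tuple(native_shape), mode=mode)
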