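"""In-memory containers for 3-D medical volumes.

Index convention is ``(z, y, x)``, zero-based, half-open ranges — the array
order SimpleITK produces for MetaImage/NIfTI files.  ``spacing`` and
``origin`` are stored in the same (z, y, x) order, in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Volume",
    "MaskVolume",
    "FormatError",
    "GeometryError",
    "GenerationError",
]


class FormatError(ValueError):
    """A file's header and payload disagree, or the format is unsupported."""


class GeometryError(ValueError):
    """An image/label pair is geometrically inconsistent."""


class GenerationError(RuntimeError):
    """Phantom construction cannot satisfy its constraints."""


def _vec3(v) -> tuple[float, float, float]:
    a = tuple(float(x) for x in v)
    if len(a) != 3:
        raise ValueError(f"expected a 3-vector, got length {len(a)}")
    return a  # type: ignore[return-value]


@dataclass
class Volume:
    """A 3-D scalar grid with voxel spacing and origin (z, y, x order)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume data must be 3-D, got shape {self.data.shape}")
        self.spacing = _vec3(self.spacing)
        self.origin = _vec3(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.isfinite(self.data).all():
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class MaskVolume(Volume):
    """A binary 3-D grid; values are exactly {0, 1}."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask values must be in {{0, 1}}, found {vals[:5]}")

    @property
    def num_foreground(self) -> int:
        return int(self.data.sum())


def same_geometry(a: Volume, b: Volume, rtol: float = 1e-3) -> bool:
    """True when shapes match and spacings agree within relative tolerance."""
    return a.shape == b.shape and bool(
        np.allclose(a.spacing, b.spacing, rtol=rtol, atol=0.0)
    )
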