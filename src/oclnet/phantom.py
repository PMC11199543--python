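"""Synthetic jaw-phantom volumes with a single embedded cystic lesion.

Each phantom emulates the geometry that makes jaw-lesion delineation on
cone-beam CT hard: a bright, curved bone arch (mandible surrogate) carrying
small hyperintense spheres (teeth surrogates), with one hypointense
ellipsoidal lesion carved into the arch.  Four lesion profiles span the
size/location variability of the clinical subtypes — small lesions near the
tooth crowns, small peri-apical lesions, and medium/large expansile
lesions.  The paired ground-truth mask is the exact voxelization of the
lesion ellipsoid; additive Gaussian noise is applied to the image only.

All randomness flows from ``PhantomParams.seed``, so identical parameters
give bit-identical phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Sequence

import numpy as np

from .volume import GenerationError, MaskVolume, Volume

__all__ = [
    "PhantomParams",
    "LESION_PROFILES",
    "generate_phantom",
    "generate_dataset",
    "phantom_summary",
]

Profile = Literal["small_crown", "small_apical", "medium", "large"]

# lesion radius range per profile, as a fraction of the volume extent
LESION_PROFILES: dict[str, tuple[float, float]] = {
    "small_crown": (0.045, 0.075),
    "small_apical": (0.045, 0.075),
    "medium": (0.08, 0.12),
    "large": (0.13, 0.19),
}

_PROFILE_CYCLE: tuple[str, ...] = ("small_crown", "small_apical", "medium", "large")


@dataclass(frozen=True)
class PhantomParams:
    """Generation parameters for one phantom volume."""

    shape: tuple[int, int, int] = (64, 64, 64)
    lesion_profile: Profile = "medium"
    lesion_radius_range: tuple[float, float] | None = None  # overrides profile
    background_intensity: float = 0.10
    bone_intensity: float = 0.85
    tooth_intensity: float = 1.0
    lesion_intensity: float = 0.25
    noise_sd: float = 0.04
    anisotropy: float = 0.35  # max relative deviation of ellipsoid semi-axes
    n_teeth_range: tuple[int, int] = (4, 8)
    spacing: tuple[float, float, float] = (0.4, 0.4, 0.4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lesion_profile not in LESION_PROFILES:
            raise ValueError(f"unknown lesion profile {self.lesion_profile!r}")
        if self.lesion_intensity >= self.bone_intensity:
            raise ValueError("lesion must be hypointense relative to bone")
        lo, hi = self.radius_range
        if not (0.0 < lo <= hi < 0.5):
            raise ValueError(f"lesion radius fractions must lie in (0, 0.5): {lo, hi}")

    @property
    def radius_range(self) -> tuple[float, float]:
        if self.lesion_radius_range is not None:
            return self.lesion_radius_range
        return LESION_PROFILES[self.lesion_profile]


def _arch_geometry(shape: Sequence[int]) -> dict[str, float]:
    """Geometry of the bone arch: a half-torus in the axial (y, x) plane."""
    nz, ny, nx = shape
    ext = min(shape)
    return {
        "cz": nz * 0.5,
        "cy": ny * 0.62,  # arch bows toward the anterior (low y) side
        "cx": nx * 0.5,
        "R": 0.30 * ext,  # major radius of the arch
        "rt": 0.12 * ext,  # tube (bone thickness) radius
    }


def generate_phantom(params: PhantomParams) -> tuple[Volume, MaskVolume]:
    """Build one (image, mask) phantom pair.

    Raises :class:`GenerationError` when the requested lesion cannot be
    placed inside the bone arch within the volume bounds.
    """
    rng = np.random.default_rng(params.seed)
    nz, ny, nx = params.shape
    ext = float(min(params.shape))
    g = _arch_geometry(params.shape)

    zz, yy, xx = np.meshgrid(
        np.arange(nz, dtype=np.float32),
        np.arange(ny, dtype=np.float32),
        np.arange(nx, dtype=np.float32),
        indexing="ij",
    )

    # half-torus arch: distance from the tube axis, restricted to the
    # anterior half-plane (y <= cy) plus a blend margin
    rho = np.sqrt((yy - g["cy"]) ** 2 + (xx - g["cx"]) ** 2)
    tube_d = np.sqrt((rho - g["R"]) ** 2 + (zz - g["cz"]) ** 2)
    arch = (tube_d <= g["rt"]) & (yy <= g["cy"] + 0.05 * ext)

    image = np.full(params.shape, params.background_intensity, dtype=np.float32)
    image[arch] = params.bone_intensity

    # teeth surrogates: small bright spheres on the crest of the arch
    n_teeth = int(rng.integers(params.n_teeth_range[0], params.n_teeth_range[1] + 1))
    tooth_r = 0.045 * ext
    angles = np.sort(rng.uniform(-0.45 * np.pi, 0.45 * np.pi, size=n_teeth))
    for a in angles:
        ty = g["cy"] - g["R"] * np.cos(a)
        tx = g["cx"] + g["R"] * np.sin(a)
        tz = g["cz"] - g["rt"] * 0.8  # crowns sit above the arch midline
        d2 = (zz - tz) ** 2 + (yy - ty) ** 2 + (xx - tx) ** 2
        image[d2 <= tooth_r**2] = params.tooth_intensity

    # lesion: axis-aligned ellipsoid centred on the arch tube axis
    lo, hi = params.radius_range
    base_r = rng.uniform(lo, hi) * ext
    radii = base_r * (1.0 + rng.uniform(-params.anisotropy, params.anisotropy, 3))
    radii = np.clip(radii, 1.2, None)

    theta = rng.uniform(-0.40 * np.pi, 0.40 * np.pi)
    cy = g["cy"] - g["R"] * np.cos(theta)
    cx = g["cx"] + g["R"] * np.sin(theta)
    if params.lesion_profile == "small_crown":
        cz = g["cz"] - 0.5 * g["rt"]  # near the crowns
    elif params.lesion_profile == "small_apical":
        cz = g["cz"] + 0.5 * g["rt"]  # near the root apices
    else:
        cz = g["cz"] + rng.uniform(-0.3, 0.3) * g["rt"]
    center = np.array([cz, cy, cx])

    margin = 1.0
    for axis, (c, r, n) in enumerate(zip(center, radii, params.shape)):
        if 2 * r + 2 * margin > n:
            raise GenerationError(
                f"lesion radius {r:.1f} vox on axis {axis} cannot fit the "
                f"{n}-voxel volume"
            )
        center[axis] = float(np.clip(c, r + margin, n - 1 - r - margin))

    mask_arr = (
        ((zz - center[0]) / radii[0]) ** 2
        + ((yy - center[1]) / radii[1]) ** 2
        + ((xx - center[2]) / radii[2]) ** 2
    ) <= 1.0
    if not mask_arr.any():
        raise GenerationError("degenerate lesion: no voxel inside the ellipsoid")
    image[mask_arr] = params.lesion_intensity

    if params.noise_sd > 0:
        image += rng.normal(0.0, params.noise_sd, size=params.shape).astype(np.float32)

    vol = Volume(image.astype(np.float32), params.spacing)
    mask = MaskVolume(mask_arr.astype(np.uint8), params.spacing)
    return vol, mask


def _child_seed(master_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31))


def generate_dataset(
    n: int,
    params: PhantomParams | None = None,
    seed: int = 0,
) -> list[tuple[Volume, MaskVolume, str]]:
    """Generate ``n`` phantoms cycling over the four lesion profiles.

    Returns (image, mask, profile) triples; item seeds are derived
    deterministically from ``seed`` so the whole dataset is reproducible.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    template = params or PhantomParams()
    out = []
    for i in range(n):
        profile = _PROFILE_CYCLE[i % len(_PROFILE_CYCLE)]
        p = replace(
            template,
            lesion_profile=profile,  # type: ignore[arg-type]
            seed=_child_seed(seed, i),
        )
        vol, mask = generate_phantom(p)
        out.append((vol, mask, profile))
    return out


def phantom_summary(mask: MaskVolume) -> dict:
    """Voxel count, volume fraction, and centroid (None when empty)."""
    count = int(mask.data.sum())
    if count == 0:
        return {"lesion_voxels": 0, "volume_fraction": 0.0, "centroid": None}
    idx = np.argwhere(mask.data)
    centroid = tuple(float(c) for c in idx.mean(axis=0))
    return {
        "lesion_voxels": count,
        "volume_fraction": count / mask.data.size,
        "centroid": centroid,
    }
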