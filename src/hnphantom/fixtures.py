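"""Synthetic head-and-neck MRI volumes with known ground truth.

The fixture emulates the statistical structure of a neck MR exam rather
than its anatomy: an elliptic-cylinder body on a zero background, lobed
muscle compartments, a central mixed-tissue core, the remainder fat, with
each tissue painted at a distinct intensity plateau and corrupted by
additive Gaussian noise plus salt-and-pepper impulses.  Every fixture
ships its own ground-truth label map and body mask, so the whole pipeline
is testable without any external image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import labels as L
from .errors import ConfigError
from .io_volumes import VoxelVolume

DEFAULT_PLATEAUS = {"fat": 0.25, "muscle": 0.55, "mixed": 0.85}


@dataclass
class FixtureParams:
    """Geometry, plateau intensities and noise of the synthetic neck.

    The plateau means must be pairwise separated by more than four Gaussian
    noise standard deviations, which guarantees a separable clustering
    problem and makes exact-recovery tests meaningful.
    """

    shape: tuple[int, int, int] = (96, 96, 48)
    spacing: tuple[float, float, float] = (0.5, 0.5, 1.0)
    plateaus: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PLATEAUS))
    salt_pepper_fraction: float = 0.002
    gaussian_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 8 for n in self.shape):
            raise ConfigError(f"fixture shape {self.shape} too small")
        if any(s <= 0 for s in self.spacing):
            raise ConfigError("spacing must be positive")
        if not 0 <= self.salt_pepper_fraction < 0.5:
            raise ConfigError("salt_pepper_fraction must be in [0, 0.5)")
        if self.gaussian_sigma < 0:
            raise ConfigError("gaussian_sigma must be >= 0")
        unknown = set(self.plateaus) - set(L.SEGMENTED_TISSUES)
        if unknown:
            raise ConfigError(f"unknown plateau tissues {sorted(unknown)}")
        means = sorted(self.plateaus.values())
        for a, b in zip(means, means[1:]):
            if b - a <= 4 * self.gaussian_sigma:
                raise ConfigError(
                    f"plateau means {a} and {b} separated by <= 4 sigma "
                    f"({self.gaussian_sigma}); clustering would not be separable")


def make_fixture(params: FixtureParams | None = None
                 ) -> tuple[VoxelVolume, VoxelVolume, VoxelVolume]:
    """(intensity volume, ground-truth label map, body mask), seeded.

    Geometry (all in voxel units, scaled to the grid):
      * body: elliptic cylinder through all slices, semi-axes 0.8 of the
        half-extent in-plane;
      * mixed: central circular core, radius 0.18 of the smaller in-plane
        half-extent;
      * muscle: two lateral elliptical lobes flanking the core;
      * fat: every remaining body voxel.
    """
    params = params or FixtureParams()
    nx, ny, nz = params.shape
    rng = np.random.default_rng(params.seed)

    i, j = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    ax_, ay = 0.8 * nx / 2.0, 0.8 * ny / 2.0
    body2d = ((i - cx) / ax_) ** 2 + ((j - cy) / ay) ** 2 <= 1.0

    r_core = 0.18 * min(nx, ny) / 2.0
    core2d = (i - cx) ** 2 + (j - cy) ** 2 <= r_core ** 2

    lobe_dx = 0.45 * ax_
    la, lb = 0.28 * ax_, 0.42 * ay
    lobes2d = np.zeros_like(body2d)
    for sgn in (-1, 1):
        lobes2d |= ((i - (cx + sgn * lobe_dx)) / la) ** 2 + ((j - cy) / lb) ** 2 <= 1.0
    lobes2d &= body2d & ~core2d

    truth2d = np.zeros((nx, ny), dtype=np.int16)
    truth2d[body2d] = L.FAT
    truth2d[lobes2d] = L.MUSCLE
    truth2d[core2d & body2d] = L.MIXED

    truth = np.repeat(truth2d[:, :, None], nz, axis=2)
    mask = (truth > 0).astype(np.uint8)

    intensity = np.zeros(params.shape, dtype=np.float64)
    for tissue, mean in params.plateaus.items():
        intensity[truth == L.SEGMENTED_TISSUES[tissue]] = mean

    body = mask.astype(bool)
    if params.gaussian_sigma > 0:
        noise = rng.normal(0.0, params.gaussian_sigma, size=params.shape)
        intensity[body] += noise[body]
    if params.salt_pepper_fraction > 0:
        impulses = rng.random(params.shape) < params.salt_pepper_fraction
        impulses &= body
        intensity[impulses] = rng.choice([0.0, 1.0], size=int(impulses.sum()))
    intensity = np.clip(intensity, 0.0, 1.0)
    intensity[~body] = 0.0

    return (VoxelVolume(intensity, params.spacing, role="intensity"),
            VoxelVolume(truth, params.spacing, role="label"),
            VoxelVolume(mask, params.spacing, role="mask"))


def make_mask_shapes(kind: str, dims: tuple[int, int, int],
                     spacing: tuple[float, float, float], **geometry
                     ) -> tuple[VoxelVolume, float]:
    """Analytic test shape rasterized by voxel-center inclusion.

    Returns (mask volume, analytic volume in mm^3) so rasterization can be
    checked against the closed-form measure.

    kind='cylinder': radius_mm, height_mm (axis = superior-inferior)
    kind='ellipsoid': semi_axes_mm = (a, b, c) along the three grid axes
    kind='slab': extent_voxels = (ni, nj, nk) axis-aligned box at the origin
    """
    nx, ny, nz = dims
    dx, dy, dz = spacing
    centers = [(np.arange(n) + 0.5) * s - n * s / 2.0 for n, s in zip(dims, spacing)]
    gx, gy, gz = np.meshgrid(*centers, indexing="ij")

    if kind == "cylinder":
        r, h = float(geometry["radius_mm"]), float(geometry["height_mm"])
        if 2 * r > nx * dx or 2 * r > ny * dy or h > nz * dz:
            raise ConfigError("cylinder exceeds the grid extent")
        mask = (gx ** 2 + gy ** 2 <= r ** 2) & (np.abs(gz) <= h / 2.0)
        analytic = np.pi * r ** 2 * h
    elif kind == "ellipsoid":
        a, b, c = (float(v) for v in geometry["semi_axes_mm"])
        if 2 * a > nx * dx or 2 * b > ny * dy or 2 * c > nz * dz:
            raise ConfigError("ellipsoid exceeds the grid extent")
        mask = (gx / a) ** 2 + (gy / b) ** 2 + (gz / c) ** 2 <= 1.0
        analytic = 4.0 / 3.0 * np.pi * a * b * c
    elif kind == "slab":
        ni, nj, nk = (int(v) for v in geometry["extent_voxels"])
        if ni > nx or nj > ny or nk > nz:
            raise ConfigError("slab exceeds the grid extent")
        mask = np.zeros(dims, dtype=bool)
        mask[:ni, :nj, :nk] = True
        analytic = ni * nj * nk * dx * dy * dz
    else:
        raise ConfigError(f"unknown shape kind {kind!r}")

    return VoxelVolume(mask.astype(np.uint8), spacing, role="mask"), float(analytic)
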