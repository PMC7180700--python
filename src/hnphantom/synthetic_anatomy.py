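"""Stage 2 synthetic tissues: the skin layer and cervical lymph nodes (CLNs).

Skin is synthesized from the binary body mask, slice by axial slice: the
outermost body voxels — those within the configured thickness of the
0-to-1 mask transition — are relabelled skin, so the external silhouette of
the body is preserved exactly.  (An ``outward`` mode that grows the layer
into the background is available as an alternative reading.)

CLNs are two-region ellipsoids: an interior (the node proper) wrapped in a
shell of perinodal adipose tissue.  They are placed into axial level slabs
approximating the surgical neck levels I-VI, either at user-given centers
or at seeded-random positions, under hard constraints: at most 12 nodes in
total, at most 6 per level, pairwise non-overlapping, entirely inside the
body.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import labels as L
from .errors import ConfigError, PlacementError
from .io_volumes import VoxelVolume

LEVELS = ("I", "II", "III", "IV", "V", "VI")

MAX_CLNS_TOTAL = 12
MAX_CLNS_PER_LEVEL = 6
CLN_MAJOR_AXIS_RANGE_MM = (1.0, 25.0)

#: default thickness of the synthetic skin layer, millimetres
DEFAULT_SKIN_THICKNESS_MM = 1.4


@dataclass
class SkinConfig:
    thickness_mm: float = DEFAULT_SKIN_THICKNESS_MM
    mode: str = "inward"  # "inward": replace outermost body voxels; "outward": dilate

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise ConfigError(f"skin thickness must be > 0 mm, got {self.thickness_mm}")
        if self.mode not in ("inward", "outward"):
            raise ConfigError(f"unknown skin mode {self.mode!r}")


@dataclass
class CLNSpec:
    """One cervical lymph node to synthesize.

    major_axis_mm : full length of the major axis, 1.0-25.0 mm
    level : surgical neck level I-VI (selects the axial slab)
    state : ``healthy`` or ``metastasized`` (selects the dielectric curves)
    center_voxel : optional (i, j, k); when omitted the node is placed at a
        seeded-random position inside its level slab and the body
    minor_ratio : minor/major semi-axis ratio (oval shape; default 0.5)
    shell_fraction : fraction of each semi-axis occupied by the perinodal
        shell (default 0.2); the interior is the ellipsoid scaled by
        ``1 - shell_fraction``
    """

    major_axis_mm: float
    level: str
    state: str = "healthy"
    center_voxel: tuple[int, int, int] | None = None
    minor_ratio: float = 0.5
    shell_fraction: float = 0.2
    orientation_axis: int = 2  # major axis along superior-inferior by default

    def __post_init__(self) -> None:
        lo, hi = CLN_MAJOR_AXIS_RANGE_MM
        if not lo <= self.major_axis_mm <= hi:
            raise ConfigError(
                f"CLN major axis {self.major_axis_mm} mm outside the allowed "
                f"range [{lo}, {hi}] mm")
        if self.level not in LEVELS:
            raise ConfigError(f"unknown CLN level {self.level!r}; expected one of {LEVELS}")
        if self.state not in ("healthy", "metastasized"):
            raise ConfigError(f"unknown CLN state {self.state!r}")
        if not 0 < self.minor_ratio <= 1:
            raise ConfigError(f"minor_ratio must be in (0, 1], got {self.minor_ratio}")
        if not 0 < self.shell_fraction < 1:
            raise ConfigError(f"shell_fraction must be in (0, 1), got {self.shell_fraction}")
        if self.orientation_axis not in (0, 1, 2):
            raise ConfigError("orientation_axis must be 0, 1 or 2")


@dataclass
class LevelBoundaries:
    """Axial slice slabs [lo, hi) approximating neck levels I-VI."""

    slabs: dict[str, tuple[int, int]]
    n_slices: int

    def __post_init__(self) -> None:
        for level, (lo, hi) in self.slabs.items():
            if not (0 <= lo < hi <= self.n_slices):
                raise ConfigError(
                    f"level {level} slab [{lo}, {hi}) outside volume slice range "
                    f"[0, {self.n_slices})")

    def slab(self, level: str) -> tuple[int, int]:
        return self.slabs[level]

    def describe(self) -> str:
        """The informative note reported to the user before placement."""
        lines = ["Cervical lymph node level boundaries (axial slices, half-open):"]
        for level in LEVELS:
            lo, hi = self.slabs[level]
            lines.append(f"  level {level}: slices [{lo}, {hi})")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# skin


def skin_thickness_voxels(thickness_mm: float, spacing: tuple[float, ...]) -> tuple[int, int]:
    """Per-axis in-plane layer thickness: round(thickness / spacing), min 1."""
    tx = max(1, round(thickness_mm / spacing[0]))
    ty = max(1, round(thickness_mm / spacing[1]))
    return tx, ty


def generate_skin(mask: VoxelVolume, cfg: SkinConfig | None = None) -> np.ndarray:
    """Boolean skin-voxel set derived from the body mask.

    Works per axial slice in 2D: the layer thickness in voxels is
    ``round(thickness_mm / in-plane spacing)`` per axis (minimum 1), and a
    voxel belongs to the skin if its elliptical voxel-count distance to the
    nearest background voxel is within that thickness.  The slice-normal
    direction gets no skin — the top and bottom of the neck are cut planes,
    not body surface.  An empty mask yields an empty skin set.
    """
    cfg = cfg or SkinConfig()
    body = mask.data.astype(bool)
    skin = np.zeros_like(body)
    if not body.any():
        return skin
    tx, ty = skin_thickness_voxels(cfg.thickness_mm, mask.spacing)
    # distance in "thickness units": 1.0 means exactly tx voxels along x /
    # ty voxels along y; anisotropic in-plane spacing thus gets per-axis counts.
    # The half-voxel allowance compensates the offset between voxel centers
    # and the mask boundary on oblique/curved contours; it is below one
    # voxel step on either axis, so axis-aligned edges keep exactly tx/ty
    # skin voxels.
    sampling = (1.0 / tx, 1.0 / ty)
    threshold = 1.0 + 0.5 / max(tx, ty) + 1e-9
    for k in range(body.shape[2]):
        sl = body[:, :, k]
        if not sl.any():
            continue
        if cfg.mode == "inward":
            dist = ndimage.distance_transform_edt(sl, sampling=sampling)
            skin[:, :, k] = sl & (dist <= threshold)
        else:  # outward: layer grown into the background, silhouette expands
            dist = ndimage.distance_transform_edt(~sl, sampling=sampling)
            skin[:, :, k] = (~sl) & (dist <= threshold)
    return skin


def apply_skin(labels: VoxelVolume, mask: VoxelVolume,
               cfg: SkinConfig | None = None) -> VoxelVolume:
    """Relabel the skin voxel set in a label map (label precedence: skin
    overwrites segmented tissue; lymph nodes are placed afterwards and may
    overwrite skin)."""
    skin = generate_skin(mask, cfg)
    data = labels.data.copy()
    data[skin] = L.SKIN
    return labels.with_data(data)


# ---------------------------------------------------------------------------
# levels


def compute_level_boundaries(mask: VoxelVolume, scheme: str = "equal-fraction",
                             fractions: tuple[float, ...] | None = None,
                             custom: dict[str, tuple[int, int]] | None = None
                             ) -> LevelBoundaries:
    """Partition the neck's axial extent into six level slabs.

    ``equal-fraction`` (default) splits the occupied slice range evenly;
    ``fractions`` gives six relative slab sizes; ``custom`` passes explicit
    per-level [lo, hi) slice intervals through unchanged.  Level I is the
    most superior slab.  The slab layout is what :meth:`LevelBoundaries.describe`
    reports to the user before placement.
    """
    n_slices = mask.data.shape[2]
    if custom is not None:
        if set(custom) != set(LEVELS):
            raise ConfigError(f"custom levels must define exactly {LEVELS}")
        return LevelBoundaries(slabs=dict(custom), n_slices=n_slices)

    occupied = np.flatnonzero(mask.data.astype(bool).any(axis=(0, 1)))
    if occupied.size == 0:
        raise ConfigError("body mask is empty; no neck extent to partition")
    lo, hi = int(occupied[0]), int(occupied[-1]) + 1
    if hi - lo < len(LEVELS):
        raise ConfigError(
            f"neck extent of {hi - lo} slices is shorter than {len(LEVELS)} levels")

    if scheme == "equal-fraction":
        fractions = (1.0,) * len(LEVELS)
    elif scheme != "fractions":
        raise ConfigError(f"unknown level scheme {scheme!r}")
    if fractions is None or len(fractions) != len(LEVELS) or any(f <= 0 for f in fractions):
        raise ConfigError("need six positive slab fractions")
    edges = lo + np.round(np.cumsum((0.0,) + tuple(fractions)) /
                          sum(fractions) * (hi - lo)).astype(int)
    slabs = {}
    for i, level in enumerate(LEVELS):
        a, b = int(edges[i]), int(edges[i + 1])
        if b <= a:
            raise ConfigError(f"level {level} slab collapsed to zero slices")
        slabs[level] = (a, b)
    return LevelBoundaries(slabs=slabs, n_slices=n_slices)


# ---------------------------------------------------------------------------
# lymph nodes


def rasterize_cln(spec: CLNSpec, spacing: tuple[float, float, float]
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize one CLN as (interior, shell) voxel-offset arrays.

    The node is an ellipsoid with semi-axes (a, b, b), a = major/2 and
    b = a * minor_ratio, the major axis along ``spec.orientation_axis``.
    Voxels are included by voxel-center test; the interior is the ellipsoid
    scaled by (1 - shell_fraction) and the shell is the set difference, so
    the two regions partition the full raster exactly.
    Offsets are integer voxel displacements relative to the center voxel.
    """
    a = spec.major_axis_mm / 2.0
    b = a * spec.minor_ratio
    semi = [b, b, b]
    semi[spec.orientation_axis] = a
    for i in range(3):
        if 2 * semi[i] < spacing[i]:
            raise ConfigError(
                f"CLN of {spec.major_axis_mm} mm (semi-axis {semi[i]:.3g} mm on axis "
                f"{i}) is smaller than one voxel at spacing {spacing}; use spacing "
                f"<= {2 * semi[i]:.3g} mm on that axis")
    half = [int(np.ceil(semi[i] / spacing[i])) for i in range(3)]
    ax = [np.arange(-h, h + 1) for h in half]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    norm2 = ((gx * spacing[0] / semi[0]) ** 2 +
             (gy * spacing[1] / semi[1]) ** 2 +
             (gz * spacing[2] / semi[2]) ** 2)
    full = norm2 <= 1.0 + 1e-12
    inner = norm2 <= (1.0 - spec.shell_fraction + 1e-9) ** 2
    offsets = np.stack([gx, gy, gz], axis=-1)
    return offsets[inner & full], offsets[full & ~inner]


@dataclass
class Placement:
    spec: CLNSpec
    center: tuple[int, int, int]
    n_interior: int
    n_shell: int


@dataclass
class PlacementResult:
    labels: VoxelVolume
    placements: list[Placement] = field(default_factory=list)


def validate_cln_specs(specs: list[CLNSpec]) -> None:
    """Hard count constraints, checked before any placement happens."""
    if len(specs) > MAX_CLNS_TOTAL:
        raise ConfigError(
            f"{len(specs)} CLNs requested but at most {MAX_CLNS_TOTAL} are allowed in total")
    per_level: dict[str, int] = {}
    for s in specs:
        per_level[s.level] = per_level.get(s.level, 0) + 1
        if per_level[s.level] > MAX_CLNS_PER_LEVEL:
            raise ConfigError(
                f"more than {MAX_CLNS_PER_LEVEL} CLNs requested in level {s.level}")


def place_clns(labels: VoxelVolume, mask: VoxelVolume, specs: list[CLNSpec],
               levels: LevelBoundaries, seed: int = 0,
               max_retries: int = 1000) -> PlacementResult:
    """Place every CLN into the label map.

    Each node goes to its given center, or to a seeded-random center inside
    its level slab and the body mask.  Placed nodes are pairwise
    non-overlapping (interior + shell), never extend outside the body, and
    overwrite whatever tissue label was there (node precedence).  Placement
    is bit-reproducible given the seed.  Random placement retries at most
    ``max_retries`` candidate centers per node before failing.
    """
    validate_cln_specs(specs)
    body = mask.data.astype(bool)
    if specs and not body.any():
        raise ConfigError("cannot place CLNs: body mask is empty")
    data = labels.data.copy()
    occupied = np.zeros_like(body)
    rng = np.random.default_rng(seed)
    placements: list[Placement] = []

    for idx, spec in enumerate(specs):
        interior, shell = rasterize_cln(spec, labels.spacing)
        voxels = np.concatenate([interior, shell], axis=0)
        lo, hi = levels.slab(spec.level)

        if spec.center_voxel is not None:
            center = tuple(int(c) for c in spec.center_voxel)
            if not (0 <= center[2] < labels.data.shape[2]) or not body[center]:
                raise ConfigError(f"CLN #{idx + 1}: center {center} is outside the body mask")
            if not lo <= center[2] < hi:
                raise ConfigError(
                    f"CLN #{idx + 1}: center slice {center[2]} outside level "
                    f"{spec.level} slab [{lo}, {hi})")
            if not _fits(center, voxels, body, occupied):
                raise PlacementError(
                    f"CLN #{idx + 1} ({spec.major_axis_mm} mm, level {spec.level}) does "
                    f"not fit at the requested center {center}")
        else:
            center = None
            for _ in range(max_retries):
                k = int(rng.integers(lo, hi))
                in_slice = np.argwhere(body[:, :, k])
                if in_slice.size == 0:
                    continue
                i, j = in_slice[int(rng.integers(len(in_slice)))]
                cand = (int(i), int(j), k)
                if _fits(cand, voxels, body, occupied):
                    center = cand
                    break
            if center is None:
                raise PlacementError(
                    f"CLN #{idx + 1} ({spec.major_axis_mm} mm, {spec.state}, level "
                    f"{spec.level}): no non-overlapping in-body position found in "
                    f"{max_retries} retries")

        c = np.asarray(center)
        int_idx = tuple((interior + c).T)
        sh_idx = tuple((shell + c).T)
        data[int_idx] = L.CLN_INTERIOR[spec.state]
        data[sh_idx] = L.CLN_SHELL[spec.state]
        occupied[int_idx] = True
        occupied[sh_idx] = True
        placements.append(Placement(spec=spec, center=center,
                                    n_interior=len(interior), n_shell=len(shell)))

    return PlacementResult(labels=labels.with_data(data), placements=placements)


def _fits(center, voxels: np.ndarray, body: np.ndarray, occupied: np.ndarray) -> bool:
    pts = voxels + np.asarray(center)
    if (pts < 0).any() or (pts >= np.asarray(body.shape)).any():
        return False
    idx = tuple(pts.T)
    return bool(body[idx].all() and not occupied[idx].any())
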