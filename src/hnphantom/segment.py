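"""Stage 0/1 segmentation: K-means over body-voxel intensities, the
cluster-to-tissue assignment policy, and the remove-tissue-to-fat
simplification.

Clustering uses scalar voxel intensity as the only feature and covers body
voxels only (the background is masked out before segmentation), so with the
default k = 5 all five clusters are tissue clusters.  Cluster indices are
relabelled so that centroids are ascending, which makes the labelling
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from . import labels as L
from .errors import ConfigError
from .io_volumes import VoxelVolume

#: cluster rank (ascending centroid) -> tissue, for the default k = 5.
#: On a fat-suppressed T1 contrast fat is dark, so the two darkest tissue
#: clusters default to fat, the middle two to muscle, and the brightest to
#: the heterogeneous mixed tissue.  This table is a documented default only
#: and is meant to be overridden per exam (see ``assign_tissues``).
DEFAULT_RANK_TABLE_K5 = ("fat", "fat", "muscle", "muscle", "mixed")

UNASSIGNED = -1


@dataclass
class ClusterModel:
    """Converged K-means model over the body voxels of one volume."""

    k: int
    centroids: np.ndarray              # (k,) ascending
    assignment: np.ndarray             # int array, shape of the volume; -1 = background
    seed: int
    inertia: float
    spacing: tuple[float, float, float]

    def assignment_volume(self) -> VoxelVolume:
        # -1 marks background, so the raw assignment grid is not a
        # registered label map; expose it as a plain array wrapper instead.
        return VoxelVolume(self.assignment.astype(np.int16), self.spacing, role="intensity")


@dataclass
class TissueAssignment:
    """Total cluster -> tissue map plus per-cluster intensity statistics."""

    cluster_to_tissue: dict[int, str]
    cluster_stats: dict[int, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for c, (lo, hi) in self.cluster_stats.items():
            if lo > hi:
                raise ConfigError(f"cluster {c}: Imin {lo} > Imax {hi}")

    def tissues(self) -> set[str]:
        return set(self.cluster_to_tissue.values())


def kmeans_segment(volume: VoxelVolume, mask: VoxelVolume, k: int = 5,
                   seed: int = 0, max_iter: int = 300, tol: float = 1e-6,
                   n_init: int = 10) -> ClusterModel:
    """Lloyd's K-means on voxel intensities within the body mask.

    Runs k-means++ initialization ``n_init`` times with a fixed seed and
    keeps the best run; cluster indices are re-ordered by ascending
    centroid.  Deterministic given the seed.
    """
    if k < 2:
        raise ConfigError(f"k must be >= 2, got {k}")
    if mask.data.shape != volume.data.shape:
        raise ConfigError("mask shape does not match volume shape")
    body = mask.data.astype(bool)
    values = np.asarray(volume.data, dtype=np.float64)[body]
    if values.size == 0:
        raise ConfigError("mask selects no body voxels")
    n_distinct = np.unique(values).size
    if n_distinct < k:
        raise ConfigError(
            f"only {n_distinct} distinct intensities within the mask but k={k}; "
            "reduce k or check that the volume was preprocessed")

    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                max_iter=max_iter, tol=tol, random_state=seed)
    raw = km.fit_predict(values.reshape(-1, 1))
    centroids = km.cluster_centers_.ravel()
    order = np.argsort(centroids, kind="stable")
    remap = np.empty(k, dtype=np.int64)
    remap[order] = np.arange(k)

    assignment = np.full(volume.data.shape, UNASSIGNED, dtype=np.int16)
    assignment[body] = remap[raw]
    return ClusterModel(k=k, centroids=centroids[order], assignment=assignment,
                        seed=seed, inertia=float(km.inertia_), spacing=volume.spacing)


def assign_tissues(model: ClusterModel, intensity: VoxelVolume,
                   policy: tuple[str, ...] | None = None,
                   override: dict[int, str] | None = None) -> TissueAssignment:
    """Map clusters to tissues and record per-cluster intensity ranges.

    ``policy`` is a rank -> tissue table of length k (default:
    :data:`DEFAULT_RANK_TABLE_K5` for k = 5).  ``override`` is an explicit
    cluster -> tissue dict respected verbatim; it wins over the policy.
    Per-cluster Imin/Imax are computed from ``intensity`` for the later
    intensity-to-dielectric mapping.
    """
    if override is not None:
        mapping = {int(c): str(t) for c, t in override.items()}
        if set(mapping) != set(range(model.k)):
            raise ConfigError(
                f"override must map every cluster 0..{model.k - 1}, got {sorted(mapping)}")
    else:
        if policy is None:
            if model.k != len(DEFAULT_RANK_TABLE_K5):
                raise ConfigError(
                    f"no default rank table for k={model.k}; pass policy or override")
            policy = DEFAULT_RANK_TABLE_K5
        if len(policy) != model.k:
            raise ConfigError(f"policy table has {len(policy)} entries for k={model.k}")
        mapping = {rank: str(t) for rank, t in enumerate(policy)}
    unknown = set(mapping.values()) - set(L.SEGMENTED_TISSUES)
    if unknown:
        raise ConfigError(f"policy maps clusters to unknown tissues {sorted(unknown)}")

    stats: dict[int, tuple[float, float]] = {}
    data = np.asarray(intensity.data, dtype=np.float64)
    for c in range(model.k):
        sel = data[model.assignment == c]
        if sel.size:
            stats[c] = (float(sel.min()), float(sel.max()))
    return TissueAssignment(cluster_to_tissue=mapping, cluster_stats=stats)


def tissue_map_from_reference(model: ClusterModel,
                              reference_means: dict[str, float]) -> dict[int, str]:
    """Cluster -> tissue override by nearest reference intensity.

    Convenience for exams (or synthetic volumes) where approximate per-tissue
    mean intensities are known: each cluster is assigned the tissue whose
    reference mean is closest to the cluster centroid.
    """
    out: dict[int, str] = {}
    names = list(reference_means)
    means = np.array([reference_means[t] for t in names])
    for c, centroid in enumerate(model.centroids):
        out[c] = names[int(np.argmin(np.abs(means - centroid)))]
    return out


def labels_from_assignment(model: ClusterModel,
                           assignment: TissueAssignment) -> VoxelVolume:
    """Build the tissue label map from cluster assignments: background 0,
    body voxels carry the code of their cluster's tissue."""
    out = np.zeros(model.assignment.shape, dtype=np.int16)
    for c, tissue in assignment.cluster_to_tissue.items():
        out[model.assignment == c] = L.SEGMENTED_TISSUES[tissue]
    return VoxelVolume(out, model.spacing, role="label")


def simplify_to_fat(labels: VoxelVolume, tissue: str) -> VoxelVolume:
    """Relabel every voxel of the named tissue (``mixed`` or ``muscle``) as
    fat; no other voxel changes.  The MRI intensities of those voxels live
    in the intensity volume and are untouched, so the dielectric stage can
    still map them within the (enlarged) fat population."""
    if tissue not in ("mixed", "muscle"):
        raise ConfigError(f"cannot simplify tissue {tissue!r}; expected 'mixed' or 'muscle'")
    code = L.SEGMENTED_TISSUES[tissue]
    data = labels.data.copy()
    data[data == code] = L.FAT
    return labels.with_data(data)
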