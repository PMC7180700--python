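"""Voxel-volume container and I/O for DICOM series, NIfTI and HDF5 bundles.

Canonical axis order is (anterior-posterior, left-right, superior-inferior):
``data[:, :, k]`` is one axial slice, and the axial axis is always axis 2.
All readers normalize to this convention and record how the axial axis was
identified so the decision is queryable, never silent.

Voxel indexing is 0-based and half-open; physical coordinates are
voxel-center based (voxel ``(i, j, k)`` sits at ``((i + 0.5) * dx, ...)``).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np

from .errors import ConfigError, FormatError
from .labels import ALL_CODES

ROLES = ("intensity", "mask", "label", "permittivity", "conductivity")

#: name -> (dtype, role) of the four arrays a phantom bundle stores
BUNDLE_DATASETS = ("mri", "labels", "conductivity", "permittivity")


@dataclass
class VoxelVolume:
    """A 3D scalar grid with physical voxel spacing.

    Parameters
    ----------
    data:
        3D array, axes (anterior-posterior, left-right, superior-inferior).
    spacing:
        (dx, dy, dz) in millimetres per voxel, all strictly positive.
    role:
        What the scalars mean: one of ``intensity``, ``mask``, ``label``,
        ``permittivity``, ``conductivity``.  Role-specific invariants are
        enforced by :meth:`validate`.
    axial_axis:
        Index of the superior-inferior axis after normalization (always 2
        for volumes produced by this package); kept explicit so axis
        handling is auditable.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    role: str = "intensity"
    axial_axis: int = 2
    axial_axis_source: str = "constructed"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.validate()

    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ConfigError(f"expected 3D volume, got {self.data.ndim}D")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ConfigError(f"voxel spacing must be three positive values, got {self.spacing}")
        if self.role not in ROLES:
            raise ConfigError(f"unknown volume role {self.role!r}; expected one of {ROLES}")
        if self.role == "mask":
            vals = np.unique(self.data)
            if not np.isin(vals, (0, 1)).all():
                raise ConfigError("mask volume must contain only {0, 1}")
        elif self.role == "label":
            vals = np.unique(self.data)
            if not np.isin(vals, ALL_CODES).all():
                bad = sorted(set(vals.tolist()) - set(ALL_CODES))
                raise ConfigError(f"label volume contains unregistered codes {bad}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def in_plane_spacing(self) -> tuple[float, float]:
        return self.spacing[0], self.spacing[1]

    def with_data(self, data: np.ndarray, role: str | None = None) -> "VoxelVolume":
        """New volume sharing spacing/axes but with different voxels."""
        return replace(self, data=data, role=role if role is not None else self.role)


@dataclass
class PhantomBundle:
    """The four matrices a finished phantom consists of, plus provenance.

    ``mri`` is the pre-processed intensity exam, ``labels`` the tissue label
    map, and ``permittivity`` / ``conductivity`` the voxel-wise dielectric
    maps evaluated at ``frequency_hz``.
    """

    mri: VoxelVolume
    labels: VoxelVolume
    permittivity: VoxelVolume
    conductivity: VoxelVolume
    frequency_hz: float
    seed: int | None = None
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        vols = {
            "mri": self.mri,
            "labels": self.labels,
            "permittivity": self.permittivity,
            "conductivity": self.conductivity,
        }
        shapes = {name: v.shape for name, v in vols.items()}
        if len(set(shapes.values())) != 1:
            raise ConfigError(f"bundle volumes disagree in shape: {shapes}")
        spacings = {v.spacing for v in vols.values()}
        if len(spacings) != 1:
            raise ConfigError("bundle volumes disagree in voxel spacing")
        body = self.labels.data > 0
        if body.any() and np.min(self.permittivity.data[body]) < 1.0 - 1e-12:
            raise ConfigError("relative permittivity < 1 inside the body")
        if np.min(self.conductivity.data) < 0:
            raise ConfigError("negative conductivity in bundle")


# ---------------------------------------------------------------------------
# readers


def read_volume(path: str | os.PathLike, format_hint: str | None = None) -> VoxelVolume:
    """Read a 3D volume from a DICOM series directory, NIfTI file or HDF5 file.

    Spacing always comes from file metadata; a file without spacing metadata
    is an error (1 mm is never silently assumed).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file or directory: {path}")
    fmt = format_hint or _sniff_format(path)
    if fmt == "dicom":
        return _read_dicom_series(path)
    if fmt == "nifti":
        return _read_nifti(path)
    if fmt == "hdf5":
        return _read_hdf5_volume(path)
    raise FormatError(f"unrecognized volume format for {path}")


def _sniff_format(path: Path) -> str:
    if path.is_dir():
        return "dicom"
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".h5", ".hdf5")):
        return "hdf5"
    raise FormatError(f"cannot infer format of {path}; pass format_hint")


def _read_nifti(path: Path) -> VoxelVolume:
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises a zoo of types
        raise FormatError(f"unreadable NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected 3D volume, got {data.ndim}D in {path}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise FormatError(f"missing or non-positive voxel spacing metadata in {path}")
    return VoxelVolume(
        data=np.asarray(data, dtype=np.float64),
        spacing=tuple(float(z) for z in zooms),
        role="intensity",
        axial_axis=2,
        axial_axis_source="nifti: third array axis taken as axial (package convention)",
    )


def _read_dicom_series(path: Path) -> VoxelVolume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue  # skip non-DICOM files in the directory
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise FormatError(f"no DICOM image slices found in {path}")
    if len(slices) < 2:
        raise FormatError("expected 3D volume; found a single DICOM slice")

    first = slices[0]
    if not hasattr(first, "PixelSpacing"):
        raise FormatError("DICOM series lacks PixelSpacing; refusing to assume 1 mm")
    if hasattr(first, "ImageOrientationPatient"):
        iop = np.asarray(first.ImageOrientationPatient, dtype=float)
        normal = np.cross(iop[:3], iop[3:])
    else:
        normal = np.array([0.0, 0.0, 1.0])

    def position(ds) -> float:
        if hasattr(ds, "ImagePositionPatient"):
            return float(np.dot(np.asarray(ds.ImagePositionPatient, dtype=float), normal))
        if hasattr(ds, "InstanceNumber"):
            return float(ds.InstanceNumber)
        raise FormatError("DICOM slice has neither ImagePositionPatient nor InstanceNumber")

    slices.sort(key=position)
    positions = np.array([position(s) for s in slices])
    dz_steps = np.diff(positions)
    if len(dz_steps) and np.all(dz_steps > 0):
        dz = float(np.mean(dz_steps))
    elif hasattr(first, "SliceThickness") and float(first.SliceThickness) > 0:
        dz = float(first.SliceThickness)
    else:
        raise FormatError("cannot determine DICOM slice spacing from positions or SliceThickness")

    dx, dy = (float(v) for v in first.PixelSpacing)
    data = np.stack([s.pixel_array.astype(np.float64) for s in slices], axis=2)
    return VoxelVolume(
        data=data,
        spacing=(dx, dy, dz),
        role="intensity",
        axial_axis=2,
        axial_axis_source="dicom: slices stacked along axis 2, sorted by ImagePositionPatient"
        " projected on the slice normal",
    )


def _read_hdf5_volume(path: Path, dataset: str = "volume") -> VoxelVolume:
    with h5py.File(path, "r") as f:
        if dataset not in f:
            raise FormatError(f"HDF5 file {path} has no dataset {dataset!r}")
        ds = f[dataset]
        if "spacing_mm" not in ds.attrs:
            raise FormatError(f"HDF5 dataset {dataset!r} lacks spacing_mm attribute")
        data = ds[()]
        spacing = tuple(float(s) for s in ds.attrs["spacing_mm"])
        role = str(ds.attrs.get("role", "intensity"))
    if data.ndim != 3:
        raise FormatError(f"expected 3D volume, got {data.ndim}D in {path}")
    return VoxelVolume(data=data, spacing=spacing, role=role, axial_axis=2,
                       axial_axis_source="hdf5: stored in canonical axis order")


def write_nifti(volume: VoxelVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1 with a diagonal affine from the spacing."""
    import nibabel as nib

    affine = np.diag([*volume.spacing, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume.data, dtype=np.float64), affine), str(path))


def write_hdf5_volume(volume: VoxelVolume, path: str | os.PathLike,
                      dataset: str = "volume") -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset(dataset, data=volume.data)
        ds.attrs["spacing_mm"] = np.asarray(volume.spacing, dtype=np.float64)
        ds.attrs["role"] = volume.role


# ---------------------------------------------------------------------------
# bundle writer / reader


def write_bundle(bundle: PhantomBundle, path: str | os.PathLike,
                 dialect: str = "hdf5") -> dict:
    """Write the four phantom matrices plus provenance; returns a manifest.

    ``dialect`` is ``hdf5`` (primary) or ``mat`` (MATLAB-v5-compatible
    container with the same four arrays).  Round-trip through
    :func:`read_bundle` is bit-exact on all arrays.
    """
    bundle.validate()
    path = Path(path)
    arrays = {
        "mri": bundle.mri.data,
        "labels": bundle.labels.data,
        "conductivity": bundle.conductivity.data,
        "permittivity": bundle.permittivity.data,
    }
    if dialect == "hdf5":
        with h5py.File(path, "w") as f:
            for name, arr in arrays.items():
                f.create_dataset(name, data=arr)
            f.attrs["frequency_hz"] = float(bundle.frequency_hz)
            f.attrs["spacing_mm"] = np.asarray(bundle.mri.spacing, dtype=np.float64)
            if bundle.seed is not None:
                f.attrs["seed"] = int(bundle.seed)
            f.attrs["provenance"] = json.dumps(bundle.provenance, sort_keys=True)
    elif dialect == "mat":
        from scipy.io import savemat

        payload = dict(arrays)
        payload["frequency_hz"] = float(bundle.frequency_hz)
        payload["spacing_mm"] = np.asarray(bundle.mri.spacing, dtype=np.float64)
        payload["seed"] = -1 if bundle.seed is None else int(bundle.seed)
        payload["provenance"] = json.dumps(bundle.provenance, sort_keys=True)
        savemat(str(path), payload)
    else:
        raise ConfigError(f"unknown bundle dialect {dialect!r}; use 'hdf5' or 'mat'")
    return {
        "path": str(path),
        "dialect": dialect,
        "datasets": list(BUNDLE_DATASETS),
        "shape": bundle.mri.shape,
        "frequency_hz": float(bundle.frequency_hz),
    }


def read_bundle(path: str | os.PathLike, dialect: str = "hdf5") -> PhantomBundle:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if dialect == "hdf5":
        with h5py.File(path, "r") as f:
            arrays = {name: f[name][()] for name in BUNDLE_DATASETS}
            spacing = tuple(float(s) for s in f.attrs["spacing_mm"])
            frequency = float(f.attrs["frequency_hz"])
            seed = int(f.attrs["seed"]) if "seed" in f.attrs else None
            provenance = json.loads(f.attrs.get("provenance", "{}"))
    elif dialect == "mat":
        from scipy.io import loadmat

        raw = loadmat(str(path))
        arrays = {name: raw[name] for name in BUNDLE_DATASETS}
        spacing = tuple(float(s) for s in np.ravel(raw["spacing_mm"]))
        frequency = float(np.ravel(raw["frequency_hz"])[0])
        seed = int(np.ravel(raw["seed"])[0])
        seed = None if seed < 0 else seed
        provenance = json.loads(str(np.ravel(raw["provenance"])[0]))
    else:
        raise ConfigError(f"unknown bundle dialect {dialect!r}")
    mk = lambda name, role: VoxelVolume(arrays[name], spacing, role=role)  # noqa: E731
    return PhantomBundle(
        mri=mk("mri", "intensity"),
        labels=mk("labels", "label"),
        permittivity=mk("permittivity", "permittivity"),
        conductivity=mk("conductivity", "conductivity"),
        frequency_hz=frequency,
        seed=seed,
        provenance=provenance,
    )
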