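"""PET volume and label-map containers with NIfTI-1 and raw-binary I/O.

A :class:`PETVolume` is a 3-D grid of non-negative tracer intensities with
physical voxel dimensions in mm, axis order ``(x, y, slice)``; a
:class:`LabelVolume` is an integer class map tagged with the domain it lives
in (spatial or wavelet) and the in-plane scale factor relating one of its
cells to the underlying spatial grid.

Supported on-disk formats:

* NIfTI-1 (``.nii`` / ``.nii.gz``) via nibabel; the affine is a pure voxel
  scaling (no rotation), so voxel size round-trips exactly.
* raw little-endian binary plus a JSON sidecar
  ``{"shape", "voxel_size_mm", "dtype", "order"}``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "PETVolume",
    "LabelVolume",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
]


@dataclass
class PETVolume:
    """3-D intensity grid with physical voxel dimensions.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Non-negative intensities; slice axis last.
    voxel_size : tuple of float
        (dx, dy, dz) in mm, all positive.
    description : str
        Free-text provenance tag.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    description: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3 or 0 in self.voxels.shape:
            raise ValueError(f"voxels must be a non-empty 3-D grid, got shape {self.voxels.shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be three positive mm values, got {self.voxel_size}")
        if np.min(self.voxels) < 0:
            raise ValueError("PET intensities must be non-negative")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("PET intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Physical volume of one voxel in millilitres."""
        dx, dy, dz = self.voxel_size
        return dx * dy * dz / 1000.0

    def with_voxels(self, voxels: np.ndarray, description: str | None = None) -> "PETVolume":
        """Copy of this volume with new voxel data but the same geometry."""
        return PETVolume(voxels, self.voxel_size,
                         self.description if description is None else description)


@dataclass
class LabelVolume:
    """Per-voxel integer class map, tagged with its domain and scale.

    ``scale_factor`` is the number of spatial voxels per label cell along
    each in-plane axis: 1 for the spatial domain, ``2**levels`` for a map
    derived from wavelet approximation coefficients (the slice axis is never
    down-sampled; the wavelet transform is 2-D per slice).
    """

    labels: np.ndarray
    domain_tag: str = "spatial"
    scale_factor: int = 1
    #: optional continuous foreground occupancy in [0, 1] per voxel (partial
    #: volume fractions from supersampled geometry); not serialized.
    occupancy: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            lab = np.rint(self.labels).astype(np.int32)
            if not np.allclose(lab, self.labels):
                raise ValueError("labels must be integral")
            self.labels = lab
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3-D, got shape {self.labels.shape}")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        if self.domain_tag not in ("spatial", "wavelet"):
            raise ValueError(f"domain_tag must be 'spatial' or 'wavelet', got {self.domain_tag!r}")
        self.scale_factor = int(self.scale_factor)
        if self.domain_tag == "spatial" and self.scale_factor != 1:
            raise ValueError("spatial-domain labels must have scale_factor 1")
        if self.domain_tag == "wavelet":
            s = self.scale_factor
            if s < 1 or (s & (s - 1)) != 0:
                raise ValueError("wavelet-domain scale_factor must be a power of two")
        if self.occupancy is not None:
            self.occupancy = np.asarray(self.occupancy, dtype=np.float64)
            if self.occupancy.shape != self.labels.shape:
                raise ValueError("occupancy must match the label grid shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def binary(self) -> np.ndarray:
        """Boolean foreground mask (any non-zero class)."""
        return self.labels > 0


def _affine(voxel_size) -> np.ndarray:
    return np.diag(list(voxel_size) + [1.0])


def _is_nifti(path: Path) -> bool:
    return path.name.endswith(".nii") or path.name.endswith(".nii.gz")


def write_volume(volume: PETVolume, path) -> Path:
    """Write a volume as NIfTI-1 or raw+JSON, chosen by file extension."""
    path = Path(path)
    if _is_nifti(path):
        img = nib.Nifti1Image(volume.voxels.astype(np.float32), _affine(volume.voxel_size))
        img.header["descrip"] = volume.description[:79].encode()
        nib.save(img, str(path))
    elif path.suffix == ".raw":
        data = np.ascontiguousarray(volume.voxels, dtype="<f4")
        data.tofile(path)
        sidecar = {
            "shape": list(volume.voxels.shape),
            "voxel_size_mm": list(volume.voxel_size),
            "dtype": "<f4",
            "order": "C",
            "description": volume.description,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    else:
        raise ValueError(f"unsupported volume format for {path.name!r} (use .nii, .nii.gz or .raw)")
    return path


def read_volume(path) -> PETVolume:
    """Read a volume written by :func:`write_volume`.

    Raises ``IOError`` naming the file on missing or truncated input.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"volume file not found: {path}")
    if _is_nifti(path):
        img = nib.load(str(path))
        vox = np.asarray(img.dataobj, dtype=np.float64)
        if vox.ndim != 3:
            raise IOError(f"{path}: expected a 3-D volume, got {vox.ndim} dimensions")
        zooms = img.header.get_zooms()[:3]
        descrip = bytes(img.header["descrip"].tobytes()).split(b"\x00")[0].decode(errors="replace")
        return PETVolume(vox, tuple(float(z) for z in zooms), descrip)
    if path.suffix == ".raw":
        sidecar_path = path.with_suffix(".json")
        if not sidecar_path.exists():
            raise IOError(f"raw volume {path} has no JSON sidecar {sidecar_path.name}")
        meta = json.loads(sidecar_path.read_text())
        shape = tuple(int(s) for s in meta["shape"])
        dtype = np.dtype(meta["dtype"])
        expected = int(np.prod(shape)) * dtype.itemsize
        actual = path.stat().st_size
        if actual != expected:
            raise IOError(f"{path}: expected {expected} bytes for shape {shape}, found {actual}")
        vox = np.fromfile(path, dtype=dtype).reshape(shape, order=meta.get("order", "C"))
        return PETVolume(vox.astype(np.float64), tuple(meta["voxel_size_mm"]),
                         meta.get("description", ""))
    raise IOError(f"unsupported volume format: {path.name!r}")


def write_labels(labels: LabelVolume, path) -> Path:
    """Write a label map as an integer-typed NIfTI-1 file.

    The domain tag and scale factor are stored in the header description so
    that wavelet-domain maps keep their physical meaning on disk.
    """
    path = Path(path)
    if not _is_nifti(path):
        raise ValueError("label maps are written as NIfTI (.nii/.nii.gz)")
    img = nib.Nifti1Image(labels.labels.astype(np.int16), np.eye(4))
    img.header["descrip"] = f"{labels.domain_tag}:{labels.scale_factor}".encode()
    nib.save(img, str(path))
    return path


def read_labels(path) -> LabelVolume:
    path = Path(path)
    if not path.exists():
        raise IOError(f"label file not found: {path}")
    img = nib.load(str(path))
    lab = np.asarray(img.dataobj).astype(np.int32)
    descrip = bytes(img.header["descrip"].tobytes()).split(b"\x00")[0].decode(errors="replace")
    tag, scale = "spatial", 1
    if ":" in descrip:
        tag, scale_s = descrip.split(":", 1)
        scale = int(scale_s)
    return LabelVolume(lab, tag, scale)
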