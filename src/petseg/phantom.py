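"""Synthetic PET phantoms with known ground truth.

Two families of phantoms are generated:

* a NEMA IEC image-quality body phantom: six hot spheres (inner diameters
  10-37 mm) suspended in a warm elliptical background, on a 168x168x66 grid
  of 4.07 x 4.07 x 5 mm voxels;
* a lung phantom: 128x128 slices with a body ellipse, two cooler lung
  ellipses, and small hot tumours of 2-3 voxels at known slice positions
  (slice 68: 2 voxels, slice 57: 3 voxels, slice 74: 2 voxels).

Each generator returns the degraded intensity volume (Gaussian blur of
configurable FWHM emulating scanner resolution, plus additive Gaussian
noise) together with the unblurred ground-truth label map, so every
downstream segmentation and quantification stage can be validated without
scanner data.  Identical specs (including the seed) produce bit-identical
volumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter, label as cc_label

from .volume_io import LabelVolume, PETVolume

__all__ = [
    "SphereSpec",
    "TumourSpec",
    "PhantomSpec",
    "true_sphere_volume",
    "rasterize_sphere",
    "sphere_occupancy",
    "generate_nema",
    "generate_lung",
    "nema_default_spec",
    "lung_default_spec",
    "NEMA_SPHERE_DIAMETERS_MM",
]

#: Inner diameters of the six NEMA IEC spheres, largest first (sphere 1..6).
NEMA_SPHERE_DIAMETERS_MM = (37.0, 28.0, 22.0, 17.0, 13.0, 10.0)

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # sigma = fwhm / 2.3548


def true_sphere_volume(diameter_mm: float) -> float:
    """Analytic sphere volume in ml, (4/3)*pi*(d/2)**3 with d in mm."""
    if diameter_mm <= 0:
        raise ValueError(f"sphere diameter must be positive, got {diameter_mm}")
    return (4.0 / 3.0) * math.pi * (diameter_mm / 2.0) ** 3 / 1000.0


@dataclass
class SphereSpec:
    """A hot sphere: centre in mm (grid coordinates), inner diameter, activity."""

    center: tuple[float, float, float]
    inner_diameter: float
    activity: float = 8.0

    def __post_init__(self) -> None:
        if self.inner_diameter <= 0:
            raise ValueError("inner_diameter must be positive")
        if self.activity < 0:
            raise ValueError("activity must be non-negative")


@dataclass
class TumourSpec:
    """A small lung tumour: axial slice, voxel count (1-10), activity.

    The voxels are laid out as one 4-connected in-plane run starting at
    ``position`` (row, col); ``None`` places the tumour at the generator's
    default in-lung location, straddling a 2x2 block boundary so the lesion
    occupies as many wavelet cells as it has voxels.
    """

    slice_index: int
    voxel_count: int
    activity: float = 8.0
    position: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.voxel_count <= 10:
            raise ValueError("voxel_count must be between 1 and 10")
        if self.slice_index < 0:
            raise ValueError("slice_index must be non-negative")


@dataclass
class PhantomSpec:
    """Full phantom description; identical specs generate identical volumes."""

    grid_shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    background_activity: float = 1.0
    spheres: list[SphereSpec] = field(default_factory=list)
    tumours: list[TumourSpec] = field(default_factory=list)
    blur_fwhm: float = 5.0
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) <= 0 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be three positive ints, got {self.grid_shape}")
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be three positive mm values, got {self.voxel_size}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.blur_fwhm < 0:
            raise ValueError("blur_fwhm must be non-negative")
        if self.background_activity < 0:
            raise ValueError("background_activity must be non-negative")

    # -- config round-trip -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        d["spheres"] = [SphereSpec(**{**s, "center": tuple(s["center"])})
                        for s in d.get("spheres", [])]
        d["tumours"] = [
            TumourSpec(**{**t, "position": tuple(t["position"]) if t.get("position") else None})
            for t in d.get("tumours", [])
        ]
        for key in ("grid_shape", "voxel_size"):
            d[key] = tuple(d[key])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "PhantomSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _voxel_centers(n: int, d: float) -> np.ndarray:
    return (np.arange(n) + 0.5) * d


def rasterize_sphere(spec: SphereSpec, grid: PhantomSpec) -> np.ndarray:
    """Boolean mask of voxels whose centre lies inside the sphere.

    Partial-volume fractions are modelled only through the downstream
    Gaussian blur; the mask itself is the ground-truth label.
    """
    nx, ny, nz = grid.grid_shape
    dx, dy, dz = grid.voxel_size
    cx, cy, cz = spec.center
    r = spec.inner_diameter / 2.0
    if (cx - r < 0 or cy - r < 0 or cz - r < 0
            or cx + r > nx * dx or cy + r > ny * dy or cz + r > nz * dz):
        raise ValueError(f"sphere at {spec.center} (d={spec.inner_diameter} mm) "
                         "extends outside the grid")
    # bounding box keeps the distance computation local
    ix = np.flatnonzero(np.abs(_voxel_centers(nx, dx) - cx) <= r + dx)
    iy = np.flatnonzero(np.abs(_voxel_centers(ny, dy) - cy) <= r + dy)
    iz = np.flatnonzero(np.abs(_voxel_centers(nz, dz) - cz) <= r + dz)
    mask = np.zeros((nx, ny, nz), dtype=bool)
    if ix.size == 0 or iy.size == 0 or iz.size == 0:
        return mask
    X = (_voxel_centers(nx, dx)[ix] - cx)[:, None, None]
    Y = (_voxel_centers(ny, dy)[iy] - cy)[None, :, None]
    Z = (_voxel_centers(nz, dz)[iz] - cz)[None, None, :]
    inside = X ** 2 + Y ** 2 + Z ** 2 <= r ** 2
    mask[np.ix_(ix, iy, iz)] = inside
    return mask


def sphere_occupancy(spec: SphereSpec, grid: PhantomSpec,
                     supersample: int = 4) -> np.ndarray:
    """Fraction of each voxel's volume inside the sphere (antialiased).

    Each voxel is sampled on a ``supersample**3`` subgrid; the returned
    float array integrates (x voxel volume) to the analytic sphere volume to
    well under 1%, which makes it the right rendering weight for continuous
    activity and the right target for partial-volume-aware occupancy
    regression.  The binary ground-truth mask remains
    :func:`rasterize_sphere`'s centre-in-sphere rule.
    """
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    nx, ny, nz = grid.grid_shape
    dx, dy, dz = grid.voxel_size
    cx, cy, cz = spec.center
    r = spec.inner_diameter / 2.0
    occ = np.zeros(grid.grid_shape, dtype=np.float64)
    ix = np.flatnonzero(np.abs(_voxel_centers(nx, dx) - cx) <= r + dx)
    iy = np.flatnonzero(np.abs(_voxel_centers(ny, dy) - cy) <= r + dy)
    iz = np.flatnonzero(np.abs(_voxel_centers(nz, dz) - cz) <= r + dz)
    if ix.size == 0 or iy.size == 0 or iz.size == 0:
        return occ
    # subvoxel sample offsets, centred within the voxel
    sub = (np.arange(supersample) + 0.5) / supersample - 0.5
    X = (_voxel_centers(nx, dx)[ix][:, None] + sub[None, :] * dx - cx).ravel()
    Y = (_voxel_centers(ny, dy)[iy][:, None] + sub[None, :] * dy - cy).ravel()
    Z = (_voxel_centers(nz, dz)[iz][:, None] + sub[None, :] * dz - cz).ravel()
    inside = (X[:, None, None] ** 2 + Y[None, :, None] ** 2 + Z[None, None, :] ** 2
              <= r ** 2)
    s = supersample
    frac = inside.reshape(ix.size, s, iy.size, s, iz.size, s).mean(axis=(1, 3, 5))
    occ[np.ix_(ix, iy, iz)] = frac
    return occ


def _ellipse_mask(nx: int, ny: int, dx: float, dy: float,
                  center_mm: tuple[float, float], semi_axes_mm: tuple[float, float]) -> np.ndarray:
    X = (_voxel_centers(nx, dx) - center_mm[0])[:, None]
    Y = (_voxel_centers(ny, dy) - center_mm[1])[None, :]
    a, b = semi_axes_mm
    return (X / a) ** 2 + (Y / b) ** 2 <= 1.0


def _degrade(activity: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Apply resolution blur and additive Gaussian noise (seeded)."""
    out = activity
    if spec.blur_fwhm > 0:
        sigma_vox = [spec.blur_fwhm / _FWHM_TO_SIGMA / d for d in spec.voxel_size]
        out = gaussian_filter(out, sigma=sigma_vox, mode="reflect")
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        out = out + rng.normal(0.0, spec.noise_sigma * spec.background_activity, out.shape)
        out = np.clip(out, 0.0, None)
    return out


def nema_default_spec(seed: int = 0, noise_sigma: float = 0.05,
                      blur_fwhm: float = 5.0) -> PhantomSpec:
    """NEMA IEC image-quality phantom on the standard 168x168x66 grid.

    The six spheres (diameters 37-10 mm) sit at 60-degree intervals on a
    ring of radius 57.2 mm in the central axial plane, inside a warm
    elliptical cylinder (semi-axes 150 x 110 mm).  Sphere activity defaults
    to 8x the background.
    """
    grid_shape = (168, 168, 66)
    voxel_size = (4.07, 4.07, 5.0)
    cx = grid_shape[0] * voxel_size[0] / 2.0
    cy = grid_shape[1] * voxel_size[1] / 2.0
    cz = grid_shape[2] * voxel_size[2] / 2.0
    ring_radius = 57.2
    spheres = []
    for i, d in enumerate(NEMA_SPHERE_DIAMETERS_MM):
        theta = math.radians(60.0 * i)
        spheres.append(SphereSpec(
            center=(cx + ring_radius * math.cos(theta),
                    cy + ring_radius * math.sin(theta), cz),
            inner_diameter=d, activity=8.0))
    return PhantomSpec(grid_shape=grid_shape, voxel_size=voxel_size,
                       background_activity=1.0, spheres=spheres,
                       blur_fwhm=blur_fwhm, noise_sigma=noise_sigma, seed=seed)


def generate_nema(spec: PhantomSpec, supersample: int = 4) -> tuple[PETVolume, LabelVolume]:
    """Render a NEMA-like phantom volume and its ground-truth labels.

    Activity is rendered with antialiased sphere edges (the tracer
    distribution is continuous; boundary voxels take partial values before
    the blur), then degraded.  The returned label map marks sphere ``i``
    (spec order) with label ``i+1`` on the centre-in-sphere mask, and its
    ``occupancy`` field carries the continuous foreground fractions used
    for partial-volume-aware quantification targets.
    """
    if not spec.spheres:
        raise ValueError("NEMA spec must contain at least one sphere")
    nx, ny, nz = spec.grid_shape
    dx, dy, dz = spec.voxel_size
    body = _ellipse_mask(nx, ny, dx, dy,
                         (nx * dx / 2.0, ny * dy / 2.0),
                         (0.44 * nx * dx, 0.33 * ny * dy))
    activity = np.where(body[:, :, None], spec.background_activity, 0.0).astype(np.float64)
    activity = np.broadcast_to(activity, (nx, ny, nz)).copy()
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    occupancy = np.zeros(spec.grid_shape, dtype=np.float64)
    for i, sphere in enumerate(spec.spheres):
        mask = rasterize_sphere(sphere, spec)
        occ = sphere_occupancy(sphere, spec, supersample=supersample)
        activity += (sphere.activity - spec.background_activity) * occ
        occupancy = np.maximum(occupancy, occ)
        labels[mask] = i + 1
    voxels = _degrade(activity, spec)
    vol = PETVolume(voxels, spec.voxel_size, "synthetic NEMA IQ phantom")
    return vol, LabelVolume(labels, "spatial", 1, occupancy=occupancy)


_LUNG_DEFAULT_POSITIONS = {
    # (row, col) of the first tumour voxel; runs extend along the column axis
    # and straddle an even column boundary so an n-voxel lesion occupies n
    # distinct 2x2 wavelet cells.
    68: (64, 83),
    57: (70, 83),
    74: (60, 83),
}


def lung_default_spec(seed: int = 0, noise_sigma: float = 0.05,
                      blur_fwhm: float = 5.0, nz: int = 180) -> PhantomSpec:
    """Lung phantom: 128x128xnz grid with 3 small tumours.

    Tumour 1 (2 voxels) at slice 68, tumour 2 (3 voxels) at slice 57 and
    tumour 3 (2 voxels) at slice 74, all at 8x background activity.
    """
    tumours = [TumourSpec(68, 2), TumourSpec(57, 3), TumourSpec(74, 2)]
    tumours = [t for t in tumours if t.slice_index < nz]
    return PhantomSpec(grid_shape=(128, 128, nz), voxel_size=(5.0625, 5.0625, 2.425),
                       background_activity=1.0, tumours=tumours,
                       blur_fwhm=blur_fwhm, noise_sigma=noise_sigma, seed=seed)


def _tumour_voxels(t: TumourSpec, nx: int, ny: int) -> list[tuple[int, int]]:
    if t.position is not None:
        row, col = t.position
    else:
        row, col = _LUNG_DEFAULT_POSITIONS.get(t.slice_index, (ny // 2, nx // 2 + 19))
    coords = [(row, col + k) for k in range(t.voxel_count)]
    for r, c in coords:
        if not (0 <= r < ny and 0 <= c < nx):
            raise ValueError(f"tumour at slice {t.slice_index} extends outside the slice")
    return coords


def generate_lung(spec: PhantomSpec) -> tuple[PETVolume, LabelVolume]:
    """Render a lung phantom volume and its ground-truth labels.

    The background is a warm body ellipse containing two cooler lung
    ellipses; tumours are in-plane runs of hot voxels at the specified
    slices.  Tumour ``i`` (spec order) carries label ``i+1``.
    """
    nx, ny, nz = spec.grid_shape
    dx, dy, dz = spec.voxel_size
    cx, cy = nx * dx / 2.0, ny * dy / 2.0
    body = _ellipse_mask(nx, ny, dx, dy, (cx, cy), (0.45 * nx * dx, 0.40 * ny * dy))
    lungs = (_ellipse_mask(nx, ny, dx, dy, (cx - 0.17 * nx * dx, cy), (0.13 * nx * dx, 0.22 * ny * dy))
             | _ellipse_mask(nx, ny, dx, dy, (cx + 0.17 * nx * dx, cy), (0.13 * nx * dx, 0.22 * ny * dy)))
    slice_activity = np.where(body, spec.background_activity, 0.0)
    slice_activity[lungs] = 0.4 * spec.background_activity
    activity = np.repeat(slice_activity[:, :, None], nz, axis=2)
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    for i, t in enumerate(spec.tumours):
        if t.slice_index >= nz:
            raise ValueError(f"tumour slice {t.slice_index} outside grid of {nz} slices")
        for r, c in _tumour_voxels(t, nx, ny):
            activity[c, r, t.slice_index] = t.activity
            labels[c, r, t.slice_index] = i + 1
        # connectivity sanity check on the placed voxels
        sl = (labels[:, :, t.slice_index] == i + 1).astype(np.int8)
        n_comp = cc_label(sl)[1]
        if n_comp != 1:
            raise ValueError(f"tumour {i + 1} voxels are not one connected component")
    voxels = _degrade(activity, spec)
    vol = PETVolume(voxels, spec.voxel_size, "synthetic lung phantom")
    return vol, LabelVolume(labels, "spatial", 1)
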