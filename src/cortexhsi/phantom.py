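"""Voxelized two-medium exposed-cortex phantom built from a binary vessel mask.

Geometry convention: right-handed, origin at the slab top-center, z increasing
downward into tissue (top surface z = 0).  The slab is 2.4 × 2.4 × 1.0 mm; the
imaged field of view is the central 1.2 × 1.2 mm of the top surface, with the
extra margin minimizing lateral boundary effects.  Pial vessels live in the
top ``vessel_layer_thickness`` (0.1 mm) of the slab, inside the FOV footprint;
everything else in the slab is subpial gray matter.

The in-plane vessel pattern comes either from a procedurally generated mask
(random-walk centerlines of a ~100 μm major and ~20 μm minor calibre,
standing in for a manually segmented in vivo image) or from a user-supplied
single-channel PNG/TIFF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "OUTSIDE",
    "GRAY_MATTER",
    "VESSEL",
    "VesselMask",
    "CortexPhantom",
    "generate_vessel_mask",
    "read_mask_image",
    "downsample_mask",
    "extrude_vasculature",
    "build_phantom",
    "make_default_phantom",
]

OUTSIDE = 0
GRAY_MATTER = 1
VESSEL = 2


@dataclass(frozen=True)
class VesselMask:
    """Binary in-plane vessel pattern.

    ``pixels[row, col]`` is True on vessels; row maps to y, col to x, with the
    mask centered on the FOV.  ``pixel_pitch`` is the pixel size in mm.
    """

    pixels: np.ndarray
    pixel_pitch: float = 0.003
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("mask must be a 2-D array")
        if px.dtype != bool:
            uniq = np.unique(px)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be strictly binary")
            object.__setattr__(self, "pixels", px.astype(bool))
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be > 0")

    @property
    def fov_size(self) -> tuple[float, float]:
        """(x, y) extent of the mask in mm."""
        ny, nx = self.pixels.shape
        return (nx * self.pixel_pitch, ny * self.pixel_pitch)

    @property
    def vessel_fraction(self) -> float:
        return float(self.pixels.mean())

    def require_two_phases(self) -> None:
        if not self.pixels.any():
            raise ValueError("mask has no vessel pixels; imaging studies need both phases")
        if self.pixels.all():
            raise ValueError("mask has no background pixels; imaging studies need both phases")


def _rasterize_centerline(shape: tuple[int, int], points: np.ndarray) -> np.ndarray:
    """Mark mask pixels touched by a polyline given in (row, col) float coords."""
    grid = np.zeros(shape, dtype=bool)
    for (r0, c0), (r1, c1) in zip(points[:-1], points[1:]):
        n = int(max(abs(r1 - r0), abs(c1 - c0), 1)) * 2 + 1
        rr = np.linspace(r0, r1, n)
        cc = np.linspace(c0, c1, n)
        ri = np.clip(np.round(rr).astype(int), 0, shape[0] - 1)
        ci = np.clip(np.round(cc).astype(int), 0, shape[1] - 1)
        grid[ri, ci] = True
    return grid


def _random_walk_centerline(rng: np.random.Generator, shape: tuple[int, int],
                            tortuosity: float) -> np.ndarray:
    """Curvilinear centerline crossing the full mask, as (row, col) points."""
    ny, nx = shape
    vertical = rng.random() < 0.5
    span = ny if vertical else nx
    lateral = nx if vertical else ny
    step = max(span / 200.0, 1.0)
    pos = rng.uniform(0.25, 0.75) * lateral
    drift = 0.0
    pts = []
    s = 0.0
    while s <= span - 1:
        pts.append((s, pos) if vertical else (pos, s))
        drift += rng.normal(0.0, tortuosity)
        drift = float(np.clip(drift, -1.5, 1.5))
        pos = float(np.clip(pos + drift * step, 0, lateral - 1))
        s += step
    pts.append((span - 1, pos) if vertical else (pos, span - 1))
    return np.asarray(pts)


def generate_vessel_mask(n_major: int = 1, n_minor: int = 1,
                         shape: tuple[int, int] = (400, 400),
                         pixel_pitch: float = 0.003,
                         major_width_mm: float = 0.1,
                         minor_width_mm: float = 0.02,
                         tortuosity: float = 0.25,
                         seed: int = 0) -> VesselMask:
    """Procedural binary vessel mask with major (~100 μm) and minor (~20 μm) vessels.

    Each vessel is a random-walk centerline crossing the field of view,
    rasterized to the requested width by thresholding the distance transform
    of the centerline.  Identical seed and parameters give identical masks.
    """
    for w in (major_width_mm, minor_width_mm):
        if w <= 0 or w >= min(shape) * pixel_pitch:
            raise ValueError("vessel widths must be positive and smaller than the FOV")
        if w < pixel_pitch:
            raise ValueError(
                f"vessel width {w} mm is below one pixel pitch "
                f"({pixel_pitch} mm); use a finer grid"
            )
    rng = np.random.default_rng(seed)
    mask = np.zeros(shape, dtype=bool)
    for width, count in ((major_width_mm, n_major), (minor_width_mm, n_minor)):
        for _ in range(count):
            center = _rasterize_centerline(shape, _random_walk_centerline(rng, shape, tortuosity))
            dist = ndimage.distance_transform_edt(~center) * pixel_pitch
            mask |= dist <= width / 2.0
    params = dict(n_major=n_major, n_minor=n_minor, major_width_mm=major_width_mm,
                  minor_width_mm=minor_width_mm, tortuosity=tortuosity)
    return VesselMask(mask, pixel_pitch, seed=seed, params=params)


def read_mask_image(path, pixel_pitch: float = 0.003,
                    threshold: float | None = None) -> VesselMask:
    """Read a single-channel PNG/TIFF as a vessel mask (nonzero → vessel)."""
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        if img.shape[2] == 1:
            img = img[..., 0]
        else:
            raise ValueError("multi-channel image; supply a single-channel mask")
    if img.ndim != 2:
        raise ValueError("mask image must be 2-D")
    uniq = np.unique(img)
    if threshold is None:
        if uniq.size > 2:
            raise ValueError("non-binary image; supply a threshold")
        pixels = img > 0
    else:
        pixels = img > threshold
    return VesselMask(pixels, pixel_pitch, params={"source": str(path)})


def write_mask_image(mask: VesselMask, path) -> None:
    """Write a mask as an 8-bit PNG/TIFF plus a plain-text provenance sidecar."""
    import imageio.v3 as iio

    path = Path(path)
    iio.imwrite(path, (mask.pixels.astype(np.uint8) * 255))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(
        {"seed": mask.seed, "pixel_pitch_mm": mask.pixel_pitch, "params": mask.params},
        indent=2))


def downsample_mask(mask: VesselMask, pitch: float) -> VesselMask:
    """Resample a mask onto a coarser grid by majority rule (ties → vessel)."""
    if pitch < mask.pixel_pitch:
        raise ValueError("target pitch must not be finer than the mask pitch")
    fx, fy = mask.fov_size
    nx = int(round(fx / pitch))
    ny = int(round(fy / pitch))
    ny0, nx0 = mask.pixels.shape
    # map each fine pixel center to a coarse cell and count votes
    rows = np.minimum(((np.arange(ny0) + 0.5) * mask.pixel_pitch / pitch).astype(int), ny - 1)
    cols = np.minimum(((np.arange(nx0) + 0.5) * mask.pixel_pitch / pitch).astype(int), nx - 1)
    votes = np.zeros((ny, nx))
    total = np.zeros((ny, nx))
    np.add.at(votes, (rows[:, None], cols[None, :]), mask.pixels.astype(float))
    np.add.at(total, (rows[:, None], cols[None, :]), 1.0)
    coarse = votes * 2 >= total
    return VesselMask(coarse, pitch, seed=mask.seed,
                      params={**mask.params, "downsampled_from_mm": mask.pixel_pitch})


def extrude_vasculature(mask: VesselMask, thickness: float,
                        voxel_size: float) -> np.ndarray:
    """Extrude a mask into a 3-D binary vessel volume with a lens-like profile.

    The cross-section is widest at the mid-plane of the vessel layer and
    shrinks symmetrically toward its top and bottom faces: at signed depth dz
    from the mid-plane the mask is eroded by the circular-segment inset
    e(dz) = h − sqrt(h² − dz²), h = thickness/2, which reproduces the rounded
    profile of a vessel whose calibre matches the layer thickness.

    Returns a boolean array indexed ``[row, col, layer]`` with
    ``round(thickness / voxel_size)`` layers; the mask must already be at the
    voxel pitch of the target phantom.
    """
    if thickness <= 0:
        raise ValueError("thickness must be > 0")
    n_layers = int(round(thickness / voxel_size))
    if n_layers < 2:
        raise ValueError("thickness must span at least 2 voxel layers")
    ny, nx = mask.pixels.shape
    volume = np.zeros((ny, nx, n_layers), dtype=bool)
    if not mask.pixels.any():
        return volume
    dist_mm = ndimage.distance_transform_edt(mask.pixels) * mask.pixel_pitch
    h = thickness / 2.0
    z_centers = (np.arange(n_layers) + 0.5) * voxel_size
    for k, zc in enumerate(z_centers):
        dz = min(abs(zc - h), h)
        erosion = h - np.sqrt(max(h * h - dz * dz, 0.0))
        volume[:, :, k] = dist_mm > erosion
    return volume


@dataclass(frozen=True)
class CortexPhantom:
    """Labeled voxel volume of the exposed-cortex slab.

    ``labels[ix, iy, iz]`` covers x, y ∈ [−extent/2, extent/2] and
    z ∈ [0, depth] in half-open voxel intervals, 0-based indices; values are
    GRAY_MATTER or VESSEL (coordinates beyond the array are OUTSIDE).
    """

    labels: np.ndarray
    voxel_size: float
    extent: tuple[float, float, float] = (2.4, 2.4, 1.0)
    fov_size: tuple[float, float] = (1.2, 1.2)
    vessel_layer_thickness: float = 0.1
    mask: VesselMask | None = None

    def __post_init__(self) -> None:
        expected = tuple(int(round(e / self.voxel_size)) for e in self.extent)
        if self.labels.shape != expected:
            raise ValueError(
                f"label volume {self.labels.shape} does not match extent "
                f"{self.extent} at voxel size {self.voxel_size}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def vessel_layer_voxels(self) -> int:
        return int(round(self.vessel_layer_thickness / self.voxel_size))

    def vessel_layer(self) -> np.ndarray:
        """uint8 view of the top vessel layer (1 = vessel), indexed [ix, iy, iz]."""
        nz = self.vessel_layer_voxels
        return (self.labels[:, :, :nz] == VESSEL).astype(np.uint8)

    def vessel_voxel_count(self) -> int:
        return int((self.labels == VESSEL).sum())

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("labels", data=self.labels, compression="gzip")
            f.attrs["voxel_size_mm"] = self.voxel_size
            f.attrs["extent_mm"] = self.extent
            f.attrs["fov_size_mm"] = self.fov_size
            f.attrs["vessel_layer_thickness_mm"] = self.vessel_layer_thickness

    @classmethod
    def from_hdf5(cls, path) -> "CortexPhantom":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                labels=f["labels"][...],
                voxel_size=float(f.attrs["voxel_size_mm"]),
                extent=tuple(f.attrs["extent_mm"]),
                fov_size=tuple(f.attrs["fov_size_mm"]),
                vessel_layer_thickness=float(f.attrs["vessel_layer_thickness_mm"]),
            )


def build_phantom(volume: np.ndarray, voxel_size: float = 0.01,
                  slab_extent: tuple[float, float, float] = (2.4, 2.4, 1.0),
                  fov_size: tuple[float, float] = (1.2, 1.2),
                  mask: VesselMask | None = None) -> CortexPhantom:
    """Embed an extruded vessel volume in the gray-matter slab.

    The vessel volume (indexed [row, col, layer], at the slab's voxel pitch)
    is centered in the top layer of the slab; every other slab voxel is gray
    matter.  Vessel voxel counts are conserved.
    """
    shape = []
    for e in slab_extent:
        n = e / voxel_size
        if abs(n - round(n)) > 1e-6:
            raise ValueError(f"voxel size {voxel_size} does not divide extent {e}")
        shape.append(int(round(n)))
    nx, ny, nz = shape
    vol = np.asarray(volume, dtype=bool)
    vy, vx, vz = vol.shape
    if vx > nx or vy > ny or vz > nz:
        raise ValueError("vessel volume does not fit within the slab")
    fov_nx = int(round(fov_size[0] / voxel_size))
    fov_ny = int(round(fov_size[1] / voxel_size))
    if vx > fov_nx or vy > fov_ny:
        raise ValueError("vessel volume footprint exceeds the central FOV")
    labels = np.full((nx, ny, nz), GRAY_MATTER, dtype=np.uint8)
    x0 = (nx - vx) // 2
    y0 = (ny - vy) // 2
    # volume is [row=y, col=x, layer=z]; labels are [x, y, z]
    labels[x0:x0 + vx, y0:y0 + vy, :vz][vol.transpose(1, 0, 2)] = VESSEL
    thickness = vz * voxel_size
    return CortexPhantom(labels, voxel_size, tuple(slab_extent), tuple(fov_size),
                         vessel_layer_thickness=thickness, mask=mask)


def make_default_phantom(seed: int = 0, voxel_size: float = 0.01,
                         n_major: int = 1, n_minor: int = 1,
                         **mask_kwargs) -> CortexPhantom:
    """Full pipeline: procedural mask → downsample → extrude → slab."""
    mask = generate_vessel_mask(n_major=n_major, n_minor=n_minor, seed=seed,
                                **mask_kwargs)
    mask.require_two_phases()
    coarse = downsample_mask(mask, voxel_size)
    volume = extrude_vasculature(coarse, thickness=0.1, voxel_size=voxel_size)
    return build_phantom(volume, voxel_size=voxel_size, mask=mask)
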