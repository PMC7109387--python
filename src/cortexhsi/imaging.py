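"""Detector binning and hypercube assembly.

Detected photons are binned by their continuous exit position into the
detector's pixel grid (185×185 by default, 6.5 μm pixels over a 1.2×1.2 mm
FOV; 1.08 μm pixels in the localized 0.2×0.2 mm configuration).  Per pixel,
the intensity map sums the residual photon weights; the pathlength maps hold
the weight-weighted mean of the total and per-medium partial pathlengths.
Empty pixels carry NaN and are excluded downstream rather than zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .transport import PhotonRecordSet

__all__ = [
    "DetectorConfig",
    "IntensityMap",
    "PathlengthMaps",
    "Hypercube",
    "bin_detections",
    "pathlength_maps",
    "assemble_hypercube",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Pixelated detector FOV on the top surface of the slab.

    Pixel (k, l) = (row, column) is 0-based internally, with the origin at
    the FOV corner of minimum x, y; rows map to y, columns to x.
    """

    fov_size: tuple[float, float] = (1.2, 1.2)
    fov_center_xy: tuple[float, float] = (0.0, 0.0)
    n_pixels: tuple[int, int] = (185, 185)

    def __post_init__(self) -> None:
        if self.fov_size[0] <= 0 or self.fov_size[1] <= 0:
            raise ValueError("FOV size must be positive")
        if self.n_pixels[0] <= 0 or self.n_pixels[1] <= 0:
            raise ValueError("pixel counts must be positive")

    @property
    def pixel_pitch(self) -> tuple[float, float]:
        return (self.fov_size[0] / self.n_pixels[1], self.fov_size[1] / self.n_pixels[0])

    @property
    def origin_xy(self) -> tuple[float, float]:
        return (self.fov_center_xy[0] - self.fov_size[0] / 2.0,
                self.fov_center_xy[1] - self.fov_size[1] / 2.0)

    def pixel_indices(self, x: np.ndarray, y: np.ndarray):
        """(rows, cols, inside) for exit positions; half-open cells, max edge out."""
        ox, oy = self.origin_xy
        pw, ph = self.pixel_pitch
        cols = np.floor((np.asarray(x) - ox) / pw).astype(np.int64)
        rows = np.floor((np.asarray(y) - oy) / ph).astype(np.int64)
        inside = ((cols >= 0) & (cols < self.n_pixels[1])
                  & (rows >= 0) & (rows < self.n_pixels[0]))
        return rows, cols, inside


@dataclass
class IntensityMap:
    intensity: np.ndarray
    n_detected: np.ndarray
    wavelength: float
    dropped_outside: int = 0

    @property
    def total_weight(self) -> float:
        return float(self.intensity.sum())


@dataclass
class PathlengthMaps:
    """Weight-weighted mean pathlengths per pixel (mm); NaN where no photons."""

    pl_total: np.ndarray
    pl_vessel: np.ndarray
    pl_gray: np.ndarray
    n_detected: np.ndarray
    wavelength: float


def bin_detections(records: PhotonRecordSet, det: DetectorConfig) -> IntensityMap:
    """Sum detected-photon weights into detector pixels."""
    rows, cols, inside = det.pixel_indices(records.exit_x, records.exit_y)
    intensity = np.zeros(det.n_pixels)
    counts = np.zeros(det.n_pixels, dtype=np.int64)
    np.add.at(intensity, (rows[inside], cols[inside]), records.weight[inside])
    np.add.at(counts, (rows[inside], cols[inside]), 1)
    return IntensityMap(intensity, counts, records.wavelength,
                        dropped_outside=int((~inside).sum()))


def pathlength_maps(records: PhotonRecordSet, det: DetectorConfig) -> PathlengthMaps:
    """Per-pixel weight-weighted mean total and partial pathlengths."""
    rows, cols, inside = det.pixel_indices(records.exit_x, records.exit_y)
    r, c = rows[inside], cols[inside]
    w = records.weight[inside]
    wsum = np.zeros(det.n_pixels)
    counts = np.zeros(det.n_pixels, dtype=np.int64)
    np.add.at(wsum, (r, c), w)
    np.add.at(counts, (r, c), 1)
    maps = []
    for path in (records.path_vessel[inside] + records.path_gray[inside],
                 records.path_vessel[inside], records.path_gray[inside]):
        acc = np.zeros(det.n_pixels)
        np.add.at(acc, (r, c), w * path)
        with np.errstate(invalid="ignore", divide="ignore"):
            maps.append(np.where(wsum > 0, acc / wsum, np.nan))
    return PathlengthMaps(maps[0], maps[1], maps[2], counts, records.wavelength)


@dataclass
class Hypercube:
    """Per-wavelength stack of intensity and pathlength maps.

    Arrays are (M, rows, cols) with M the number of wavelengths; pathlength
    entries are NaN in pixels that detected no photons.
    """

    wavelengths: np.ndarray
    intensity: np.ndarray
    pl_total: np.ndarray
    pl_vessel: np.ndarray
    pl_gray: np.ndarray
    n_detected: np.ndarray
    condition: str = ""
    detector: DetectorConfig | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = len(self.wavelengths)
        for name in ("intensity", "pl_total", "pl_vessel", "pl_gray", "n_detected"):
            arr = getattr(self, name)
            if arr.shape[0] != m:
                raise ValueError(f"{name} depth {arr.shape[0]} != wavelength count {m}")

    @property
    def n_wavelengths(self) -> int:
        return len(self.wavelengths)

    def index_of(self, wavelength: float) -> int:
        idx = np.flatnonzero(np.isclose(self.wavelengths, wavelength))
        if idx.size == 0:
            raise KeyError(f"wavelength {wavelength} nm not in hypercube")
        return int(idx[0])

    def subset(self, wavelengths) -> "Hypercube":
        """Hypercube restricted to a subset of its wavelengths."""
        idx = [self.index_of(w) for w in np.atleast_1d(wavelengths)]
        return Hypercube(
            wavelengths=self.wavelengths[idx],
            intensity=self.intensity[idx],
            pl_total=self.pl_total[idx],
            pl_vessel=self.pl_vessel[idx],
            pl_gray=self.pl_gray[idx],
            n_detected=self.n_detected[idx],
            condition=self.condition,
            detector=self.detector,
            meta=dict(self.meta),
        )

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for name in ("wavelengths", "intensity", "pl_total", "pl_vessel",
                         "pl_gray", "n_detected"):
                f.create_dataset(name, data=getattr(self, name), compression="gzip")
            f.attrs["condition"] = self.condition
            if self.detector is not None:
                f.attrs["fov_size_mm"] = self.detector.fov_size
                f.attrs["fov_center_mm"] = self.detector.fov_center_xy
                f.attrs["n_pixels"] = self.detector.n_pixels
            for k, v in self.meta.items():
                f.attrs[str(k)] = v

    @classmethod
    def from_hdf5(cls, path) -> "Hypercube":
        import h5py

        with h5py.File(path, "r") as f:
            det = None
            if "fov_size_mm" in f.attrs:
                det = DetectorConfig(
                    fov_size=tuple(f.attrs["fov_size_mm"]),
                    fov_center_xy=tuple(f.attrs["fov_center_mm"]),
                    n_pixels=tuple(int(n) for n in f.attrs["n_pixels"]),
                )
            return cls(
                wavelengths=f["wavelengths"][...],
                intensity=f["intensity"][...],
                pl_total=f["pl_total"][...],
                pl_vessel=f["pl_vessel"][...],
                pl_gray=f["pl_gray"][...],
                n_detected=f["n_detected"][...],
                condition=str(f.attrs.get("condition", "")),
                detector=det,
            )

    def write_tiff(self, path, dataset: str = "intensity") -> None:
        """Export one map stack as 32-bit TIFF."""
        import tifffile

        tifffile.imwrite(path, getattr(self, dataset).astype(np.float32))


def assemble_hypercube(maps, condition: str = "",
                       detector: DetectorConfig | None = None,
                       wavelengths=None, meta: dict | None = None) -> Hypercube:
    """Stack per-wavelength (IntensityMap, PathlengthMaps) pairs into a Hypercube.

    ``maps`` is a mapping wavelength → (IntensityMap, PathlengthMaps).  If
    ``wavelengths`` is given, every listed wavelength must be present; a gap
    raises with the missing values named.
    """
    if not maps:
        raise ValueError("no per-wavelength maps supplied")
    avail = sorted(maps)
    if wavelengths is None:
        wavelengths = avail
    else:
        missing = [w for w in wavelengths if w not in maps]
        if missing:
            raise ValueError(f"missing wavelengths in hypercube assembly: {missing}")
    wl = np.asarray(sorted(wavelengths), dtype=float)
    ints, plt, plv, plg, nd = [], [], [], [], []
    for w in wl:
        imap, pmaps = maps[w]
        ints.append(imap.intensity)
        plt.append(pmaps.pl_total)
        plv.append(pmaps.pl_vessel)
        plg.append(pmaps.pl_gray)
        nd.append(imap.n_detected)
    return Hypercube(
        wavelengths=wl,
        intensity=np.stack(ints),
        pl_total=np.stack(plt),
        pl_vessel=np.stack(plv),
        pl_gray=np.stack(plg),
        n_detected=np.stack(nd),
        condition=condition,
        detector=detector,
        meta=meta or {},
    )
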