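"""Weighted-photon Monte Carlo propagation through the phantom at one wavelength.

A wide-field planar source sits 0.5 mm above the tissue surface; photons are
launched so that entry points cover the illuminated section of the top
surface uniformly (matching the wide-field illumination the imaging geometry
assumes) with directions drawn from the source aperture within the beam
divergence cone.  A beam divergence of 90° is modeled as a cone of half-angle
45° about the surface normal.

Partial pathlengths are tallied per medium (pial vessel vs gray matter) for
every detected photon; these drive both the pathlength hypercubes and the
partial-pathlength correction downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .phantom import CortexPhantom
from .spectra import (
    ChromophoreSpectra,
    MediumComposition,
    ScatteringModel,
    TISSUE_G,
    TISSUE_N,
    default_scattering_model,
    load_spectra,
    mua_of_medium,
    mus_of_medium,
)

__all__ = [
    "SourceConfig",
    "PhotonRecordSet",
    "TransportOptions",
    "run_transport",
    "simulate_wavelength",
    "sample_scatter",
    "derive_stream_seed",
]


@dataclass(frozen=True)
class SourceConfig:
    """Planar wide-field source above the tissue surface.

    ``illuminated_size`` is the section of the top surface the photons cover
    uniformly (the detector FOV in all the imaging studies).
    """

    size: tuple[float, float] = (0.6, 0.6)
    center_xy: tuple[float, float] = (0.0, 0.0)
    standoff: float = 0.5
    divergence_half_angle_deg: float = 45.0
    illuminated_size: tuple[float, float] = (1.2, 1.2)
    illuminated_center_xy: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.size[0] <= 0 or self.size[1] <= 0:
            raise ValueError("source size must be positive")
        if self.standoff < 0:
            raise ValueError("standoff must be >= 0")
        if not 0 < self.divergence_half_angle_deg <= 90:
            raise ValueError("divergence half-angle must be in (0, 90] degrees")

    @property
    def cos_min(self) -> float:
        return math.cos(math.radians(self.divergence_half_angle_deg))

    @property
    def illum_center(self) -> tuple[float, float]:
        return self.illuminated_center_xy or self.center_xy


@dataclass(frozen=True)
class TransportOptions:
    roulette_threshold: float = 1e-4
    roulette_survive: float = 0.1
    max_steps: int = 1_000_000
    reflect_walls: bool = False


@dataclass
class PhotonRecordSet:
    """Per-detected-photon exit data for one wavelength.

    ``exit_x/exit_y`` are continuous surface positions in mm, ``weight`` the
    residual packet weight in (0, 1], ``path_vessel``/``path_gray`` the
    partial pathlengths (mm) in each medium.  ``accounting`` maps each photon
    fate to its total weight; detected + absorbed + escaped + specular +
    roulette + step-capped equals the number launched.
    """

    exit_x: np.ndarray
    exit_y: np.ndarray
    weight: np.ndarray
    path_vessel: np.ndarray
    path_gray: np.ndarray
    wavelength: float
    n_launched: int
    seed: int
    accounting: dict = field(default_factory=dict)

    @property
    def n_detected(self) -> int:
        return self.exit_x.size

    @property
    def total_path(self) -> np.ndarray:
        return self.path_vessel + self.path_gray

    def weighted_gray_fraction(self) -> float:
        """Weight-weighted mean gray path over weight-weighted mean total path."""
        wsum = self.weight.sum()
        if wsum == 0:
            return float("nan")
        return float((self.weight * self.path_gray).sum()
                     / (self.weight * self.total_path).sum())

    def to_hdf5(self, path_or_group) -> None:
        import h5py

        def _write(grp):
            for name in ("exit_x", "exit_y", "weight", "path_vessel", "path_gray"):
                grp.create_dataset(name, data=getattr(self, name))
            grp.attrs["wavelength_nm"] = self.wavelength
            grp.attrs["n_launched"] = self.n_launched
            grp.attrs["seed"] = self.seed
            for k, v in self.accounting.items():
                grp.attrs[f"accounting_{k}"] = v

        if isinstance(path_or_group, (str, bytes)) or hasattr(path_or_group, "__fspath__"):
            with h5py.File(path_or_group, "w") as f:
                _write(f)
        else:
            _write(path_or_group)


def derive_stream_seed(master_seed: int, wavelength: float,
                       condition: str = "") -> int:
    """Stable per-wavelength stream seed.

    Derived by hashing so that a wavelength subset reuses exactly the photon
    streams of the corresponding wavelengths of a denser run.  The two
    physiological conditions deliberately share one stream per wavelength
    (pass the default empty ``condition``): scattering and geometry are
    condition-independent, so identical trajectories differ only in the
    absorption weighting and the attenuation-change ratio is computed with
    common random numbers, cancelling the shot noise that would otherwise
    swamp the few-μM gray-matter signal.  Pass a non-empty ``condition``
    token to force independent streams.
    """
    mask = (1 << 64) - 1

    def _mix(z: int) -> int:
        z &= mask
        z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & mask
        z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & mask
        return (z ^ (z >> 31)) & mask

    h = _mix((master_seed & mask) ^ ((int(round(wavelength * 1000))
                                      * 0x9E3779B97F4A7C15) & mask))
    for b in condition.encode():
        h = _mix(h ^ b)
    return h


def run_transport(phantom: CortexPhantom, mua_vessel: float, mua_gray: float,
                  mus: float, g: float = TISSUE_G, n: float = TISSUE_N,
                  source: SourceConfig | None = None,
                  n_photons: int = 200_000, seed: int = 0,
                  wavelength: float = float("nan"),
                  options: TransportOptions | None = None) -> PhotonRecordSet:
    """Trace ``n_photons`` through the phantom with fixed optical properties."""
    if source is None:
        source = SourceConfig()
    if options is None:
        options = TransportOptions()
    if n_photons <= 0:
        raise ValueError("n_photons must be > 0")

    vox = np.ascontiguousarray(phantom.vessel_layer())
    hx = phantom.extent[0] / 2.0
    hy = phantom.extent[1] / 2.0
    zmax = phantom.extent[2]

    out = [np.empty(n_photons) for _ in range(5)]
    acc = np.zeros(_kernel.ACC_SLOTS)
    counters = np.zeros(2, dtype=np.int64)

    icx, icy = source.illum_center
    n_det = _kernel.run_photons(
        n_photons, np.uint64(seed % (2 ** 64)), vox, phantom.voxel_size,
        hx, hy, zmax,
        source.center_xy[0], source.center_xy[1],
        source.size[0] / 2.0, source.size[1] / 2.0,
        source.standoff, source.cos_min,
        icx, icy, source.illuminated_size[0] / 2.0, source.illuminated_size[1] / 2.0,
        mua_vessel, mua_gray, mus, g, n / 1.0,
        options.roulette_threshold, options.roulette_survive,
        options.max_steps, options.reflect_walls,
        out[0], out[1], out[2], out[3], out[4],
        acc, counters,
    )

    if counters[1] > 0:
        raise RuntimeError(
            f"{counters[1]} photons could not be launched into the illuminated "
            "section; source/illumination geometry is misconfigured"
        )
    if counters[0] > 100 * n_photons:
        raise RuntimeError(
            "launch acceptance below 1%; source/illumination geometry is "
            "misconfigured"
        )

    accounting = {
        "detected": float(acc[_kernel.ACC_DETECTED]),
        "absorbed": float(acc[_kernel.ACC_ABSORBED]),
        "escaped_side": float(acc[_kernel.ACC_ESCAPED_SIDE]),
        "escaped_bottom": float(acc[_kernel.ACC_ESCAPED_BOTTOM]),
        "specular": float(acc[_kernel.ACC_SPECULAR]),
        "roulette": float(acc[_kernel.ACC_ROULETTE]),
        "step_capped": float(acc[_kernel.ACC_STEPCAP]),
        "launch_attempts": int(counters[0]),
    }
    if n_det == 0:
        import warnings

        warnings.warn(f"no photons detected (wavelength {wavelength} nm)")
    return PhotonRecordSet(
        exit_x=out[0][:n_det].copy(), exit_y=out[1][:n_det].copy(),
        weight=out[2][:n_det].copy(), path_vessel=out[3][:n_det].copy(),
        path_gray=out[4][:n_det].copy(),
        wavelength=wavelength, n_launched=n_photons, seed=int(seed),
        accounting=accounting,
    )


def simulate_wavelength(phantom: CortexPhantom,
                        compositions: dict[str, MediumComposition],
                        wavelength: float,
                        source: SourceConfig | None = None,
                        n_photons: int = 200_000, seed: int = 0,
                        spectra: ChromophoreSpectra | None = None,
                        scattering: ScatteringModel | None = None,
                        options: TransportOptions | None = None) -> PhotonRecordSet:
    """Run one wavelength with media compositions mapped to optical properties.

    ``compositions`` maps ``"vasculature"`` and ``"gray_matter"`` to their
    :class:`MediumComposition` for the simulated physiological condition.
    """
    if spectra is None:
        spectra = load_spectra()
    if scattering is None:
        scattering = default_scattering_model()
    mua_v = mua_of_medium(compositions["vasculature"], wavelength, spectra)
    mua_g = mua_of_medium(compositions["gray_matter"], wavelength, spectra)
    mus = mus_of_medium(wavelength, scattering)
    return run_transport(phantom, mua_v, mua_g, mus, g=scattering.g, n=TISSUE_N,
                         source=source, n_photons=n_photons, seed=seed,
                         wavelength=wavelength, options=options)


def sample_entries(source: SourceConfig, n: int, seed: int = 0):
    """Entry points (x, y) and downward cosines of n launches at the surface."""
    out_x = np.empty(n)
    out_y = np.empty(n)
    out_uz = np.empty(n)
    icx, icy = source.illum_center
    cos_min = source.cos_min
    collimated = cos_min >= 1.0 - 1e-12
    tan_max = 0.0 if collimated else math.sqrt(1.0 / cos_min ** 2 - 1.0)
    _kernel.sample_entry_points(
        n, np.uint64(seed), collimated, source.standoff * tan_max, source.standoff,
        source.center_xy[0], source.center_xy[1],
        source.size[0] / 2.0, source.size[1] / 2.0,
        icx, icy, source.illuminated_size[0] / 2.0, source.illuminated_size[1] / 2.0,
        out_x, out_y, out_uz)
    return out_x, out_y, out_uz


def sample_scatter(g: float, n: int, seed: int = 0) -> np.ndarray:
    """Draw deflection cosines from the Henyey–Greenstein phase function."""
    out = np.empty(n)
    _kernel.sample_hg_many(n, np.uint64(seed), g, out)
    return out
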