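"""End-to-end orchestration of the four computational imaging studies.

Study 1: two-condition (baseline → acute hypoxia) hyperspectral simulation
on the vessel phantom at the full 121-wavelength grid, MBLL reconstruction,
and the selective partial-pathlength correction.
Study 2: same protocol at reduced wavelength sets (25 at 5-nm sampling, and
the optimal 8: 784, 800, 818, 835, 851, 868, 881, 894 nm).
Study 3: ablations — metabolic-only (ΔS and the [Hb] rise zeroed) and
hemodynamic-only (CCO held constant) hypoxic responses, 8 wavelengths,
no correction.
Study 4: localized configuration — 0.1×0.1 mm source and 0.2×0.2 mm detector
FOV placed over a vessel-free patch of gray matter, 8 wavelengths, 60×60
pixel ROI, no correction.

Default photon budget is a desk-scale 2×10⁵ packets per wavelength; the
count is a single config knob for full-scale replication.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np

from . import phantom as phantom_mod
from . import unmixing as um
from .imaging import DetectorConfig, Hypercube, assemble_hypercube, bin_detections, \
    pathlength_maps
from .phantom import CortexPhantom, VesselMask
from .spectra import (
    GRAY_MATTER_BASELINE,
    VASCULATURE_BASELINE,
    MediumComposition,
    default_scattering_model,
    load_spectra,
)
from .transport import SourceConfig, TransportOptions, derive_stream_seed, \
    simulate_wavelength

__all__ = [
    "OPTIMAL_8_WAVELENGTHS",
    "wavelength_set",
    "hypoxic_composition",
    "condition_compositions",
    "StudyConfig",
    "ROIResult",
    "StudyReport",
    "run_study",
    "simulate_condition",
    "reconstruct",
    "compare_wavelength_sets",
]

log = logging.getLogger("cortexhsi")

#: optimal minimum wavelength combination for separating Hb and CCO signals
OPTIMAL_8_WAVELENGTHS = (784.0, 800.0, 818.0, 835.0, 851.0, 868.0, 881.0, 894.0)

_WAVELENGTH_SETS = {
    "full121": tuple(np.arange(780.0, 901.0, 1.0)),
    "sub25": tuple(np.arange(780.0, 901.0, 5.0)),
    "optimal8": OPTIMAL_8_WAVELENGTHS,
}


def wavelength_set(name_or_list) -> np.ndarray:
    """Resolve a named wavelength set ('full121' | 'sub25' | 'optimal8') or list."""
    if isinstance(name_or_list, str):
        try:
            return np.asarray(_WAVELENGTH_SETS[name_or_list])
        except KeyError:
            raise ValueError(
                f"unknown wavelength set {name_or_list!r}; "
                f"choose from {sorted(_WAVELENGTH_SETS)}") from None
    wl = np.asarray(name_or_list, dtype=float)
    if wl.size == 0:
        raise ValueError("wavelength set is empty")
    return wl


def hypoxic_composition(baseline: MediumComposition,
                        delta_s: float = -0.35,
                        hb_factor: float = 1.30,
                        delta_oxcco_uM: float = -3.0,
                        metabolic_only: bool = False,
                        hemodynamic_only: bool = False) -> MediumComposition:
    """Derive the hypoxic composition of a medium from its baseline.

    Hypoxia lowers the oxygen saturation by ΔS (−35 %), raises total [Hb] by
    +30 % (cerebral blood volume increase) and, in CCO-bearing tissue, moves
    ``delta_oxcco_uM`` of oxCCO into redCCO (the CCO pool is conserved).
    The ablation flags zero out the hemodynamic or metabolic response.
    """
    if metabolic_only and hemodynamic_only:
        raise ValueError("ablation flags are mutually exclusive")
    s = baseline.saturation
    hb = baseline.hb_total_uM
    ox, red = baseline.oxcco_uM, baseline.redcco_uM
    if not metabolic_only:
        s = s + delta_s
        hb = hb * hb_factor
    if not hemodynamic_only and baseline.oxcco_uM > 0:
        ox = baseline.oxcco_uM + delta_oxcco_uM
        red = baseline.redcco_uM - delta_oxcco_uM
        if ox < 0 or red < 0:
            raise ValueError("CCO swing exceeds the available pool")
    return replace(baseline, saturation=s, hb_total_uM=hb,
                   oxcco_uM=ox, redcco_uM=red)


def condition_compositions(metabolic_only: bool = False,
                           hemodynamic_only: bool = False,
                           delta_s: float = -0.35, hb_factor: float = 1.30,
                           delta_oxcco_uM: float = -3.0) -> dict:
    """Baseline and hypoxia compositions for both media (defaults as tabulated)."""
    base = {"gray_matter": GRAY_MATTER_BASELINE, "vasculature": VASCULATURE_BASELINE}
    hyp = {name: hypoxic_composition(c, delta_s, hb_factor, delta_oxcco_uM,
                                     metabolic_only, hemodynamic_only)
           for name, c in base.items()}
    return {"baseline": base, "hypoxia": hyp}


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one end-to-end simulation study."""

    study: str = "1"                       # "1" | "2" | "3a" | "3b" | "4" | "custom"
    wavelengths: object = "optimal8"
    photons_per_wavelength: int = 200_000
    master_seed: int = 1
    voxel_size: float = 0.01
    phantom_seed: int | None = None        # defaults to master_seed
    n_major: int = 1
    n_minor: int = 1
    delta_s: float = -0.35
    hb_factor: float = 1.30
    delta_oxcco_uM: float = -3.0
    metabolic_only: bool = False
    hemodynamic_only: bool = False
    roi_size: int = 10                     # in native 185-grid pixels
    apply_correction: bool = True
    localized: bool = False                # study-4 source/detector geometry
    detector_downscale: int = 1            # 5 → 37×37 pixels at desk-scale N
    output_dir: str | None = None

    @classmethod
    def from_file(cls, path, **overrides) -> "StudyConfig":
        """Load a configuration from a YAML/key-value file.

        The file holds the dataclass fields by name; a ``study`` key routes
        through the per-study presets, and explicit keys override them.
        """
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a key/value mapping")
        data.update(overrides)
        study = data.pop("study", None)
        if study is not None:
            return cls.for_study(str(study), **data)
        return cls(**data)

    @classmethod
    def for_study(cls, study: str, **overrides) -> "StudyConfig":
        presets = {
            "1": dict(wavelengths="full121"),
            "2": dict(wavelengths="optimal8"),
            "3a": dict(wavelengths="optimal8", metabolic_only=True,
                       apply_correction=False),
            "3b": dict(wavelengths="optimal8", hemodynamic_only=True,
                       apply_correction=False),
            "4": dict(wavelengths="optimal8", localized=True, roi_size=60,
                      apply_correction=False),
        }
        if study not in presets:
            raise ValueError(f"unknown study {study!r}; choose from {sorted(presets)}")
        kw = dict(presets[study])
        kw.update(overrides)
        return cls(study=study, **kw)

    def __post_init__(self) -> None:
        if self.metabolic_only and self.hemodynamic_only:
            raise ValueError("ablation flags are mutually exclusive")
        wavelength_set(self.wavelengths)  # validates


def localized_fov_center(mask: VesselMask, fov_size: float = 0.2) -> tuple[float, float]:
    """Center of the largest vessel-free patch, for the localized configuration.

    Found as the maximum of the distance transform of the vessel map,
    constrained so the FOV stays inside the mask footprint.
    """
    from scipy import ndimage

    dist = ndimage.distance_transform_edt(~mask.pixels) * mask.pixel_pitch
    ny, nx = mask.pixels.shape
    margin = int(np.ceil(fov_size / 2.0 / mask.pixel_pitch))
    interior = np.zeros_like(dist, dtype=bool)
    interior[margin:ny - margin, margin:nx - margin] = True
    dist = np.where(interior, dist, -1.0)
    r, c = np.unravel_index(np.argmax(dist), dist.shape)
    fx, fy = mask.fov_size
    x = -fx / 2.0 + (c + 0.5) * mask.pixel_pitch
    y = -fy / 2.0 + (r + 0.5) * mask.pixel_pitch
    return (float(x), float(y))


def geometry_for(config: StudyConfig, mask: VesselMask):
    """(SourceConfig, DetectorConfig) for the study's illumination/detection.

    ``detector_downscale`` divides the native 185×185 grid (and the ROI size
    with it) so that reduced photon budgets keep a per-pixel photon count in
    the regime the full-scale protocol has; the ROI keeps its physical size.
    """
    d = config.detector_downscale
    n = (185 // d, 185 // d)
    if config.localized:
        center = localized_fov_center(mask, 0.2)
        det = DetectorConfig(fov_size=(0.2, 0.2), fov_center_xy=center, n_pixels=n)
        src = SourceConfig(size=(0.1, 0.1), center_xy=center,
                           illuminated_size=(0.2, 0.2))
    else:
        det = DetectorConfig(n_pixels=n)
        src = SourceConfig()
    return src, det


def effective_roi_size(config: StudyConfig) -> int:
    return max(config.roi_size // config.detector_downscale, 1)


@dataclass
class ROIResult:
    roi: str
    chromophore: str
    theoretical_uM: float
    mean_uM: float
    std_uM: float
    corrected: bool

    @property
    def error_percent(self) -> float:
        if self.theoretical_uM == 0:
            return float("nan")
        return abs(self.mean_uM - self.theoretical_uM) / abs(self.theoretical_uM) * 100.0


@dataclass
class StudyReport:
    """All quantitative outputs of one study, reproducible from config + seed."""

    config: StudyConfig
    wavelengths: np.ndarray
    maps: um.ConcentrationMaps
    corrected_maps: um.ConcentrationMaps | None
    correction: um.CorrectionMaps | None
    rois: dict
    roi_results: list
    theory: dict
    detection_stats: dict
    hypercubes: dict | None = None
    phantom: CortexPhantom | None = None
    timings: dict = field(default_factory=dict)

    def roi_mean(self, roi: str, chromophore: str, corrected: bool | None = None):
        if corrected is None:
            corrected = self.corrected_maps is not None
        for r in self.roi_results:
            if r.roi == roi and r.chromophore == chromophore and r.corrected == corrected:
                return r
        raise KeyError((roi, chromophore, corrected))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([
            dict(study=self.config.study, roi=r.roi, chromophore=r.chromophore,
                 corrected=r.corrected, theoretical_uM=r.theoretical_uM,
                 mean_uM=r.mean_uM, std_uM=r.std_uM,
                 error_percent=r.error_percent)
            for r in self.roi_results
        ])


def simulate_condition(phantom: CortexPhantom, compositions: dict,
                       wavelengths, source: SourceConfig, det: DetectorConfig,
                       n_photons: int, master_seed: int, condition: str,
                       spectra=None, scattering=None,
                       options: TransportOptions | None = None) -> Hypercube:
    """Simulate all wavelengths of one physiological condition into a hypercube."""
    if spectra is None:
        spectra = load_spectra()
    if scattering is None:
        scattering = default_scattering_model()
    maps = {}
    stats = {}
    for wl in np.asarray(wavelengths, float):
        # one stream per wavelength, shared by both conditions (common random
        # numbers: scattering paths are condition-independent)
        seed = derive_stream_seed(master_seed, wl)
        t0 = time.perf_counter()
        rec = simulate_wavelength(phantom, compositions, wl, source=source,
                                  n_photons=n_photons, seed=seed,
                                  spectra=spectra, scattering=scattering,
                                  options=options)
        maps[float(wl)] = (bin_detections(rec, det), pathlength_maps(rec, det))
        stats[float(wl)] = dict(n_detected=rec.n_detected,
                                detected_weight=rec.accounting["detected"],
                                seconds=time.perf_counter() - t0)
        log.info("%s %g nm: %d detected (%.2fs)", condition, wl,
                 rec.n_detected, stats[float(wl)]["seconds"])
    return assemble_hypercube(maps, condition=condition, detector=det,
                              meta={"n_photons": n_photons, "master_seed": master_seed,
                                    "per_wavelength_stats": str(stats)})


def reconstruct(baseline: Hypercube, hypoxia: Hypercube, spectra=None):
    """ΔA → MBLL maps and correction-factor maps from a hypercube pair."""
    if spectra is None:
        spectra = load_spectra()
    dA = um.attenuation_change(baseline, hypoxia)
    pl = um.mean_pathlength(baseline, hypoxia)
    maps = um.solve_mbll(dA, pl, spectra)
    cf = um.correction_factors(baseline, hypoxia)
    return maps, cf


def run_study(config: StudyConfig,
              phantom: CortexPhantom | None = None,
              keep_hypercubes: bool = False) -> StudyReport:
    """Execute one study end to end and evaluate the ROI accuracy."""
    t_start = time.perf_counter()
    spectra = load_spectra()
    scattering = default_scattering_model()
    wl = wavelength_set(config.wavelengths)

    stage = "phantom"
    try:
        if phantom is None:
            seed = config.phantom_seed if config.phantom_seed is not None \
                else config.master_seed
            phantom = phantom_mod.make_default_phantom(
                seed=seed, voxel_size=config.voxel_size,
                n_major=config.n_major, n_minor=config.n_minor)
        mask = phantom.mask
        if mask is None:
            raise ValueError("phantom carries no registered vessel mask")
        src, det = geometry_for(config, mask)
        t_phantom = time.perf_counter()

        stage = "transport"
        comps = condition_compositions(
            metabolic_only=config.metabolic_only,
            hemodynamic_only=config.hemodynamic_only,
            delta_s=config.delta_s, hb_factor=config.hb_factor,
            delta_oxcco_uM=config.delta_oxcco_uM)
        cubes = {}
        for condition in ("baseline", "hypoxia"):
            cubes[condition] = simulate_condition(
                phantom, comps[condition], wl, src, det,
                config.photons_per_wavelength, config.master_seed, condition,
                spectra=spectra, scattering=scattering)
        t_transport = time.perf_counter()

        stage = "reconstruction"
        maps, cf = reconstruct(cubes["baseline"], cubes["hypoxia"], spectra)
        vessel_px = um.mask_to_pixel_grid(mask, det)
        corrected = um.apply_correction(maps, cf, vessel_px) \
            if config.apply_correction else None

        stage = "roi analysis"
        roi_px = effective_roi_size(config)
        if config.localized:
            # concentric ROI over homogeneous gray matter
            nrow, ncol = det.n_pixels
            r0 = (nrow - roi_px) // 2
            c0 = (ncol - roi_px) // 2
            rois = {"gray_matter": um.ROISpec(r0, c0, roi_px, "gray_matter")}
        else:
            rois = um.default_rois(vessel_px, size=roi_px)

        theory = {
            "vasculature": um.theoretical_deltas(comps["baseline"]["vasculature"],
                                                 comps["hypoxia"]["vasculature"]),
            "gray_matter": um.theoretical_deltas(comps["baseline"]["gray_matter"],
                                                 comps["hypoxia"]["gray_matter"]),
        }
        # no CCO is simulated in the vasculature: its theoretical change is 0
        results = []
        for corrected_flag, cmaps in ((False, maps),) + (
                ((True, corrected),) if corrected is not None else ()):
            for roi_name, roi in rois.items():
                th = theory[roi_name]
                for i, chrom in enumerate(("hbo2", "hhb", "oxcco")):
                    st = um.roi_stats(cmaps.chromophore(chrom), roi)
                    results.append(ROIResult(
                        roi=roi_name, chromophore=chrom,
                        theoretical_uM=th[i], mean_uM=st.mean, std_uM=st.std,
                        corrected=corrected_flag))

        detection_stats = {
            cond: dict(total_detected=int(cube.n_detected.sum()),
                       total_weight=float(cube.intensity.sum()))
            for cond, cube in cubes.items()
        }
        report = StudyReport(
            config=config, wavelengths=wl, maps=maps, corrected_maps=corrected,
            correction=cf, rois=rois, roi_results=results, theory=theory,
            detection_stats=detection_stats,
            hypercubes=cubes if keep_hypercubes else None,
            phantom=phantom,
            timings=dict(phantom=t_phantom - t_start,
                         transport=t_transport - t_phantom,
                         reconstruction=time.perf_counter() - t_transport),
        )
    except Exception as exc:
        raise RuntimeError(
            f"study {config.study} failed at stage '{stage}' "
            f"(seed {config.master_seed})") from exc

    if config.output_dir:
        _write_outputs(report, cubes, config)
    return report


def _write_outputs(report: StudyReport, cubes: dict, config: StudyConfig) -> None:
    from pathlib import Path

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for cond, cube in cubes.items():
        cube.to_hdf5(out / f"hypercube_{cond}.h5")
    import tifffile

    for name in ("dhbo2", "dhhb", "doxcco"):
        tifffile.imwrite(out / f"{name}.tif",
                         getattr(report.maps, name).astype(np.float32))
        if report.corrected_maps is not None:
            tifffile.imwrite(out / f"{name}_corrected.tif",
                             getattr(report.corrected_maps, name).astype(np.float32))
    report.to_frame().to_csv(out / "roi_table.csv", index=False)


def compare_wavelength_sets(reports: list) -> "object":
    """Percent differences of ROI means across wavelength sets.

    All reports must share phantom geometry and condition parameters; the
    report with the most wavelengths is the reference.
    """
    import pandas as pd

    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    key0 = [(r.roi, r.chromophore, r.corrected) for r in reports[0].roi_results]
    for rep in reports[1:]:
        if [(r.roi, r.chromophore, r.corrected) for r in rep.roi_results] != key0:
            raise ValueError("reports are not comparable (different ROI layouts)")
    ref = max(reports, key=lambda r: len(r.wavelengths))
    rows = []
    for rep in reports:
        if rep is ref:
            continue
        for r, r0 in zip(rep.roi_results, ref.roi_results):
            denom = abs(r0.mean_uM)
            rows.append(dict(
                n_wavelengths=len(rep.wavelengths),
                ref_wavelengths=len(ref.wavelengths),
                roi=r.roi, chromophore=r.chromophore, corrected=r.corrected,
                mean_uM=r.mean_uM, ref_mean_uM=r0.mean_uM,
                diff_percent=abs(r.mean_uM - r0.mean_uM) / denom * 100.0
                if denom > 0 else float("nan"),
            ))
    return pd.DataFrame(rows)
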