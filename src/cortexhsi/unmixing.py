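"""MBLL spectral unmixing and the partial-pathlength correction.

From baseline/hypoxia intensity hypercubes the per-pixel attenuation change

    ΔA(λ) = −log10( I_hypoxia(λ) / I_baseline(λ) )           (decadic)

is inverted, pixel by pixel, through the modified Beer–Lambert law

    ΔA(λᵢ) = PL(λᵢ) · [ εHbO2(λᵢ)·Δ[HbO2] + εHHb(λᵢ)·Δ[HHb]
                        + εdiffCCO(λᵢ)·Δ[oxCCO] ]

in least squares over the M wavelengths (Moore–Penrose pseudoinverse of the
pathlength-scaled extinction matrix).  PL is the per-pixel mean, between the
two conditions, of the average total photon pathlength.

Because detected photons travel mostly in gray matter, the total pathlength
badly overestimates the path relevant to vessel pixels, which underestimates
vascular Δ[HbO2]/Δ[HHb] by an order of magnitude.  The correction-factor
maps CF′ = ⟨PL_total/PL_vessel⟩_λ and CF″ = ⟨PL_total/PL_gray⟩_λ (averaged
across the two conditions) rescale the hemodynamic estimates selectively:
vessel pixels multiply Δ[HbO2], Δ[HHb] by CF′ (the metabolic map is left
untouched there — no CCO lives in the vasculature); gray-matter pixels
multiply all three by CF″ (a near no-op, since gray paths dominate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import DetectorConfig, Hypercube
from .phantom import VesselMask
from .spectra import ChromophoreSpectra, MediumComposition

__all__ = [
    "AttenuationCube",
    "ConcentrationMaps",
    "CorrectionMaps",
    "ROISpec",
    "ROIStats",
    "attenuation_change",
    "mean_pathlength",
    "solve_mbll",
    "correction_factors",
    "apply_correction",
    "mask_to_pixel_grid",
    "roi_stats",
    "default_rois",
    "theoretical_deltas",
]

_MM_TO_CM = 0.1
_M_TO_UM = 1e6


@dataclass
class AttenuationCube:
    """Decadic attenuation changes, (M, rows, cols); NaN where undetected."""

    delta_A: np.ndarray
    wavelengths: np.ndarray


@dataclass
class ConcentrationMaps:
    """Δ-concentration images in μM; NaN propagates from missing pixels."""

    dhbo2: np.ndarray
    dhhb: np.ndarray
    doxcco: np.ndarray
    corrected: bool = False
    n_uncorrectable: int = 0

    def chromophore(self, name: str) -> np.ndarray:
        return {"hbo2": self.dhbo2, "hhb": self.dhhb, "oxcco": self.doxcco}[name]


@dataclass
class CorrectionMaps:
    """CF′ (vessel) and CF″ (gray) correction-factor maps; NaN where undefined."""

    cf_vessel: np.ndarray
    cf_gray: np.ndarray
    n_wavelengths: int


def _check_compatible(a: Hypercube, b: Hypercube) -> None:
    if a.intensity.shape != b.intensity.shape or \
            not np.allclose(a.wavelengths, b.wavelengths):
        raise ValueError("hypercubes have mismatched wavelengths or detector grids")


def attenuation_change(baseline: Hypercube, hypoxia: Hypercube) -> AttenuationCube:
    """ΔA = −log10(I_hypoxia / I_baseline), per pixel and wavelength."""
    _check_compatible(baseline, hypoxia)
    ib = baseline.intensity
    ih = hypoxia.intensity
    with np.errstate(divide="ignore", invalid="ignore"):
        dA = -np.log10(np.where((ib > 0) & (ih > 0), ih / np.where(ib > 0, ib, 1.0),
                                np.nan))
    return AttenuationCube(dA, baseline.wavelengths.copy())


def mean_pathlength(baseline: Hypercube, hypoxia: Hypercube,
                    dataset: str = "pl_total") -> np.ndarray:
    """Arithmetic mean of a pathlength stack between the two conditions.

    NaN (no detected photons) on either side propagates.
    """
    _check_compatible(baseline, hypoxia)
    return 0.5 * (getattr(baseline, dataset) + getattr(hypoxia, dataset))


def solve_mbll(dA: AttenuationCube, pathlength: np.ndarray,
               spectra: ChromophoreSpectra,
               wavelengths=None, cond_limit: float = 1e10) -> ConcentrationMaps:
    """Invert the MBLL system per pixel for (Δ[HbO2], Δ[HHb], Δ[oxCCO]) in μM.

    ``pathlength`` is the (M, rows, cols) per-pixel mean total pathlength in
    mm.  Pixels missing any wavelength (NaN in ΔA or PL) are left NaN.  A
    rank-deficient spectral system (e.g., duplicate wavelengths) raises with
    the condition number named.
    """
    wl = np.asarray(dA.wavelengths if wavelengths is None else wavelengths, float)
    if wl.size < 3:
        raise ValueError("MBLL needs at least 3 wavelengths")
    if wavelengths is not None and not np.allclose(wl, dA.wavelengths):
        raise ValueError("wavelengths do not match the attenuation cube")
    E = spectra.extinction_matrix(wl)  # (M, 3), M⁻¹cm⁻¹
    cond = np.linalg.cond(E)
    if not np.isfinite(cond) or cond > cond_limit:
        raise ValueError(
            f"rank-deficient extinction system (condition number {cond:.3g}); "
            "check for duplicate wavelengths"
        )
    m, nr, nc = dA.delta_A.shape
    if pathlength.shape != (m, nr, nc):
        raise ValueError("pathlength cube shape does not match attenuation cube")

    pl_cm = pathlength.reshape(m, -1) * _MM_TO_CM
    y = dA.delta_A.reshape(m, -1)
    valid = np.all(np.isfinite(y) & np.isfinite(pl_cm) & (pl_cm > 0), axis=0)

    # per-pixel design is diag(PL) @ E; solve the 3x3 normal equations
    plv = pl_cm[:, valid]                       # (M, P)
    yv = y[:, valid]                            # (M, P)
    G = np.einsum("mp,mi,mj->pij", plv * plv, E, E)   # (P, 3, 3)
    b = np.einsum("mp,mi,mp->pi", plv, E, yv)         # (P, 3)
    sol = np.linalg.solve(G, b[..., None])[..., 0] * _M_TO_UM   # mol/L → μM

    out = np.full((3, nr * nc), np.nan)
    out[:, valid] = sol.T
    out = out.reshape(3, nr, nc)
    return ConcentrationMaps(out[0], out[1], out[2])


def synthesize_attenuation(dhbo2_uM: float, dhhb_uM: float, doxcco_uM: float,
                           pathlength: np.ndarray, spectra: ChromophoreSpectra,
                           wavelengths) -> AttenuationCube:
    """Forward MBLL: ΔA from known concentration changes (round-trip oracle)."""
    wl = np.asarray(wavelengths, float)
    E = spectra.extinction_matrix(wl)
    c = np.array([dhbo2_uM, dhhb_uM, doxcco_uM]) / _M_TO_UM
    spectral = E @ c                              # (M,) per cm
    dA = pathlength * _MM_TO_CM * spectral[:, None, None]
    return AttenuationCube(dA, wl)


def correction_factors(baseline: Hypercube, hypoxia: Hypercube) -> CorrectionMaps:
    """Correction-factor maps from per-medium partial-pathlength cubes.

    Per condition and pixel, CF′ is the mean over the M wavelengths of
    PL_total/PL_vessel (CF″ analogous with PL_gray); the returned maps are
    the mean of the two conditions.  Pixels where the denominator pathlength
    is zero or missing at any wavelength are NaN (no correction applied).
    """
    _check_compatible(baseline, hypoxia)
    m = baseline.n_wavelengths

    def _cf(cube: Hypercube, medium: str) -> np.ndarray:
        denom = getattr(cube, medium)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(denom > 0, cube.pl_total / denom, np.nan)
        return ratio.mean(axis=0)  # NaN propagates across wavelengths

    cf_vessel = 0.5 * (_cf(baseline, "pl_vessel") + _cf(hypoxia, "pl_vessel"))
    cf_gray = 0.5 * (_cf(baseline, "pl_gray") + _cf(hypoxia, "pl_gray"))
    return CorrectionMaps(cf_vessel, cf_gray, m)


def mask_to_pixel_grid(mask: VesselMask, det: DetectorConfig) -> np.ndarray:
    """Register a vessel mask to the detector pixel grid.

    Majority rule over the mask pixels whose centers fall in each detector
    pixel; ties count as vessel (conservative for the correction).  Detector
    pixels receiving no mask pixel (coarser mask) use the nearest mask pixel.
    """
    nrow, ncol = det.n_pixels
    mny, mnx = mask.pixels.shape
    ox, oy = det.origin_xy
    pw, ph = det.pixel_pitch
    # mask is centered on the mask's own FOV, which is centered at (0, 0)
    mx0 = -mask.fov_size[0] / 2.0
    my0 = -mask.fov_size[1] / 2.0

    # detector pixel centers → mask pixel lookup (nearest neighbor)
    xc = ox + (np.arange(ncol) + 0.5) * pw
    yc = oy + (np.arange(nrow) + 0.5) * ph
    mc = np.clip(((xc - mx0) / mask.pixel_pitch).astype(int), 0, mnx - 1)
    mr = np.clip(((yc - my0) / mask.pixel_pitch).astype(int), 0, mny - 1)
    nearest = mask.pixels[mr[:, None], mc[None, :]]

    # majority vote where the mask is finer than the detector grid
    mxc = mx0 + (np.arange(mnx) + 0.5) * mask.pixel_pitch
    myc = my0 + (np.arange(mny) + 0.5) * mask.pixel_pitch
    cols = np.floor((mxc - ox) / pw).astype(int)
    rows = np.floor((myc - oy) / ph).astype(int)
    okc = (cols >= 0) & (cols < ncol)
    okr = (rows >= 0) & (rows < nrow)
    votes = np.zeros((nrow, ncol))
    total = np.zeros((nrow, ncol))
    rr = rows[okr]
    cc = cols[okc]
    sub = mask.pixels[np.ix_(okr, okc)].astype(float)
    np.add.at(votes, (rr[:, None], cc[None, :]), sub)
    np.add.at(total, (rr[:, None], cc[None, :]), 1.0)
    grid = np.where(total > 0, votes * 2 >= np.where(total > 0, total, 1), nearest)
    return grid.astype(bool)


def apply_correction(maps: ConcentrationMaps, cf: CorrectionMaps,
                     vessel_pixels: np.ndarray) -> ConcentrationMaps:
    """Selective partial-pathlength correction of the concentration maps.

    ``vessel_pixels`` is the boolean vessel map registered to the detector
    grid.  Vessel pixels: Δ[HbO2], Δ[HHb] × CF′ (Δ[oxCCO] untouched).
    Gray pixels: all three × CF″.  Pixels with undefined CF pass through
    unchanged and are counted in ``n_uncorrectable``.
    """
    if vessel_pixels.shape != maps.dhbo2.shape:
        raise ValueError("vessel mask is not registered to the pixel grid")
    vessel = vessel_pixels.astype(bool)
    cfv = cf.cf_vessel
    cfg = cf.cf_gray
    solved = np.isfinite(maps.dhbo2)
    uncorrectable = solved & ((vessel & ~np.isfinite(cfv))
                              | (~vessel & ~np.isfinite(cfg)))

    factor_hemo = np.ones_like(maps.dhbo2)
    factor_meta = np.ones_like(maps.dhbo2)
    vmask = vessel & np.isfinite(cfv)
    gmask = ~vessel & np.isfinite(cfg)
    factor_hemo[vmask] = cfv[vmask]
    factor_hemo[gmask] = cfg[gmask]
    factor_meta[gmask] = cfg[gmask]

    return ConcentrationMaps(
        dhbo2=maps.dhbo2 * factor_hemo,
        dhhb=maps.dhhb * factor_hemo,
        doxcco=maps.doxcco * factor_meta,
        corrected=True,
        n_uncorrectable=int(uncorrectable.sum()),
    )


@dataclass(frozen=True)
class ROISpec:
    """Square pixel window (row0, col0, size) with a medium label."""

    row0: int
    col0: int
    size: int = 10
    label: str = ""

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row0, self.row0 + self.size),
                slice(self.col0, self.col0 + self.size))


@dataclass
class ROIStats:
    mean: float
    std: float
    n_pixels: int
    n_missing: int
    label: str = ""


def roi_stats(map2d: np.ndarray, roi: ROISpec) -> ROIStats:
    """Mean and standard deviation over the non-missing ROI pixels."""
    nr, nc = map2d.shape
    if roi.row0 < 0 or roi.col0 < 0 or roi.row0 + roi.size > nr \
            or roi.col0 + roi.size > nc:
        raise ValueError("ROI out of map bounds")
    window = map2d[roi.slices()]
    finite = np.isfinite(window)
    if not finite.any():
        raise ValueError("ROI contains no valid pixels")
    vals = window[finite]
    return ROIStats(mean=float(vals.mean()), std=float(vals.std(ddof=0)),
                    n_pixels=int(finite.sum()), n_missing=int((~finite).sum()),
                    label=roi.label)


def default_rois(vessel_pixels: np.ndarray, size: int = 10) -> dict[str, ROISpec]:
    """Auto-place the vasculature and gray-matter ROIs on the pixel grid.

    The vessel ROI is the ``size``×``size`` window whose pixels are all
    vessel and whose center is deepest inside the vessel map
    (distance-transform maximum); the gray ROI is the all-gray window
    farthest from any vessel.  Windows touching the map border are avoided
    (the FOV edge carries illumination boundary effects).
    """
    from scipy import ndimage

    vessel = vessel_pixels.astype(bool)
    nr, nc = vessel.shape

    def _best_window(phase: np.ndarray, label: str) -> ROISpec:
        # distance from the complement, so larger = deeper inside the phase;
        # border treated as outside to keep the window in the interior
        padded = np.zeros((nr + 2, nc + 2), dtype=bool)
        padded[1:-1, 1:-1] = phase
        dist = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
        # score each window by its worst pixel: all pixels must be in phase
        worst = ndimage.minimum_filter(dist, size=size, mode="constant", cval=0.0)
        # minimum_filter is centered; convert center to window origin
        r, c = np.unravel_index(np.argmax(worst), worst.shape)
        r0 = int(np.clip(r - size // 2, 0, nr - size))
        c0 = int(np.clip(c - size // 2, 0, nc - size))
        if worst[r, c] <= 0 and not phase[r0:r0 + size, c0:c0 + size].all():
            # no window fits entirely inside the phase; fall back to deepest point
            r, c = np.unravel_index(np.argmax(dist), dist.shape)
            r0 = int(np.clip(r - size // 2, 0, nr - size))
            c0 = int(np.clip(c - size // 2, 0, nc - size))
        return ROISpec(r0, c0, size, label)

    rois = {}
    if vessel.any():
        rois["vasculature"] = _best_window(vessel, "vasculature")
    rois["gray_matter"] = _best_window(~vessel, "gray_matter")
    return rois


def theoretical_deltas(baseline: MediumComposition,
                       hypoxia: MediumComposition) -> tuple[float, float, float]:
    """Expected (Δ[HbO2], Δ[HHb], Δ[oxCCO]) in μM between two compositions."""
    dhbo2 = hypoxia.hbo2_uM - baseline.hbo2_uM
    dhhb = hypoxia.hhb_uM - baseline.hhb_uM
    doxcco = hypoxia.oxcco_uM - baseline.oxcco_uM
    return (dhbo2, dhhb, doxcco)
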