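"""Chromophore spectra and wavelength-dependent optical properties of tissue media.

The exposed-cortex phantom contains two tissue media — pial vasculature and
subpial gray matter — whose near-infrared absorption is built from the major
chromophores: water, fat, oxy-/deoxyhemoglobin (HbO2/HHb) and the oxidized and
reduced states of cytochrome-c-oxidase (oxCCO/redCCO).  The packaged spectra
cover 780–900 nm on a 1-nm grid:

* ``mua_water``, ``mua_fat``: absorption coefficients in cm⁻¹,
* ``eps_*``: decadic molar extinction coefficients in M⁻¹ cm⁻¹,
* ``eps_diffcco``: the oxidized-minus-reduced difference spectrum of CCO, an
  independently tabulated column used for spectral unmixing (it is *not*
  recomputed as ``eps_oxcco - eps_redcco``; the tabulated values differ).

All transport-facing quantities are returned in mm⁻¹; the unit conversion from
the printed cm-based units happens at the boundary of this module only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ChromophoreSpectra",
    "MediumComposition",
    "OpticalProperties",
    "ScatteringModel",
    "load_spectra",
    "mua_of_medium",
    "mus_of_medium",
    "optical_properties",
    "air_properties",
    "GRAY_MATTER_BASELINE",
    "GRAY_MATTER_HYPOXIA",
    "VASCULATURE_BASELINE",
    "VASCULATURE_HYPOXIA",
    "TABLE_COMPOSITIONS",
    "WAVELENGTH_MIN",
    "WAVELENGTH_MAX",
]

WAVELENGTH_MIN = 780.0
WAVELENGTH_MAX = 900.0

#: anisotropy and refractive index shared by both tissue media
TISSUE_G = 0.9
TISSUE_N = 1.365

_LN10 = math.log(10.0)
_CM1_TO_MM1 = 0.1

_DATA_FILE = "chromophore_spectra_nir.csv"
_EXPECTED_COLUMNS = [
    "wavelength_nm",
    "mua_water_cm1",
    "mua_fat_cm1",
    "eps_hbo2_M1cm1",
    "eps_hhb_M1cm1",
    "eps_oxcco_M1cm1",
    "eps_redcco_M1cm1",
    "eps_diffcco_M1cm1",
]
_EXPECTED_ROWS = 121


@dataclass(frozen=True)
class ChromophoreSpectra:
    """Wavelength-indexed chromophore spectra (printed units: cm⁻¹, M⁻¹cm⁻¹)."""

    wavelengths: np.ndarray
    mua_water: np.ndarray
    mua_fat: np.ndarray
    eps_hbo2: np.ndarray
    eps_hhb: np.ndarray
    eps_oxcco: np.ndarray
    eps_redcco: np.ndarray
    eps_diffcco: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size == 0:
            raise ValueError("wavelength grid must be a non-empty 1-D array")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        for name in _EXPECTED_COLUMNS[1:]:
            attr = name.rsplit("_", 1)[0]
            vals = np.asarray(getattr(self, attr), dtype=float)
            if vals.shape != wl.shape:
                raise ValueError(f"column {attr} does not match the wavelength grid")
            if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
                raise ValueError(f"column {attr} must be finite and positive")

    def at(self, wavelengths) -> "ChromophoreSpectra":
        """Spectra sampled at the requested wavelengths (linear interpolation)."""
        wl = np.atleast_1d(np.asarray(wavelengths, dtype=float))
        _check_range(wl)
        cols = {
            "wavelengths": wl,
            **{
                attr: np.interp(wl, self.wavelengths, getattr(self, attr))
                for attr in (
                    "mua_water",
                    "mua_fat",
                    "eps_hbo2",
                    "eps_hhb",
                    "eps_oxcco",
                    "eps_redcco",
                    "eps_diffcco",
                )
            },
        }
        return ChromophoreSpectra(**cols)

    def extinction_matrix(self, wavelengths=None) -> np.ndarray:
        """(M, 3) decadic extinction matrix [eps_hbo2, eps_hhb, eps_diffcco].

        This is the spectral design matrix of the MBLL unmixing step; the CCO
        column is the tabulated oxidized-reduced difference spectrum.
        Duplicate or unsorted wavelengths are permitted here (rank checks
        happen in the solver).
        """
        if wavelengths is None:
            return np.column_stack([self.eps_hbo2, self.eps_hhb, self.eps_diffcco])
        wl = np.atleast_1d(np.asarray(wavelengths, dtype=float))
        _check_range(wl)
        return np.column_stack([
            np.interp(wl, self.wavelengths, col)
            for col in (self.eps_hbo2, self.eps_hhb, self.eps_diffcco)
        ])


def _check_range(wl: np.ndarray) -> None:
    bad = wl[(wl < WAVELENGTH_MIN) | (wl > WAVELENGTH_MAX)]
    if bad.size:
        raise ValueError(
            f"wavelength {bad[0]:g} nm outside the tabulated range "
            f"[{WAVELENGTH_MIN:g}, {WAVELENGTH_MAX:g}] nm"
        )


def load_spectra(wavelengths=None) -> ChromophoreSpectra:
    """Load the packaged chromophore table, optionally resampled.

    Parameters
    ----------
    wavelengths : array-like of float, optional
        Wavelengths in nm at which to sample the spectra.  Values between grid
        points are linearly interpolated; values outside [780, 900] nm raise a
        ``ValueError``.  By default the full native 1-nm grid is returned.
    """
    ref = resources.files("cortexhsi").joinpath("data", _DATA_FILE)
    with ref.open("r") as fh:
        table = pd.read_csv(fh)
    if list(table.columns) != _EXPECTED_COLUMNS:
        raise ValueError(f"unexpected column header in {_DATA_FILE}")
    if len(table) != _EXPECTED_ROWS:
        raise ValueError(
            f"expected {_EXPECTED_ROWS} rows in {_DATA_FILE}, found {len(table)}"
        )
    native = ChromophoreSpectra(
        wavelengths=table["wavelength_nm"].to_numpy(float),
        mua_water=table["mua_water_cm1"].to_numpy(float),
        mua_fat=table["mua_fat_cm1"].to_numpy(float),
        eps_hbo2=table["eps_hbo2_M1cm1"].to_numpy(float),
        eps_hhb=table["eps_hhb_M1cm1"].to_numpy(float),
        eps_oxcco=table["eps_oxcco_M1cm1"].to_numpy(float),
        eps_redcco=table["eps_redcco_M1cm1"].to_numpy(float),
        eps_diffcco=table["eps_diffcco_M1cm1"].to_numpy(float),
    )
    if wavelengths is None:
        return native
    return native.at(wavelengths)


@dataclass(frozen=True)
class MediumComposition:
    """Composition of one medium in one physiological condition.

    Attributes
    ----------
    water, fat : float
        Volume fractions of water and lipid, in [0, 1].
    hb_total_uM : float
        Total hemoglobin concentration [Hb] in blood, μM.
    blood : float
        Blood volume fraction B of the medium, in [0, 1].
    saturation : float
        Hemoglobin oxygen saturation S, in [0, 1].
    oxcco_uM, redcco_uM : float
        Tissue concentrations of oxidized and reduced CCO, μM.  CCO is a
        tissue chromophore and is not scaled by the blood fraction.
    """

    water: float = 0.0
    fat: float = 0.0
    hb_total_uM: float = 0.0
    blood: float = 0.0
    saturation: float = 0.0
    oxcco_uM: float = 0.0
    redcco_uM: float = 0.0

    def __post_init__(self) -> None:
        for name in ("water", "fat", "hb_total_uM", "blood", "saturation",
                     "oxcco_uM", "redcco_uM"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"composition field {name} must be >= 0, got {v}")
        for name in ("water", "fat", "blood", "saturation"):
            if getattr(self, name) > 1:
                raise ValueError(f"fraction {name} must be <= 1")

    @property
    def hbo2_uM(self) -> float:
        """Effective tissue HbO2 concentration [Hb]·B·S, μM."""
        return self.hb_total_uM * self.blood * self.saturation

    @property
    def hhb_uM(self) -> float:
        """Effective tissue HHb concentration [Hb]·B·(1−S), μM."""
        return self.hb_total_uM * self.blood * (1.0 - self.saturation)


# Media compositions of the exposed-cortex phantom for the two simulated
# physiological conditions (baseline / acute hypoxia).  Hypoxia applies an
# oxygen-saturation drop ΔS = −35 %, a +30 % rise in total [Hb] (increased
# cerebral blood volume), and a −3 μM swing of oxCCO into redCCO restricted
# to the gray matter; water and fat stay fixed.
GRAY_MATTER_BASELINE = MediumComposition(0.70, 0.10, 2325.6, 0.0375, 0.85, 4.0, 1.0)
GRAY_MATTER_HYPOXIA = MediumComposition(0.70, 0.10, 3023.3, 0.0375, 0.50, 1.0, 4.0)
VASCULATURE_BASELINE = MediumComposition(0.50, 0.01, 2325.6, 1.0, 0.85, 0.0, 0.0)
VASCULATURE_HYPOXIA = MediumComposition(0.50, 0.01, 3023.3, 1.0, 0.50, 0.0, 0.0)

TABLE_COMPOSITIONS = {
    ("gray_matter", "baseline"): GRAY_MATTER_BASELINE,
    ("gray_matter", "hypoxia"): GRAY_MATTER_HYPOXIA,
    ("vasculature", "baseline"): VASCULATURE_BASELINE,
    ("vasculature", "hypoxia"): VASCULATURE_HYPOXIA,
}


def mua_of_medium(comp: MediumComposition, wavelength, spectra: ChromophoreSpectra):
    """Absorption coefficient μa of a medium, mm⁻¹.

    μa(λ) is the sum of the chromophore contributions: water and fat enter
    through their volume-fraction-weighted absorption coefficients; the
    hemoglobin species through [Hb]·B·S and [Hb]·B·(1−S); CCO through its
    tissue concentrations.  Extinction coefficients are decadic, hence the
    ln(10) factor converting them to natural absorption.  Linear in every
    concentration.
    """
    s = spectra.at(wavelength)
    conc_terms = (
        s.eps_hbo2 * comp.hbo2_uM
        + s.eps_hhb * comp.hhb_uM
        + s.eps_oxcco * comp.oxcco_uM
        + s.eps_redcco * comp.redcco_uM
    ) * 1e-6  # μM → mol/L
    mua_cm1 = comp.water * s.mua_water + comp.fat * s.mua_fat + _LN10 * conc_terms
    mua = mua_cm1 * _CM1_TO_MM1
    return float(mua[0]) if np.isscalar(wavelength) else mua


@dataclass(frozen=True)
class ScatteringModel:
    """Reduced-scattering power law μs′(λ) = a′ (λ/500 nm)^(−b), scaled by 1/(1−g).

    Parameters
    ----------
    a_prime : float
        Reduced scattering amplitude at 500 nm, mm⁻¹.
    b : float
        Scattering power.  Default 1.611 (brain tissue).
    g : float
        Scattering anisotropy used to scale μs′ to μs.
    """

    a_prime: float
    b: float = 1.611
    g: float = TISSUE_G

    def __post_init__(self) -> None:
        if self.a_prime <= 0:
            raise ValueError("a_prime must be > 0")
        if self.b < 0:
            raise ValueError("b must be >= 0")
        if not -1.0 <= self.g < 1.0:
            raise ValueError(
                "invalid anisotropy for scaled scattering: g must be in [-1, 1)"
            )

    @classmethod
    def calibrated(cls, mus_mm1: float = 9.1841, at_wavelength: float = 835.0,
                   b: float = 1.611, g: float = TISSUE_G) -> "ScatteringModel":
        """Model with a′ chosen so that μs(at_wavelength) equals ``mus_mm1``.

        The default anchors μs(835 nm) = 9.1841 mm⁻¹, the value shared by both
        tissue media and both conditions.
        """
        a_prime = mus_mm1 * (1.0 - g) * (at_wavelength / 500.0) ** b
        return cls(a_prime=a_prime, b=b, g=g)


def default_scattering_model() -> ScatteringModel:
    return ScatteringModel.calibrated()


def mus_of_medium(wavelength, model: ScatteringModel):
    """Scattering coefficient μs(λ) = a′ (λ/500)^(−b) / (1−g), mm⁻¹.

    Identical for both tissue media and both physiological conditions; the
    scattering spectrum depends only on wavelength.
    """
    wl = np.asarray(wavelength, dtype=float)
    if np.any(wl <= 0):
        raise ValueError("wavelength must be > 0")
    mus = model.a_prime * (wl / 500.0) ** (-model.b) / (1.0 - model.g)
    return float(mus) if np.isscalar(wavelength) else mus


@dataclass(frozen=True)
class OpticalProperties:
    """Bundle (μa, μs, g, n); lengths in mm⁻¹."""

    mua: float
    mus: float
    g: float
    n: float

    def __post_init__(self) -> None:
        if self.mua < 0 or self.mus < 0:
            raise ValueError("mua and mus must be >= 0")
        if not -1.0 <= self.g <= 1.0:
            raise ValueError("g must be in [-1, 1]")
        if self.n < 1.0:
            raise ValueError("n must be >= 1")


def air_properties() -> OpticalProperties:
    """The non-interacting gap medium between source and tissue."""
    return OpticalProperties(mua=0.0, mus=0.0, g=1.0, n=1.0)


def optical_properties(comp: MediumComposition, wavelength: float,
                       spectra: ChromophoreSpectra,
                       model: ScatteringModel | None = None) -> OpticalProperties:
    """Optical properties of a tissue medium at one wavelength."""
    if model is None:
        model = default_scattering_model()
    return OpticalProperties(
        mua=mua_of_medium(comp, wavelength, spectra),
        mus=mus_of_medium(wavelength, model),
        g=model.g,
        n=TISSUE_N,
    )
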