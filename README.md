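# cortexhsi

Monte Carlo simulation of near-infrared (780–900 nm) hyperspectral imaging
(HSI) of the exposed cerebral cortex, with reconstruction of hemodynamic and
metabolic activity maps.

Wide-field HSI of the exposed cortex promises to separate where hemodynamics
happen (the pial vessels) from where metabolism happens (the subpial gray
matter) by unmixing the spectral signatures of oxy-/deoxyhemoglobin
(HbO2/HHb) and the oxidation state of cytochrome-c-oxidase (oxCCO).
`cortexhsi` is a simulation framework for designing and stress-testing that
measurement: it builds a two-medium voxel phantom (pial vasculature over
gray matter), propagates weighted photon packets from a wide-field source
through it at up to 121 wavelengths, records per-pixel intensities and
per-medium photon pathlengths, and inverts the modified Beer–Lambert law
(MBLL) pixel by pixel,

    ΔA(λ) = −log10 I_hyp(λ)/I_base(λ)
          = PL(λ) · [ εHbO2(λ)·Δ[HbO2] + εHHb(λ)·Δ[HHb] + εdiffCCO(λ)·Δ[oxCCO] ],

solving the M×3 system by pseudoinverse for the concentration changes
between a baseline and an acute-hypoxia condition (ΔS = −35 %, +30 % total
hemoglobin, −3 μM oxCCO → redCCO).  Because detected photons travel mostly
in gray matter, vascular changes are strongly underestimated; the package
implements the selective partial-pathlength correction that rescales vessel
pixels by CF′ = ⟨PL_total/PL_vessel⟩_λ (and gray pixels by the analogous
CF″), plus four end-to-end studies: full 121-wavelength imaging, reduced
wavelength sets (25 and an optimal 8), metabolic-only / hemodynamic-only
ablations, and a localized 0.2×0.2 mm illumination-and-detection
configuration.

It is aimed at researchers designing benchtop HSI/bNIRS instruments for
small-animal neuroimaging who need to quantify crosstalk and
partial-pathlength effects before building hardware.

## Worked example

Run the wavelength-optimized imaging study (8 wavelengths, two conditions,
2×10⁵ photon packets per wavelength, procedural one-major/one-minor-vessel
phantom) and print the region-of-interest accuracy table:

```python
from cortexhsi.studies import StudyConfig, run_study

config = StudyConfig.for_study("2", master_seed=1, detector_downscale=5)
report = run_study(config)
print(report.to_frame().to_string(index=False))
```

```
study         roi chromophore  corrected  theoretical_uM     mean_uM     std_uM  error_percent
    2 vasculature        hbo2      False        -465.120  -58.562418  47.975616      87.409181
    2 vasculature         hhb      False        1162.800  134.503579  38.815340      88.432785
    2 vasculature       oxcco      False           0.000    0.050389  29.586850            NaN
    2 gray_matter        hbo2      False         -17.442  -21.743416   4.349501      24.661256
    2 gray_matter         hhb      False          43.605   51.583396  15.506033      18.296975
    2 gray_matter       oxcco      False          -3.000   -3.444627   4.595837      14.820889
    2 vasculature        hbo2       True        -465.120 -776.472834 681.947011      66.940324
    2 vasculature         hhb       True        1162.800 1693.946850 596.463029      45.678264
    2 vasculature       oxcco       True           0.000    0.050389  29.586850            NaN
    2 gray_matter        hbo2       True         -17.442  -21.787325   4.394474      24.912996
    2 gray_matter         hhb       True          43.605   51.685747  15.607273      18.531699
    2 gray_matter       oxcco       True          -3.000   -3.452005   4.612601      15.066849
```

Reading the table: uncorrected vascular Δ[HbO2] recovers only −59 μM of the
true −465 μM (the partial-pathlength effect — detected photons spend ~90 %
of their path outside the vessel), while gray matter is already within
~15–25 % at this reduced photon budget.  The correction multiplies vessel
pixels by CF′ ≈ 10–13 and restores the vascular estimates to the right
order of magnitude (−776 μM), though with a substantial overshoot whose
origin is analyzed in `docs/methods.md`.  The localized configuration
(study `"4"`) quantifies gray matter far better — Δ[HbO2]/Δ[HHb] to 0.6 %
and 1.8 % with no correction at the same budget.

The same pipeline is scriptable from the shell:

```sh
cortexhsi phantom --seed 7 --out mask.png
cortexhsi study --study 2 --seed 1 --out results/study2
cortexhsi compare --seed 1 --photons 200000
```

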