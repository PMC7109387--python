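# Methods

`cortexhsi` simulates near-infrared (NIR, 780–900 nm) hyperspectral
reflectance imaging of an exposed-cortex preparation — pial vessels lying on
subpial gray matter — and reconstructs per-pixel changes in oxygenated
hemoglobin (HbO2), deoxygenated hemoglobin (HHb) and the oxidation state of
cytochrome-c-oxidase (oxCCO) between a baseline and an acute-hypoxia
condition.  This note records the model, the numerical choices, and what the
synthetic phantom does and does not represent.

## Optical-property model

Each medium is a mixture of water, fat, hemoglobin and (in gray matter only)
the two CCO redox pools.  Its absorption coefficient is the sum of the
chromophore contributions,

    μa(λ) = W·μa,H2O(λ) + F·μa,fat(λ)
            + ln(10)·[ εHbO2(λ)·[Hb]·B·S + εHHb(λ)·[Hb]·B·(1−S)
                       + εoxCCO(λ)·[oxCCO] + εredCCO(λ)·[redCCO] ],

with the extinction coefficients decadic (M⁻¹cm⁻¹, hence the ln 10), blood
concentrations scaled by the blood volume fraction B and oxygen saturation
S, and CCO treated as a tissue chromophore (not scaled by B).  The packaged
chromophore table covers 780–900 nm at 1 nm; values between grid points are
linearly interpolated and the range is never extrapolated.  This convention
reproduces the tabulated vascular μa(835) = 0.5559/0.6492 mm⁻¹ to <0.2%.
For the dilute gray-matter mixture it lands ~5% below the tabulated
0.0275/0.0294 mm⁻¹; the exact weighting used for that printed value is not
recoverable, so the gray-matter entries are treated as approximate and the
model, not the printed number, defines the simulated medium.

Scattering is condition-independent and identical in both tissue media:
μs(λ) = a′(λ/500 nm)^(−b) / (1−g) with the brain-typical scattering power
b = 1.611, anisotropy g = 0.9 and refractive index n = 1.365.  The amplitude
a′ is calibrated once so that μs(835 nm) = 9.1841 mm⁻¹, the value shared by
all media and conditions; both parameters are exposed.

Hypoxia is parameterized as ΔS = −35 %, a +30 % rise in total [Hb]
(cerebral blood volume increase), and a −3 μM swing of oxCCO into redCCO
confined to gray matter (the CCO pool is conserved).  The implied
"theoretical" tissue-concentration changes are ΔHbO2 = −465.1 μM and
ΔHHb = +1162.8 μM in the vessels and (−17.44, +43.61, −3) μM in gray
matter; these are the reference values for all accuracy figures.

## Phantom

The domain is a 2.4 × 2.4 × 1.0 mm voxel slab (default 10 μm voxels), gray
matter throughout except for a vessel layer occupying the top 0.1 mm of the
central 1.2 × 1.2 mm field of view.  The in-plane vessel pattern is a binary
mask — procedurally generated by default (random-walk centerlines rasterized
to ~100 μm major and ~20 μm minor calibres via a distance transform), or
read from a single-channel PNG/TIFF.  The mask is extruded into 3-D with a
lens-like profile: at signed depth dz from the layer mid-plane the mask is
eroded by the circular-segment inset h − √(h²−dz²), h = 0.05 mm, so a
100 μm vessel acquires an approximately circular cross-section.  The erosion
profile is a modelling choice; only "widest at the mid-plane, symmetrically
eroded toward the faces" is constrained by the construction this phantom
emulates.

The synthetic mask stands in for a manually segmented in vivo microscope
image.  It reproduces vessel calibres, areal coverage (~10 %) and surface
placement, but not the branching topology, calibre variation or density of a
real pial network — the quantitative correction results below are sensitive
to exactly those unobserved properties.

## Photon transport

Weighted-photon (continuous-absorption) Monte Carlo on the voxel grid,
single-threaded, with per-photon splitmix64 substreams derived from the
stream seed and launch index — results are bitwise-reproducible and
independent of batch size.  A voxelized domain replaces tetrahedral-mesh
transport: with the same μa, μs, g, n, source and detector the physics is
equivalent, and exact ray–voxel segment splitting (3-D DDA) preserves the
per-medium partial-pathlength bookkeeping that the reconstruction depends
on.

* Source: 0.6 × 0.6 mm plane 0.5 mm above the surface; a "90° beam
  divergence" is modeled as a cone of half-angle 45° about the normal.
  Entry points cover the illuminated 1.2 × 1.2 mm section uniformly (the
  stated illumination), with each photon's direction drawn by rejection from
  the source aperture within the cone; the collimated limit falls back to
  uniform sampling of the source footprint.  Photons specularly reflected at
  first contact never enter tissue and are not detected.
* Propagation: step lengths −ln u/μs (μs is medium-independent here), weight
  attenuated by exp(−μa·ℓ) per traversed voxel segment with ℓ accrued to
  that voxel's medium; unpolarized Fresnel reflection/refraction at the
  n = 1/1.365 top surface decides detection; lateral and bottom faces absorb
  (the slab margin keeps boundary losses away from the FOV); Russian
  roulette below weight 1e−4 with survival probability 0.1.
* Energy bookkeeping closes to ~1e−14: launched = detected + absorbed +
  escaped + specular + roulette-killed.

**Common random numbers across conditions.**  Baseline and hypoxia share
one photon stream per wavelength.  Scattering, anisotropy, refractive index
and geometry are identical in the two conditions — only μa changes — so the
shared trajectories are exact for both, and the attenuation-change ratio
ΔA = −log10(I_hyp/I_base) is computed photon-by-photon on the same paths.
This cancels the shot noise that would otherwise exceed the ~0.002-decadic
gray-matter signal by orders of magnitude at any affordable photon count;
it is the standard reweighting trick enabled by recording partial
pathlengths.  Wavelength subsets reuse the streams of the corresponding
wavelengths of denser runs, so wavelength-set comparisons are also paired.

## Imaging and reconstruction

Detected photons are binned by exit position into the detector grid
(185×185 pixels over the 1.2×1.2 mm FOV; 0.2×0.2 mm FOV in the localized
configuration).  Per pixel: intensity = Σ weights; pathlength maps =
weight-weighted mean total and per-medium partial pathlengths.  Pixels with
no detections are NaN and are excluded, never imputed.  Per-wavelength maps
stack into hypercubes (121, 25 or 8 wavelengths).

The modified Beer–Lambert law is inverted per pixel: ΔA(λᵢ) = PL(λᵢ)·
[εHbO2, εHHb, εdiffCCO](λᵢ)·ΔC, where PL is the per-pixel mean between the
two conditions' average total pathlengths (mm → cm inside the solver) and
εdiffCCO is the tabulated oxidized-minus-reduced difference spectrum, used
exactly as tabulated.  The least-squares solution over the M wavelengths is
computed from the 3×3 normal equations (equivalent to the Moore–Penrose
pseudoinverse of the pathlength-scaled extinction matrix); a pixel missing
any wavelength stays missing, and a rank-deficient spectral system raises
with its condition number.

**Partial-pathlength correction.**  Detected photons travel almost entirely
in gray matter (>97 % of the average total path), so total-pathlength MBLL
underestimates vascular changes by roughly the vessel path fraction.  The
correction builds per-pixel factor maps CF′ = mean over wavelengths of
PL_total/PL_vessel and CF″ = mean of PL_total/PL_gray (each computed per
condition, then averaged across the two), and multiplies: vessel pixels —
Δ[HbO2], Δ[HHb] by CF′, the metabolic map untouched (no CCO is simulated in
vessels); gray pixels — all three by CF″ (a near no-op, CF″ ≈ 1).  The
mask-to-pixel registration uses majority vote with ties counted as vessel.

### Known quantification limits

Two structural effects bound the achievable accuracy and are measured, not
hidden:

* **Difference-spectrum mismatch.**  The simulation deposits CCO absorption
  through εoxCCO and εredCCO, while the unmixing uses the independently
  measured εdiffCCO column, which is not their difference.  With perfect
  pathlengths a −3 μM oxCCO swing reads as −3.19 μM (+6.2 %) at the 8
  optimal wavelengths.  Measured localized-FOV oxCCO errors (~6.5–9 %) sit
  on this floor; hemoglobin in the same configuration recovers to 0.6–2 %.
* **Correction overshoot.**  In an unbiased reconstruction the
  MBLL-effective vessel path fraction equals 1/CF′ (verified on this
  phantom: 0.1015 vs 0.1000), so the corrected vessel estimate is inflated
  by the gray-matter term: corrected/true ≈ 1 + (PL_gray/PL_vessel)·
  (ΔC_gray/ΔC_vessel) ≈ 1.3 here.  The correction restores the order of
  magnitude of the vascular deltas (×~10) but its few-percent published
  accuracy depends on the geometry and noise regime of the specific
  vasculature being imaged; on this synthetic phantom the corrected vessel
  errors settle near +30 %.

## Desk-scale protocol

The reference photon budget (3×10⁷ packets/wavelength) is a single config
knob; the default study scale is 2×10⁵/wavelength, at which a full
two-condition 8-wavelength study runs in seconds.  At that budget the
native 185² grid would catch <1 photon/pixel, so scaled-down runs divide
the grid by `detector_downscale = 5` (37×37 pixels, ~12 photons/pixel —
the same per-pixel statistics regime as the reference scale) and shrink the
ROIs by the same factor so their physical size (65×65 μm) is unchanged.
The wavelength-set consistency analysis (8 vs 121 wavelengths on matched
streams) is run on the vessel-free localized target with an 18×18 grid,
where the comparison is free of vessel-crossing noise and resolves the
0.5 %-level wavelength-set effect at 2×10⁵ photons/wavelength.  The
ablation checks (metabolic-only, hemodynamic-only) assert residuals on
whole-region means for the same reason.

## Numerical details worth knowing

* Half-open pixel and voxel intervals everywhere; a photon exactly on the
  FOV's max edge is dropped.
* The Henyey–Greenstein inversion is used for deflection cosines
  (E[cos θ] = g); azimuth is uniform.
* Roulette threshold/survival, step cap, and mirror-wall test boundaries are
  exposed in `TransportOptions`; the step cap (10⁶) is a safety net that
  never triggers in practice and is tallied separately if it does.
* Degenerate inputs raise early: empty wavelength sets, non-binary masks,
  ROI windows out of bounds or fully missing, vessel widths under one pixel,
  voxel sizes that do not divide the slab.
* Reflectance in the diffusion regime was validated against an
  independently coded dipole diffusion-approximation oracle (5 %), the
  ballistic limit against Beer–Lambert (1e−12), and sampling statistics
  against closed-form moments.
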