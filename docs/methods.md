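# Methods

This note documents the physical models, parameter choices, numerical
methods, and known limitations of `cliquant`. Units are mm/cm as stated,
MBq for activity, Gy for dose; planar images are photons/s/cm²/sr.

## 1. Tissue optics (`optics`)

Tissue absorption is a volume-fraction mixture of bundled chromophore
spectra (oxy/deoxyhemoglobin, water, fat, 400–1000 nm):

```
mu_a(λ) = B [ S mu_a_oxy + (1−S) mu_a_deoxy ] + W mu_a_water + F mu_a_fat
```

The default skin composition is a published murine skin parameterization:
blood fraction B = 0.0034, oxygen saturation S = 0.985, water W = 0.214,
fat F = 0.277, reduced scattering amplitude a′ = 48 cm⁻¹ at 500 nm,
Rayleigh fraction fRay = 0.409, Mie power b = 0.702, refractive index
n = 1.4. Scattering splits into a Rayleigh term a′·fRay·(λ/500)⁻⁴ and a Mie
term a′·(1−fRay)·(λ/500)^−b (19.632 and 28.368 cm⁻¹ at 500 nm
respectively). Anisotropy uses a double Henyey–Greenstein phase function:
forward lobe g_f = 0.91 sampled with probability 0.85, backward lobe
−g_b = −0.87 otherwise.

**Modeling choice.** The published parameterization gives *reduced*
scattering coefficients. The Monte Carlo uses these directly as interaction
coefficients while also sampling the anisotropic phase function, which makes
the simulated medium effectively more diffusive than a
similarity-transformed one. This is the single largest systematic of the
transport model; it widens shallow-depth spread functions by roughly 20%
relative to the reference widths while staying well inside the declared
±25% acceptance band, and it affects forward and inverse modeling
identically, so activity quantification is unaffected.

## 2. Cherenkov emission and positron transport (`cherenkov`)

Cherenkov emission requires β > 1/n; for electrons this is a kinetic-energy
threshold K = 511(n/√(n²−1) − 1) keV = 219.2 keV at n = 1.4. The photon
yield per path length in the 400–1000 nm band follows the Frank–Tamm
expression 2πα (1/λmin − 1/λmax)(1 − 1/(β²n²)), i.e. 336.9 photons/cm at
β → 1 in water-like media with n = 1.4.

Beta spectra are stored as (endpoint, intensity) branch tables; branch
energies are drawn by rejection sampling from the allowed-shape
distribution with the Fermi function approximated to first order. Positrons
follow a condensed-history continuous-slowing-down (CSDA) track: 0.01 cm
steps, energy loss integrated with a midpoint evaluation of the water
collision stopping power (second-order accurate; simulated track lengths
match tabulated CSDA ranges within 2% from 100 keV to 2 MeV), and a
Highland-formula multiple-scattering deflection per step. Photons are
emitted along the track at the local Cherenkov angle cos θ = 1/(βn) with
uniform azimuth, with per-step counts drawn from the local Frank–Tamm
yield.

## 3. Spread-function Monte Carlo (`csf_mc`)

Geometry: a 2×2×2 cm tissue cube in air, source on the axis at depth d below
the top face, and a thin (0.1 cm) scoring slab at the top surface. Each
photon random-walks with exponential free paths of the total interaction
coefficient at its wavelength; at each interaction the event type
(absorption, Rayleigh, Mie) is chosen proportionally to the coefficients,
and the scattering cosine is sampled isotropically (Rayleigh approximation)
or from the double Henyey–Greenstein (Mie). Photons crossing the top plane
are recorded list-mode as (x, y); bookkeeping guarantees
emitted = recorded + absorbed + escaped.

Crossings are binned on a centered odd-dimensioned grid (0.554 mm pixels by
default, matching 8×8 hardware binning of a 13.4 cm field over 1945 px).
The FWHM estimator azimuthally averages the kernel in one-pixel annuli,
fits a weighted non-increasing isotonic sequence (pool-adjacent-violators)
so that the sparsely sampled central annuli cannot inflate the apparent
peak, refits the flat top with a weighted parabola in r² when at least four
annuli lie inside 0.4× the half-max radius, and interpolates the half-max
crossing linearly. With optics disabled, an isotropic point source at depth
d produces a surface flux d/(2π(d²+r²)^{3/2}) whose binned FWHM is
2d√(2^{2/3}−1) = 1.533 d — the suite verifies this analytic oracle within
3% at 2, 5 and 10 mm.

Measured widths with full optics: ≈3.5 mm FWHM at 2 mm depth and ≈12.2 mm
at 10 mm depth, growing monotonically and near-linearly across 2–10 mm
(Pearson r > 0.98). `scripts/acceptance.py` recomputes both from scratch.

## 4. Depth calibration (`quantify`)

The calibration phantom is a 96-well plate: five activities (0, 0.185,
0.370, 0.925, 1.850 MBq) in triplicate under six liquid depths
(1.66–9.93 mm). Stage 1 regresses radiance on areal activity concentration
(µCi/cm², well growth area 0.34 cm²) at each depth by weighted least
squares with the measurement error model var = (cv·radiance)² +
background_spread² (defaults 5% and 307); the slope is the per-depth
calibration coefficient. Stage 2 regresses the coefficients on depth,
giving the linear curve c(d) = 9734.2 − 613.8·d (radiance per µCi/cm², d in
mm) with Pearson r ≈ −0.98. The instrument background (7902 ± 307
photons/s/cm²/sr, open filter) is subtracted before fitting, floored at
zero; estimates whose ROI is mostly floored carry a below-sensitivity flag.

**Operational meaning of c(d).** The coefficients are measured on *blurred
images of extended sources*: the well radiance includes the lateral spread
of the liquid column. c(d) therefore converts the observed in-footprint
mean radiance of an extended source at depth d — not the unblurred surface
fluence — into concentration. The synthetic forward model preserves this
semantics (section 7), which is why the noiseless no-deconvolution round
trip is exact for isolated organs.

ROI activity = mean(reconvolved radiance / c(depth)) × ROI planar area ×
0.037 MBq/µCi; out-of-range depths raise unless extrapolation is explicitly
enabled (the whole-body estimate enables it, see section 8).

## 5. CT geometry (`geometry`)

Volumes are indexed (lateral, depth, longitudinal) with the camera looking
along the depth axis; planar images are (lateral, longitudinal). The body
mask is HU ≥ −700 reduced to its largest connected component; the camera
view is its maximum-intensity projection. The ROI depth map assigns each
planar pixel the mean (ROI-voxel depth − surface depth) of its projection
column, in mm. Optical-to-CT registration is a 2-D similarity transform
(scale, rotation, translation) estimated on lightly smoothed binary masks
with a mean-squares metric and regular-step gradient descent (learning rate
0.2, relaxation 0.6, moments initialization); it is deterministic and
reports its metric history and convergence flag. Prone/supine conversion
is a 180° rotation about the longitudinal axis (involutive).

## 6. Depth-weighted deconvolution (`deconv`)

Each ROI's kernel weights come from its depth histogram: weight(depth) ∝
(ROI pixels nearest that kernel depth) × (kernel intensity factor), with
the intensity factor defaulting to the fraction of kernel counts inside its
FWHM (a "peak" option exists). Weights are normalized to 1.

Richardson–Lucy deconvolution runs once per kernel depth and the results
are weight-averaged. The RL data term is masked: pixels outside the body
footprint are unobserved, and the kernel mass is renormalized by the
in-mask response conv(mask, g̃) so flux does not leak across the boundary.
Numerical safeguards, each verified by a dedicated invariant test:

- the image is padded by the kernel size with **zero-weight** pixels, making
  a flat image an exact fixed point regardless of boundary content;
- the iterate starts **flat** at the observed mean — starting from the data
  leaves exact zeros that multiplicative updates can never repopulate, and
  the guarded ratio then diverges at the edge of the zero region;
- iterates are clamped non-negative (FFT round-off can push the correction
  slightly negative, which otherwise destabilizes the iteration);
- unobserved pixel values are replaced by the observed mean before
  iterating, so results are independent of garbage outside the mask.

After deconvolution the image is masked to the ROI projection and
*reconvolved* with the same weighted kernel set, returning to the blurred
image space in which c(d) was measured.

**Iteration count.** The library default is 10 iterations. On the synthetic
study the multiplicative updates are still far from convergence at 10
iterations (organ estimates low by 15–40%); the study harness and the
acceptance suite therefore run 150 iterations, where recovery plateaus
(liver within ~6%, tumor within ~14%). This is a convergence requirement of
the masked RL variant on these image sizes, not a tuning parameter; the
default is kept at 10 for API compatibility with the documented workflow.

## 7. Synthetic data (`synthdata`)

- **Well plate**: radiance = c(depth) × concentration × (1 + cv·ε) +
  background(level 7902, spread 307); zero-activity wells emit background
  only; deterministic per seed.
- **Mouse phantom**: ellipsoidal body (semi-axes 12×12×40 mm, ~25 g mouse),
  liver ellipsoid (5×3×6 mm semi-axes, centroid ~4 mm deep) and a 2.5 mm
  radius tumor sphere (centroid ~2.6 mm deep), ≥5 mm apart in the image
  plane so spread-function cross-talk is present but separable. Raises on
  organ overlap or protrusion.
- **Forward CLI image**: each compartment is filled uniformly at its planar
  concentration, mapped through c(depth) pixel-by-pixel, blurred with its
  depth-weighted kernel average, then rescaled so the in-footprint mean
  equals c(d) × concentration (the operational definition of c(d),
  section 4). Compartments sum; multiplicative Gaussian noise (CV 5%
  default; a Poisson-scaled option exists) and the background field are
  added last. The model is linear in activity before noise.
- **PET-like volume**: uniform compartment filling + 1.5 mm FWHM Gaussian
  blur + optional noise; total activity conserved. ROI readout re-captures
  spill-out by dilating the ROI 1.6 mm (dilated ROIs stay disjoint at
  ≥5 mm organ separation).
- **Study**: four timepoints (3.5, 29, 52, 97 h) of 9.25 MBq injected, with
  single-exponential biological washout per compartment on top of ⁸⁶Y decay.

**Realism limits** (deliberate): the forward optical model is the exact
inverse of the quantification model — it validates the pipeline's internal
consistency, not the transport model; no surface curvature, no spatially
varying optics, no structured autoluminescence, no camera optics (f-number
and exposure are carried as metadata only), no PET attenuation/scatter. The
study generator emits no white-light photograph, so the study harness runs
with registration disabled (images are already in the CT frame); the
registration stage is exercised separately on synthetic masks.

## 8. Dosimetry (`dosimetry`)

The total-body curve is modeled bi-exponentially (multi-start nonlinear
least squares over a fixed rate grid; deterministic); the remainder
compartment is modeled total − liver − tumor, clamped at zero with a
warning. The whole-body activity estimate from the planar image
overestimates (the organ radiance is dominated by shallow structures while
the body depth map averages full columns); it only shapes the remainder
compartment and does not affect liver/tumor doses under local deposition.

The imaging surrogate's time-activity curves convert to the therapy
isotope by preserving biological retention: r(t) = A(t)·e^{+λ_img t},
re-decayed with λ_therapy (⁸⁶Y 14.74 h → ⁹⁰Y 64.05 h), assuming equal
administered activities.

Dose rates use a **local-deposition** engine: every voxel's emitted energy
is absorbed in that voxel, rate = A·E_mean·1.602×10⁻¹³/mass × 3600 Gy/h
(1 MBq of ⁹⁰Y, mean beta energy 0.9337 MeV, in 1 g gives 0.5385 Gy/h).
This ignores beta crossfire between compartments and is flagged in every
output (`"local-deposition"` in the provenance and report). Time
integration is trapezoidal across the timepoints, plus a constant-rate head
from t = 0 to the first timepoint and an analytic physical-decay tail
(last rate / λ); on a mono-exponential curve sampled at the study
timepoints this is within 1% of the closed form. Unit density inside the
body is assumed unless a density volume is provided.

On the synthetic study, the CLI-arm (3 planar timepoints + modeled total)
and PET-arm (4 volumetric timepoints) agree within ~1% for liver and ~10%
for tumor Gy/MBq — inside the activity-recovery tolerance.

## 9. Numerical and reproducibility choices

- The photon/positron core is `numba`-compiled with explicit integer
  seeding; every generator and pipeline is deterministic per seed, and all
  outputs carry a `ProvenanceRecord` (tool version, config hash, seeds,
  approximation flags, timestamp).
- Convolutions are FFT-based; deconvolution tolerances, padding and clamps
  are described in section 6.
- Default pixel size is 0.554 mm; the synthetic study uses a 0.4 mm grid
  (voxel count vs runtime compromise; kernels must be simulated at the
  image pixel size).
- File formats: HDF5 kernel archives, NIfTI volumes, float32 TIFF planar
  images with JSON sidecars, CSV tables, JSON results/curves, YAML config.

## 10. Known limitations

1. Condensed-history positron transport (no secondary electrons or
   bremsstrahlung) and the reduced-coefficient scattering choice widen
   shallow spread functions ~20% relative to full radiation-transport
   codes.
2. Local-deposition dosimetry has no crossfire; small-structure doses are
   upper bounds.
3. The planar whole-body estimate is biased high (section 8); treat it as a
   clearance-shape input only.
4. The synthetic study validates internal consistency, not absolute
   radiometric accuracy; no real instrument data are bundled.
5. Registration is 2-D similarity only — no deformation, no out-of-plane
   correction.
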