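# Methods

`transocular` models a transmission interference microscope for the anterior
human eye.  The instrument projects a near-infrared LED spot through the
pupil onto the sclera; the diffusely back-scattered patch acts as a
*secondary source* that trans-illuminates the cornea and crystalline lens
from behind.  The size of that patch plays exactly the role of the condenser
aperture in classical transmission microscopy: a small patch gives low
illumination NA, high spatial coherence and strong interference (dark/bright)
contrast of transparent structures; a large patch trades contrast for
lateral resolution.  The package implements the closed-form optics of this
trade-off, the ocular light-safety budget of the pulsed illumination, a
wave-optics simulation of the imaging principle, the raw-frame processing
chain, and the morphometric quantification, with seeded phantoms standing in
for patient data.

## Closed-form optics (`optics`)

The chain is four closed-form steps applied in sequence:

1. **Spot projection.** The LED (visible size 1.8 mm, the die magnified by
   its dome) is relayed by a lens pair (magnification f2/f1) and demagnified
   by the objective/eye pair (f_eye/f_obj):
   `d_spot = d_src · (f2/f1) · (f_eye/f_obj)`.  An aperture in front of the
   LED replaces the LED as the projected object.
2. **Scleral diffusion.** A Gaussian random-walk model of the double pass
   through the scleral wall: `D = 2·sqrt(sigma0² + 2·z·l*)` with
   `sigma0 = d_spot/2`, wall thickness `z = 1 mm`, and transport mean free
   path `l* = 1/mu_s'` from the reduced scattering coefficient
   `mu_s' = 30 cm⁻¹`.
3. **Illumination NA.** The diffuse patch sits one eye length `L = 23 mm`
   behind the anterior segment, inside media of index `n = 1.4`:
   `NA_i = n·sin(arctan((D/2)/L))`.
4. **Effective NA and resolution.** `NA_eff = (min(NA_i, NA_d) + NA_d)/2`
   (illumination outside the detection cone is never collected, so NA_i is
   clamped at NA_d *inside* `effective_na`, keeping `illumination_na` purely
   geometric), then `Δx = 0.61·λ/NA_eff` and `DOF = n·λ/NA_eff²` at
   λ = 0.85 µm.

All lengths are millimetres internally, wavelengths and resolution outputs
micrometres — the units in which every formula above is conventionally
written.  Relay magnification is ideal thin-lens; aberrations are out of
scope.  The étendue lower bound on the spot size is exposed as an
informative diagnostic only (`etendue_bound`); it enters no computation.

Eye presets: `adult` (23 mm / 17 mm), `child` (shorter globe, 15 mm focal
length, which yields the 1.5 mm retinal spot used in the paediatric safety
margin), `artificial_model` (bench eye with a 25 mm focal length).

## Light-safety budget (`safety`)

The budget follows Group-1-style checks for pulsed NIR illumination with two
deliberate conventions:

- **Area convention.** Spot "area" enters as `(diameter in cm)²`, not the
  circular `π(d/2)²`.  This is forced by the budget's own arithmetic: only the
  square convention reproduces the time-averaged retinal irradiance
  (≈220 mW/cm² for 100 mW at 10% duty over a 1.7 mm spot, weighted by
  R = 0.63) and the 20 s radiant exposure (≈4.4 J/cm²).  A circular-area
  variant exists behind a flag for sensitivity checks but is excluded from
  all validated numbers.
- **Corneal pulse limit.** The corneal radiant-exposure limit is modelled as
  `1.8·t^(1/4) J/cm²` — the unique power law through both anchor values
  used in the budget (1.8 J/cm² at 1 s, ≈3.8 J/cm² at 20 s).  It is a
  reconstruction of the standard's tabulated limit, not a quotation.

Other checks: pulsed retinal limit `(10/d_mm)·t^(3/4)·N_pulses^(-1/4)`
J/cm², CW retinal irradiance limit `1.2/d_mm W/cm²`, fixed corneal
irradiance limit 100 mW/cm².  The spectral weighting coefficient defaults to
R = 0.63 (thermal hazard weighting near 800 nm, applied to the 850 nm
source — the instrument's own convention, kept as-is).  `assess_mode`
evaluates every check for a mode (standard: 10 ms on / 90 ms off;
alternative: 1 s on / 19 s off, with its single-pulse short-time check at
duty 1 and N = 1) and additionally sweeps all assessment windows t ≤ 20 s,
reporting the worst margin.  Margins are limit/value, so they scale exactly
inversely with power.

## Wave simulation (`wavesim`)

A 2D (one transverse dimension) explicit time-domain solver for the scalar
wave equation `u_tt = (c0/n)²∇²u` — leapfrog update, 5-point Laplacian,
CFL number 0.5 (2D limit 1/√2), quadratic-ramp absorbing sponge layers of
3λ at every edge.  Units: vacuum wavelength = 1, optical period = 1.

The 4F bench is reduced to its optical skeleton: soft line source →
random-particle diffuser assembly → wavelength-scale scatterer near the
front focal plane of lens 1 → two-lens 4F relay → camera line.  Since every
phenomenon of interest (Gouy-phase contrast inversion, transmitted/diffracted
separation in the back focal plane, the condenser trade-off) is
scale-invariant, the simulated bench is tens of wavelengths long
(focal length 12–14λ, domain ≈ 90λ × 32λ at λ/10 sampling), not a 23 mm
eye — sizes chosen so a full characterization runs in minutes on one CPU
core.  The properties validated on it are qualitative orderings and sign
changes, never pixel values.

Numerical design choices that required iteration:

- **Lenses.** The primary lens model is a smooth graded-index slab
  `n(x,y) = 1 + A(y)·cos²(πx/2W)` whose integrated optical path equals the
  ideal quadratic lens profile (A(y) ∝ R² − y²).  A literal biconvex glass
  lens (n = 1.5, parabolic thickness) is available (`style="glass"`), but at
  these scales its Fresnel reflections (4% per surface) and thick-glass
  aberrations bury the few-percent interference signal under coherent
  ringing; the graded slab keeps the index near glass values while removing
  both artifacts.  The slab's elevated on-axis index shortens the *reduced*
  distance of each focal gap, so the 4F spacings are stretched by
  `δ = W(1 − 1/√(1+a))` per gap.
- **Aperture.** The system NA is set by a smoothly absorbing stop in the
  Fourier plane (angle maps to height there), with oversized lenses.  A
  hard-edged stop at the lens reflects obliquely incident light and clips
  the illumination envelope; the Fourier-plane stop truncates the angular
  spectrum cleanly.
- **Focus calibration.** Residual higher-order focus error is removed the
  way an experimentalist removes it: `calibrate_focus` scans the scatterer
  through defocus under the system's own illumination and stores the
  contrast zero-crossing as `focus_offset`; scans are then expressed
  relative to that plane.
- **Quasi-incoherence.** Each realization re-randomizes the particle
  assembly *and* drives the source with a transverse random phase screen
  that decorrelates every ~4 optical periods, so time-averaging the camera
  intensity over 40–80 periods averages tens of independent speckle
  patterns per run.  With 4 realizations the no-scatterer camera image is
  uniform to better than 5% relative std — matching the quasi-collimated
  uniform illumination of the bench — at a cost far below running hundreds
  of independent assemblies.  Convergence was checked by doubling both the
  averaging window and the realization count.
- **Diffuser assembly.** n = 1.5 particles of 0.35λ diameter, ~5 per λ² in
  a 4λ-thick band.  This is optically thick enough that the diffuse field
  dominates the residual ballistic beam; with a thin or sparse assembly the
  unscattered plane wave (effectively a point source at infinity) sets a
  contrast floor and masks the source-size dependence.  Particle diameter
  is kept sub-wavelength but slightly above λ/4 because a λ/4 assembly
  dense enough to be opaque multiply-scatters into so wide a halo that the
  equivalent source size saturates.
- **Scatterer.** The contrast-inversion scans use a weak-phase scatterer
  (1λ disc, n = 1.15).  A high-index disc (n = 2.5, the value used for
  clearly visible demonstration figures and for the back-focal-plane
  energy-separation analysis, where strong scattering is the point) is
  extinction-dominated: it images as a dark shadow at every defocus and
  the "invisible at focus, bright/dark on either side" behaviour — a
  weak-phase-object phenomenon, which transparent cells are — does not
  appear.
- **Contrast metric.** `(I_feature − I_ref)/I_ref` at the conjugate pixel,
  with the reference a matched no-scatterer run using the same seeds (same
  assemblies, same phase screens), which cancels residual speckle and the
  illumination envelope.  The equivalent source size is swept by moving the
  assembly (`width/distance`), exactly as on the bench.

## Analytic defocus model (`contrast`)

In the Gaussian-beam picture the interference term of a point scatterer
defocused by z is the imaginary part of the complex defocus factor
`1/(1 − iz/z_R)`:

    m(z) = A·(z/z_R)/(1 + (z/z_R)²)

— antisymmetric, extrema at ±z_R (so their separation is the DOF = 2 z_R),
with a built-in Lorentzian axial envelope.  This specific functional form is
a modelling choice; any antisymmetric Gouy-phase profile with an axial
envelope would serve, and the model is validated against the three
properties it must have (zero at focus, antisymmetry, extrema one DOF
apart), not fitted to data.  An illumination angle θ shears the pattern
laterally by z·tanθ; the on-axis pixel sees the profile attenuated by the
Gaussian beam envelope at that shear.  An extended incoherent source is a
weighted sum of tilted profiles over the disc (chord-weighted 1D marginal,
65 angular samples by default; halving/doubling the sampling changes the
summed contrast by < 1%).  The sum reproduces both halves of the condenser
trade-off: peak-to-trough contrast falls monotonically with source
diameter, and the axial FWHM of the modulation grows as NA_eff shrinks.
`z_R` defaults to half the detection-limited DOF (NA_eff = NA_d/2, the
point-source limit).

The bench normalization is mirrored in `normalize_profiles`: all axial
profiles are affinely mapped by the min/max of the most contrasted
(smallest-source) condition, which therefore spans [0, 1] exactly.

## Image pipeline (`pipeline`)

The chain per camera type, in the order enforced by `process_stack`:

- colour rolling-shutter camera: 3×3 Gaussian blur (σ = 0.8 px,
  kernel-limited to the stated 3×3 support) to even out the Bayer-segment
  gain checkerboard;
- mono global-shutter camera: fixed-pattern removal by subtracting the
  per-pixel temporal mean of a stack of *moving* frames (the motion blurs
  scene content out of the mean while the static sensor pattern survives
  and cancels exactly);
- both: high-pass with a large 121×121 kernel — subtract-the-boxcar-mean by
  default, Gaussian variant behind a flag — to strip the bright uniform
  transmission background; reflect padding throughout;
- optional frame averaging (√n noise reduction), with translation-only
  registration by phase cross-correlation available but off by default
  (synthetic validation stacks are generated pre-registered; on circularly
  shifted phantoms, alignment wraps edge content and does more harm than
  good at large shifts);
- pulse synchronization: a software rolling buffer keeps the frame with the
  highest mean intensity (ties to the earliest), standing in for a hardware
  trigger;
- tomography: subtraction of two co-registered frames at opposite defocus
  (gain-matched by median ratio), which doubles structures that flip sign
  between the phases and cancels the defocus-symmetric background.

## Quantification (`quantify`)

- **Cell detection/density.** Because interference contrast renders cells
  bright on one side of focus and dark on the other (both signs in one
  image when the cornea curves through focus), counting is restricted to one
  contrast sign within the region where that sign dominates, and density is
  count/area of that region; edge cells count iff their centre is inside.
  Detection is local-maximum picking at the expected cell scale (smoothing
  at diameter/8, minimum separation 0.4 diameter) with a threshold relative
  to the robust deviation range, making it invariant to affine intensity
  changes.
- **Nerve length density.** Total centreline length per area (mm/mm²);
  polylines are summed directly, skeleton masks are measured with Kulpa's
  corrected link weights (0.948 orthogonal, 1.340 diagonal), which remove
  the ~5% over-estimation of the naive (1, √2) chain estimator.
  `trace_nerves` (threshold + small-object removal + skeletonization)
  replaces the neural-network segmentation used clinically, which is out of
  scope here.
- **SNR.** `20·log10(mean(signal ROI)/std(noise ROI))` — an amplitude-ratio
  convention, chosen and documented because the measurement itself does not
  state one; `power=True` gives the 10·log10 variant.
- **Diameter.** Arithmetic mean of measured diameters.

## Phantoms (`phantoms`)

All generators are deterministic given the seed, and every metric can be
scored from the returned ground truth without touching pixels.

- **Endothelial mosaic.** Jittered hexagonal point process at the target
  density (jitter σ = 0.10 of the lattice constant — healthy endothelium is
  quite regular; stronger jitter creates unresolvable cell pairs that no
  counting method, human or automatic, could separate), nearest-centre
  partition, each cell rendered as a Gaussian bump at its own centre.  The
  modulation sign and strength follow the same Gouy law as the analytic
  model, driven by a smooth curvature-like z-offset field passed through a
  sigmoid so that most of the field sits clearly above or below focus with
  a narrow invisible transition band at the crossing — as in real
  endothelial fields, where a thin band of cells at exact focus disappears.
  Supported density range 500–6000 cells/mm².
- **Nerve layer.** Random-walk strokes of bounded curvature (~2 px steps,
  heading σ = 0.12 rad) and 1–5 µm width, added until the total length per
  area is within 2% of the target; the stroke list is the ground truth.
- **Scatterer stacks.** Point scatterers rendered through
  `contrast.incoherent_sum_profile` at each focal offset — phantoms and
  theory share one defocus law — with a lateral footprint that widens with
  defocus; a smaller secondary source keeps scatterers visible over more
  slices.
- **Camera artifacts.** Static fixed-pattern field (60% smooth + 40%
  per-pixel, scaled to the requested RMS, shared across a stack),
  multiplicative period-2 Bayer gain map, and per-frame Gaussian noise
  (Poisson shot noise optional).  The injected fields are returned for
  oracle tests.

What the phantoms do *not* emulate: real corneal texture, guttae and other
pathology, motion blur within a frame, rolling-shutter skew, and the actual
noise spectra of the two cameras.  Passing the recovery tests therefore
shows that the processing chain and estimators are unbiased under the
stated artifact model, not that they meet clinical accuracy on patient
images.

## Problem sizes of the validation runs

Chosen so the whole suite runs comfortably on one CPU core: phantom
recovery uses 0.5×0.5 mm fields at 1 µm/px over 20 seeds (~800 cells or
5.5 mm of nerve per field); wave-optics validation uses the reduced bench
above with 3 realizations × 40 averaged periods per scan point, 13 defocus
points per scan and 3 source sizes; the uniformity check uses 4
realizations × 80 periods.  Doubling any of these changes no conclusion
(checked during development).

## Known limitations

- The closed-form NA_eff = (NA_i + NA_d)/2 is itself an approximation whose
  validity depends on the scattering regime of the imaged structures; no
  alternative closed form is implemented.
- The 2D scalar solver cannot represent polarization (and thus
  cross-polarized specular rejection) or 3D speckle statistics.
- The safety module implements exactly the checks of the two clinical
  modes, not the full ISO 15004-2 dual-limit system across all wavelengths.
- Quantification thresholds are tuned for phantom contrast levels; real
  images need per-dataset threshold review.
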