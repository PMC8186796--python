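# Methods

## Sedimentation velocimetry of spheroids

A spheroid released in a quiescent vertical fluid column accelerates until its
buoyant weight balances viscous drag and then settles at a constant terminal
velocity. Modeling the aggregate as a rigid sphere of radius `r` and mass
density `ρ_s` in a fluid of density `ρ_f` and dynamic viscosity `μ`, the
creeping-flow (Stokes) balance gives

    v_t = (2/9) (ρ_s − ρ_f) g r² / μ,

so a measured `(v_t, r)` pair determines the mass density

    ρ_s = ρ_f + 9 μ v_t / (2 g r² K),

and from it the mass `ρ_s·(4/3)πr³` (reported in µg) and the buoyant weight
`(ρ_s − ρ_f)·(4/3)πr³·g` (reported in nN). `K` is an optional on-axis
cylindrical wall correction

    K(λ) = 1 − 2.104 λ + 2.089 λ³ − 0.948 λ⁵,  λ = r/R,

for a channel of radius `R`; it is **off by default** (the unbounded-fluid
model is the simplest defensible choice, and no calibration against a real
channel is available), and turning it on rescales all absolute densities by
`1/K`. The model assumes a rigid, impermeable, homogeneous sphere, a
quiescent Newtonian fluid, and the Stokes regime; a particle Reynolds number
`Re = ρ_f |v_t| (2r)/μ > 0.5` (where Stokes drag is ~5% off) attaches a
`stokes_regime_violated` QC flag rather than rejecting the measurement.
Spheroid diameters outside the 50–500 µm operative range are likewise flagged
(`outside_operative_range`), not refused.

The transient is modeled by `physics.settle_ode`, which integrates

    m dv/dt = (ρ_s − ρ_f) V g − 6πμ r v / K,   m = ρ_s V,

with an added-mass-free effective inertia (the Basset and added-mass terms
are negligible at these density contrasts and the transient relaxes in
`τ = 2 ρ_s r² K / (9 μ)` ≈ milliseconds, far below typical frame intervals).
The ODE backs the video generator and serves as an independent numerical
cross-check of the closed form: the two agree to better than 0.1% after 10
relaxation times across the tested parameter grid, by construction of the
physics rather than by shared code.

### Tracking and the steady window

Frames use image coordinates (origin top-left, y down), so sinking means
increasing y. Each frame is segmented by a global Otsu threshold honoring the
stated polarity (spheroid darker or brighter than background); the spheroid
is the largest connected component not touching the frame border with area
≥ 20 px. Its centroid is contrast-weighted (sub-pixel, exact for
area-weighted anti-aliased disks) and its radius is the equivalent-circle
radius `sqrt(area/π)`; the per-spheroid radius is the median over directly
detected frames, which suppresses single-frame segmentation failures.
Tracking uses nearest-neighbor continuity with a gate of 3× the median
frame-to-frame displacement; gaps of up to two frames are linearly
interpolated and flagged.

The terminal velocity is the OLS slope of vertical position against time over
the *steady window*: the longest suffix of the track whose 3-point local
slopes all lie within `max(5% · |median slope|, 4 σ̂)` of the suffix median,
where `σ̂` is a robust (MAD-based) estimate of the slope measurement noise
taken from consecutive slope differences. The noise term is exactly zero for
noiseless tracks — there the rule is a pure 5% relative tolerance, which
excludes the settling transient — and prevents the maximum of ~100 noisy
local slopes from spuriously breaking a genuine plateau. A suffix must
contain at least two local slopes (a 3-frame window has one slope that
trivially equals its own median); a track with no qualifying suffix raises
`no_terminal_plateau`. Fits with R² < 0.99 are flagged `poor_plateau_fit`.
Timestamps are authoritative; a constant frame rate is not assumed.

Repetitions of the same spheroid are averaged arithmetically; the velocity
standard error is pooled as the SE of the mean of independent estimates, and
QC flags are unioned.

### Defaults

| parameter | default | rationale |
|---|---|---|
| fluid density | 1005 kg/m³ | DPBS modeled as water-like; not a printed value |
| fluid viscosity | water at the stated temperature (Vogel-type fit, ~1.00 mPa·s at 20 °C) | buffer viscosity ≈ water |
| gravity | 9.80665 m/s² | standard gravity, overridable |
| channel radius | 0.5 mm | keeps λ ≤ 0.5 across the operative range |
| wall correction | off | see above |
| Reynolds guard | 0.5 | Stokes error ~5% at that Re |

## Cohort statistics

Measurements are long-format rows `(spheroid_id, condition, state, parameter,
value)` with conditions CTRL / CZB250 / CZB500 (0, 250, 500 nM dose), states
live/fixed and parameters density (g/cm³), weight (µg; "weight" in cohort
tables means mass — it is the fixation-stable quantity), diameter (µm).
Cells with fewer than 10 spheroids draw a warning, mirroring the
minimum-cohort convention, but are still analyzed.

Per (condition × state × parameter) cell the pipeline is: Shapiro–Wilk
normality test; if rejected at α = 0.05, **one** round of Tukey-fence
outlier elimination (quartiles by linear interpolation — the hinge convention
is fixed so fence positions are reproducible; `k = 1.5`; points strictly
outside `Q1 − k·IQR, Q3 + k·IQR` removed), then a re-test. `converged`
records whether the cleaned sample looks normal; heavy-tailed samples that
stay non-normal are reported, not refused. Note the fences are not idempotent
in general (removal shifts the quartiles), only samples already inside their
own fences are fixed points; one round is the default precisely to keep the
cleaning conservative.

Group comparisons are two-tailed unpaired Student (equal-variance) t-tests of
each treated condition against control on cleaned values, with mean ± SD
reported; no multiple-testing correction is applied by design. Dose–response
is the sample Pearson correlation between dose and per-dose cell means. The
overall fixation effect is a one-way ANOVA with state (live vs fixed) as the
single factor applied to per-(condition × parameter) cell means after
z-scoring within parameter, so density, weight and diameter are
commensurable; an F near zero means fixation leaves the standardized profile
unchanged. This layout is a declared choice — several groupings could be
called "total effect of fixation", and the per-cell-mean layout is the one
that treats the three parameters symmetrically.

Fluorescence protein quantification uses an OLS standard curve (fluorescence
on concentration, R² reported) inverted as `(f − intercept)/slope`.

## 3D nuclei quantification

The chain maps a proprietary GA3-style recipe onto open operators, in order:

1. **Denoise** — Gaussian, physical σ (default 0.5 µm) converted per axis to
   voxels.
2. **Z-alignment** — slice-to-slice translation by plain cross-correlation
   (the spectrally-whitened variant is unreliable on smooth fluorescence
   slices), 10× upsampled, cumulative, applied with sub-pixel interpolation.
   A step is kept only if the registered slice correlates with its neighbor
   (Pearson r ≥ 0.2) and exceeds a 0.3 px deadband — without the deadband an
   already-aligned stack accumulates a random-walk drift; effectively empty
   slices keep the running shift.
3. **Deconvolution (optional)** — Richardson–Lucy with a unit-sum Gaussian
   PSF (no measured PSF is assumed); multiplicative updates preserve
   nonnegativity and conserve total intensity within ~1%.
4. **Spot detection** — scale-normalized Laplacian of Gaussian at
   σ = diameter/3, local maxima above `max(threshold_rel · peak, 16 σ_noise)`
   with minimum seed separation 0.7× the nucleus diameter. The noise floor
   `σ_noise` is a MAD estimate of the blob response in the *background*
   intensity class, scaled by the √ intensity ratio to the dim foreground
   (Poisson statistics); estimating it there keeps bright-nucleus structure
   from inflating the floor. Shot-noise bumps genuinely look like small
   blobs: their extremes reach ~10σ over a stack-sized response field, while
   a nucleus at peak SNR ≥ 10 responds at ≥ ~25σ, so a 16σ floor sits in the
   gap between them.
5. **Region growing** — seeded watershed on inverted smoothed intensity,
   masked to voxels above the stack Otsu threshold. When the stack carries
   faint interior signal, the Otsu mask includes it and the watershed basins
   extend beyond the stained margins into that signal; the object count, not
   the per-label volume, is the robust readout there.
6. **Label smoothing** — morphological opening then closing per label with an
   ellipsoidal element of physical radius 0.332 µm (≥ 1 voxel); the label
   count never increases.
7. **Object separation** — each label is eroded 2 counts ("2 counts" read as
   two erosion passes); erosion acts in the lateral plane only, because the
   z-step (1 µm) is coarser than the pixel pitch and isotropic voxel erosion
   would strip a nucleus-thick slab in z before separating lateral fusions.
   Only cores ≥ 25% of the largest core trigger a split (ragged boundaries
   must not fragment single nuclei); accepted cores are re-grown inside the
   original footprint by a distance-transform watershed.
8. **Count** — labels with volume ≥ 5 µm³ (debris floor).

Spheroid volume comes either from the whole-spheroid mask — threshold at the
lower level of a 3-class multi-Otsu (so faint interior signal between bright
nuclei counts as foreground), Euclidean-ball closing of physical radius
(default 6 µm) implemented with distance transforms, largest component,
hole-filling — or from the equivalent-sphere formula `(π/6)d³`. Volumetric
nuclear density is count/volume by definition. Bright-field optical density
is the modal background-subtracted absorbance `−log10(I/I_bg)` inside the
largest dark Otsu component, divided by its area in µm² (`I_bg` = modal
background intensity).

All thresholds are relative or Otsu-derived (bit-depth independent) and all
physical parameters are voxel-size aware: the same physical scene at halved
voxel size changes counts by well under 5%.

## Synthetic data

Generators are pure functions of (scenario, seed) and return ground truth
sufficient to score every downstream stage.

**Fall videos** render an area-weighted anti-aliased dark disk (so sub-pixel
centroid truth is meaningful) at positions integrated by `settle_ode`, with
optional Gaussian centroid jitter and additive Gaussian pixel noise. Default
scenario: 1050 kg/m³, 100 µm radius, DPBS-like fluid at 25 °C, 0.5 mm
channel, 50 frames at 50 fps, 2 µm/px. `fall_scenario_for` picks the pixel
size (spheroid ~50 px across) and frame rate (fall spanning ~150 px) the way
an operator would tune the camera.

**Nuclei stacks** place nucleus centers by rejection sampling inside the
spheroid at a minimum separation, render each nucleus as a 3D Gaussian blob
(σ = radius/2), convolve with a Gaussian PSF, add faint interior haze
(out-of-focus light from the stained content — absent when there are no
nuclei), and apply Poisson shot noise (peak SNR defined as peak amplitude
over shot noise at the peak) plus a small Gaussian read-noise floor. Defaults:
20 µm spheroid radius, 2 µm nucleus radius, 5 µm separation, (1, 0.5, 0.5) µm
voxels, peak SNR 20. A matching bright-field image renders the spheroid as an
absorbing disk. The generator does not model clearing artifacts, refractive
index mismatch, depth-dependent attenuation or nucleus shape variation, so
passing tests demonstrate correct pipeline mechanics on well-posed inputs,
not robustness to every real-microscopy pathology.

**Cohorts** draw Gaussian values per (condition × state × parameter) cell.
The treated scenario encodes the qualitative treatment pattern — density up
(1.046 → 1.056 → 1.060 g/cm³), weight down (4.5 → 3.6 → 3.2 µg), diameter
down (200 → 180 → 170 µm), live and fixed states identical (fixation-stable)
— at realistic scatter (σ = 0.004 g/cm³, 0.5 µg, 12 µm) and 15 spheroids per
cell. The null scenario gives every condition the control distribution.
Outliers are injected at stated sd offsets and recorded in ground truth; note
that k = 1.5 fences clip a clean Gaussian point with ~0.7% probability each,
so cleaning recovers injected outliers with high recall but occasionally
removes a legitimate tail point as well.

## Numerical choices and limitations

- ODE integration: RK45 with rtol 1e-11; positions and velocities are exact
  to visualization precision for these linear dynamics.
- Quartiles: linear interpolation (numpy default) throughout.
- Degenerate inputs are contracts, not crashes: zero pooled variance with
  equal means gives t = 0, p = 1; with unequal means it is an error; empty
  stacks yield zero seeds; a uniform bright-field image raises
  `no_spheroid`.
- Problem sizes in the test-suite and acceptance runs (16 noiseless videos,
  200 noisy replicates, 10 nuclei stacks of 20–100 nuclei, 200 null cohorts)
  are the package's chosen verification conditions; each completes in
  seconds to a couple of minutes on one CPU.
- The sedimentation inversion is only as good as the sphere idealization:
  porous or aspherical aggregates bias the inferred density; the wall factor
  is an on-axis approximation and spheroids settling off-axis are slightly
  faster than it predicts.
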