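# Methods

## Model

FDG is transported from plasma into tissue (rate `K1`, mL·min⁻¹·mL⁻¹),
transported back (`k2`, min⁻¹) and phosphorylated, i.e. irreversibly trapped
on the time scale of a cardiac acquisition (`k3`, min⁻¹; `k4 = 0`).  For such
a tracer the Patlak linearization holds after an equilibration time `t*`:

    C_T(t)/Cp(t) = Ki · x(t) + V,     x(t) = ∫₀ᵗ Cp dτ / Cp(t)

with slope `Ki = K1·k3/(k2+k3)` (net influx constant) and intercept `V`
(apparent distribution volume).  MRGlu is then

    MRGlu = Ki · PG / LC · 100   [µmol · min⁻¹ · (100 g)⁻¹]

where PG is plasma glucose in µmol/mL (mg/dL × 10 / 180.16) and LC the
lumped constant.  Negative MRGlu can occur when the input-function slope
dominates the VOI concentration; no correction is applied — such values are
flagged and, in "clinical" mode, filtered from group analyses.

Full nonlinear compartment fitting, SUV, partial-volume correction,
metabolite correction and arterial sampling models are out of scope.

## Numerical choices

* **Patlak integral**: trapezoidal rule over frame mid-times, with a
  `(t=0, Cp=0)` sample prepended when the first mid-time is after injection
  (activity is zero at injection).  The discretization error vanishes as the
  frame schedule refines; on the default schedule it biases Ki by well under
  1%.
* **Fit**: ordinary least squares of `y` on `x` over points with mid-time
  ≥ `t*`, in the centered form (exactly zero slope for constant data).
  Default `t* = 10 min` — conventional for cardiac FDG, and late enough that
  the transient term `e^-(k2+k3)t` is negligible for the rate constants of
  interest.  `t* = "auto"` picks the earliest `t*` whose fit has a maximum
  absolute relative residual ≤ 5% over `[t*, end]`; if no candidate
  qualifies it falls back to the minimiser of that residual with ≥ 3 points.
* **Input function**: always an explicit argument.  Clinically the left
  ventricle blood pool is the usual image-derived choice and is the default
  in the pipeline; the aorta VOI may be passed instead.  Frames with
  `Cp ≤ 0` are dropped and reported.
* **Units**: frame times are stored in seconds and converted to minutes at
  the kinetics boundary, because Ki and MRGlu are conventionally per minute.
  Tissue density is treated as 1 g/mL (per-mL ≡ per-100g up to a
  configurable multiplier).
* **Lumped constant**: default 1.0 and always echoed in reports, so MRGlu is
  proportional to Ki·PG unless the user supplies a tissue-specific LC.

## Registration

All alignment is rigid (Euler angles + translation) — no tissue deformation.
SimpleITK's multi-resolution framework is used with *full* metric sampling,
which makes every registration deterministic; shrink factors 4/2/1 with
smoothing sigmas 2/1/0.5 voxels.  The residual half-voxel smoothing at full
resolution matters: on piecewise-constant images the metric surface is
locally rough and a gradient-descent optimizer otherwise stalls ~1 mm from
the optimum.

* **PET ↔ CT**: Mattes mutual information (50 bins), the standard
  cross-modality choice.  The recovered transform maps CT physical space
  onto PET space; `fuse` resamples the CT onto the PET grid (linear), never
  the PET, so quantification always reads original counts.
* **Frame-to-frame**: the reference is the duration-weighted mean of the
  latter half of frames (high counts, kinetically stable), overridable to
  `last_frame`, `mean_image` or an index.  The metric default is also
  Mattes MI: measured on the phantom, normalized cross-correlation leaves
  1–1.7 mm residuals across the early(blood-pool)/late(trapped-tracer)
  contrast change, while MI stays below ~0.5 mm, which is what the 2%
  TAC-fidelity requirement needs.  NCC remains available via
  `metric="ncc"`.
* Frames whose optimizer raises are left unregistered and flagged in the
  report; a max-iteration stop still applies its (usable) estimate.

## Seed-point VOIs

* **Vessel (CT)**: 26-connected region growing from the seed within an HU
  window (default (0, 100), non-contrast blood); the seed slice must not
  exceed `max_radius_mm` (leak check).  On each axial slice the
  cross-section is replaced by the least-squares (Kåsa) circle of its
  boundary — reproducing the circular one-click aorta VOI — inflated by half
  an in-plane pixel (boundary voxel centres sit inside the true edge) and
  clipped to `max_radius_mm`.  Slices are tracked along the centerline both
  ways until half of `axial_extent_mm` from the seed or until circularity
  `4πA/P²` drops below `min_circularity` (default 0.8).
  `axial_extent_mm = 0` reproduces a single-slice circular ROI.
* **Uptake (PET)**: threshold at `threshold_fraction` (default 0.5) of the
  local maximum within `search_radius_mm` of the seed, on the mean of the
  late frames (last 10 min) for trapped-tracer tissue, or of the early
  frames (first 2 min) for the blood pool; largest/seed-containing
  26-connected component, one binary closing.  The left-ventricle VOI is
  additionally eroded by one voxel as a crude guard against myocardial
  spill-in — a documented limitation, not a partial-volume correction.
  Masks smaller than 2 voxels are rejected as degenerate.

## Cohort statistics

* Quartiles by linear interpolation of order statistics; skewness as the
  adjusted Fisher–Pearson standardized third moment (absent for n < 3);
  sample SDs with n−1.
* ANCOVA: `post = β0 + β1·pre + β2·group`, group effect tested by the
  partial F-test.  Because pre/post p-values in treatment tables are
  sometimes paired t-tests instead, the per-group paired t-test is computed
  and labelled alongside; neither is privileged.
* Multiple regression: OLS with intercept on the 13 risk factors;
  `R = √R²`, overall F and p reported, plus the design-matrix condition
  number (a 13-predictor model on a 20-patient cohort is near-saturated and
  the condition number makes that visible).  No variable selection,
  regularization or multiple-testing correction is applied.
* Negative-MRGlu filtering is a flag: off for descriptive tables (which
  legitimately include negative vessel values), on for clinical group
  analysis.

## The phantom — what it does and does not emulate

The generator is a pure function of (spec, seed).  It emulates: a
piecewise-constant thorax CT (air −1000 / lungs −800 / soft tissue 40 /
myocardium 45 / aorta 50 / spine 300 HU); a dynamic PET driven by the
analytic input function `Cp(t) = A·t·e^(−λt) + B·(1−e^(−µt))`
(A = 80 kBq/cc/min, λ = 1.5 min⁻¹, B = 8 kBq/cc, µ = 0.3 min⁻¹ — a smooth,
positive bolus-plus-recirculation shape, fully parameterized for tests);
region kinetics via the 2TC ODEs integrated on a 1 s grid with an exact
exponential integrator and averaged over each frame; frame-duration-scaled
Gaussian noise `sd = cv·value·√(ref/duration)`; optional per-frame rigid
motion; and a cohort whose 13 risk factors are independent Gaussians with
configurable means/SDs.

Deliberate simplifications — and hence what phantom-based validation does
*not* show about clinical data: no scanner PSF, sinogram or Poisson
reconstruction noise; no respiratory/cardiac gating structure; organs are
analytic shapes with sharp edges; blood regions carry pure `Cp` with no wall
signal or spill-over; risk factors are uncorrelated.  Default grid
64×64×32 at 4 mm (a 128×128 in-plane option mirrors clinical matrices);
frame schedule 12×10 s, 4×30 s, 4×60 s, 10×300 s (58 min) — a conventional
cardiac FDG protocol.  Phantom plasma glucose defaults to 100 mg/dL, LC 1.0.
The aorta tube is z-limited (12–112 mm of the 128 mm field) so that moderate
axial motion cannot push lumen content irrecoverably out of the field.

Because the aortic lumen and LV carry the blood curve, their ground-truth Ki
and MRGlu are exactly zero.  End-to-end accuracy is therefore assessed as a
relative 10% bound for metabolising districts and an absolute bound of
0.5 µmol/min/100g (~3% of the phantom's myocardial MRGlu) for blood
districts, set a priori from the expected VOI-edge contamination of a
circle-fit vessel mask.

Validation experiments use integer-voxel applied translations so that
`apply_known_motion` (linear interpolation) is an exact shift and residual
TAC error isolates registration accuracy; recovery bounds (half a voxel) are
additionally checked with non-integer perturbations.  Motion is applied to
the early half of frames only, since the mean-late reference is only
motion-free when the patient has settled.

On the default phantom the soft tissue (40 HU) and aorta (50 HU) are
adjacent in HU, so phantom configurations pass an explicit `hu_window`
(45, 65) to the vessel extractor; on clinical non-contrast CT the default
(0, 100) blood window applies.

## Reduced problem sizes

The kinetic-recovery grid (K1 ∈ {0.3, 0.6, 0.9}, k2 ∈ {0.6, 1.2},
k3 ∈ {0.05, 0.1} min⁻¹, noiseless, plus 50 noisy replicates at 5% CV) runs
on a 32×32×16 version of the phantom (same 256 mm field of view), and motion
experiments use a 16-frame, 35 min schedule.  These sizes were chosen so the
whole validation suite runs comfortably on a laptop while keeping every
estimate's error far from its tolerance.

## Known limitations

* Rigid-only alignment; cardiac/respiratory deformation is not modelled.
* The LV erosion is a fixed one-voxel guard, not a partial-volume model.
* The auto-t* rule assumes a late linear segment exists; heavily noisy
  curves fall back to the best residual rather than failing.
* The cohort generator's risk factors are independent; it cannot emulate
  collinearity between, e.g., blood-pressure measures.
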