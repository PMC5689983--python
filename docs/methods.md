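# Methods

This note documents the models implemented in `tomovsm`, the choices
made where the design was genuinely open, and what the synthetic test
fixtures do and do not demonstrate about real machine data.

## The virtual source

Helical tomotherapy delivers a 6 MV fan beam, without a flattening
filter, through a fixed Y jaw (nominal widths 1.0 / 2.5 / 5.0 cm at
isocenter) and a 64-leaf binary MLC.  Instead of simulating the linac
head (and storing phase-space files), the engine samples primary
photons from a single virtual source described entirely by
commissioning-style beam data:

* **Cone profile** `C(x)` — the transverse relative fluence of the
  unflattened beam, peaked on the axis.  `x` is the *tangent of the
  off-axis angle*, which makes the profile valid at any distance from
  the source.
* **Jaw profile** `J(x, y)` per jaw setting — a 2D envelope carrying
  the longitudinal (and transverse) penumbra.  Both profiles are
  normalized to 1 at the beam axis.
* **Leaf filters** — per-leaf transmission profiles conditioned on the
  open/closed state of the two adjacent leaves (open–open, close–close,
  close–open, open–close), relative to the cone.  Only direct
  neighbours matter; the open–open profile is by definition the
  indicator of the leaf's interval, so it is never stored.
* **Energy spectrum** — the parametric density
  `phi(E) = a·E^0.5 + b·E^-0.5 + c·e^-E + d` with default coefficients
  `a = -0.352, b = -1.42, c = 2.22, d = 1.437`.  The fit is meaningless
  below 0.25 MeV (the `E^-0.5` term diverges negative), so the support
  is `[0.25 MeV, E_max]` with `E_max` the zero crossing near 6.0 MeV;
  negative values are clamped to zero.  Mean energy ≈ 1.7 MeV.
* **Focal spot** — a double-Gaussian in the target plane.  The widths
  are not published for this machine class; defaults are
  `sigma1 = 0.5 mm, sigma2 = 1.0 mm, weight1 = 0.7` (FWHM in the
  1.1–1.4 mm range reported for tomotherapy sources), fully
  configurable.

### Per-projection fluence

For a sinogram row `s = (s_1 … s_64)` of leaf-open-time (LOT)
fractions, the leaf-filtered profile is

    LF(s, x) = Σ_i a1_i·f_oo_i(x) + a2_i·f_cc_i(x) + a3_i·f_co_i(x) + a4_i·f_oc_i(x)

where the `a_k` are the time fractions the leaf spends in each
neighbour state.  Binary leaves open as pulses centred in the
projection; for centred pulses the fractions have the closed form

    a1 = min(s_prev, s_i, s_next)
    a2 = max(0, s_i − max(s_prev, s_next))
    a3 (or a4) = s_i − a1 − a2, assigned to the longer-open neighbour side

The `max(0, ·)` clamp is required when both neighbours are open longer
than the leaf itself; with it the closed form reproduces the continuous
pulse-overlap model exactly (verified against a time-discretization
oracle; the residual is provably at most two oracle grid steps, one per
interval endpoint).  Leaves 1 and 64 have permanently closed virtual
outer neighbours.  The projection fluence map is then

    f(s, x, y) = C(x) · J(x, y) · LF(s, x)

which reduces *exactly* to the open-field map `C·J` when every leaf is
open.

### Particle sampling

The exit position is drawn proportional to the fluence map (uniform
jitter within a map cell) at the MLC exit plane, 30 cm from the source
by default (the value is arbitrary: tangent coordinates make the map
plane-independent).  The origin is drawn from the focal spot in the
target plane; the direction is the unit vector from origin to exit
position.  This makes head-scattered photons appear to come from the
target — the defining approximation of a single-source model, justified
for tomotherapy by its thick fixed primary collimation and the absence
of a flattening filter (an order of magnitude less head scatter than
conventional linacs).  Electron contamination and interleaf leakage
(~0.3%) are not modelled.

## Delivery geometry

Patient coordinates are DICOM (x right→left, y anterior→posterior,
z inferior→superior); the machine uses IEC 61217.  Per projection the
beam-to-patient map is composed as

    T(iso) · Rx(90°) · Rz(−θ_couch) · Ry(β_gantry) · T(0, 0, SAD) · Rz(θ_col)

with θ_couch = θ_col = 0 for tomotherapy and SAD = 85 cm.  The chain is
composed on device coordinates with the origin at the source;
`T(0,0,SAD)` shifts them onto the isocentric *beam frame* (origin at
the isocenter, +z toward the source) in which the sampler emits
particles, and `Rx(90°)` maps the IEC "z up" axis onto the DICOM
anterior axis: at gantry 0 the source sits at `(0, −85, 0)` cm.
Helical plans advance the gantry by `360°/N_proj-per-rotation` and the
couch by `pitch × jaw width` per rotation.

## Transport engine

A deliberately simplified coupled photon–electron Monte Carlo in the
fast-planning lineage, numba-compiled, tallying energy per voxel in a
density grid.  All interaction data are per unit mass thickness for a
single water composition, density-scaled per voxel — sufficient for
water-equivalent and low-density phantoms, a documented limitation for
real CT with bone (no Z dependence beyond water).

**Photons** (cutoff 50 keV, below which energy deposits locally):

* Woodcock (majorant) tracking; the majorant is the maximum phantom
  density times the total mass attenuation coefficient at the current
  energy.  Zero-density voxels are vacuum.
* Compton scattering on free electrons: the scattered-photon fraction
  is sampled with the standard mixture/rejection algorithm for the
  Klein–Nishina differential cross section; the electron takes the
  complementary energy and the momentum-balancing direction.  The
  attenuation coefficient is the *analytic* Klein–Nishina total cross
  section times the electron density of water, so tracking and
  kinematics are exactly consistent.
* Photoelectric absorption: `E^-3` power law anchored at the 100 keV
  water value (a few percent of the total near the cutoff, negligible
  above); the photoelectron continues along the photon direction.
* Pair production above 1.022 MeV (tabulated coefficient): the kinetic
  energy is split uniformly at random; the positron is transported as
  an electron and annihilates at the end of its range into two
  back-to-back isotropic 511 keV photons.
* Rayleigh scattering is omitted.

**Electrons** (class II condensed history, cutoff and hard-event
thresholds 200 keV):

* Continuous loss along short steps (≤ the smaller of `max_step`,
  one voxel, and a 15% energy-loss limit) using the restricted
  stopping power: the tabulated collision stopping power minus the
  analytic hard-collision loss above the threshold, plus the
  sub-threshold share of the radiative loss.  The step's loss is
  deposited in the voxel the step starts in, whose density set the
  stopping power.
* Discrete Møller knock-ons with the leading `1/T²` spectrum between
  the threshold and `T/2`, secondary emitted at its kinematic angle.
* Discrete bremsstrahlung with a `1/k` photon spectrum on
  `[200 keV, T]`, normalised so the mean hard-photon energy matches the
  above-threshold share of the tabulated radiative stopping power;
  photons are emitted forward.
* Gaussian multiple scattering per step (Highland formula,
  X₀ = 36.08 g/cm²).
* Below the cutoff: straight-line CSDA residual, deposited along the
  residual range (locally when the range is below one voxel).

Stopping powers and pair coefficients are compact tables transcribed
once from standard public compilations for liquid water and embedded in
the source; the CSDA range is integrated from those same tables (0.437
g/cm² at 1 MeV).  Nothing is fetched at run time.

**Tallies and statistics.**  Runs are split into `n_batches` (default
10) independently seeded PCG32 streams; per-voxel variance is the
batch-spread variance of the mean.  Batches are distributed over worker
threads; because the batch→seed mapping is fixed, results are
bit-identical for a fixed seed regardless of worker count.  Energy is
conserved exactly by construction (every transfer is either tallied in
a voxel or in the escape ledger; pair production stores the 1.022 MeV
rest-mass debt in the positron until annihilation), and each run
reports launched/deposited/escaped energy.  Dose per primary uses
1 MeV = 1.602176634×10⁻¹³ J and voxel mass = density × voxel volume.
Histories are allocated across projections proportional to each
projection's summed leaf open time.

**Calibration.**  `D_measured = M × T_open × D_MC` defines the machine
factor `M` (particles/s) from one measured point dose, the plan's total
leaf open time and the Monte Carlo dose-per-particle at the same point.

## Analytics

* **PDD / profiles** — trilinear sampling along a ray (or lateral line
  at depth), normalized to the curve maximum (PDD) or central-axis
  value (profiles).
* **Gamma index** — per reference point, the minimum over a
  neighbourhood of radius 3×DTA (sampled at 0.1×DTA by linear
  interpolation of the evaluated grid) of
  `sqrt((ΔD/tol)² + (Δr/DTA)²)`; `tol` is a percentage of the reference
  maximum (global, the default — which of global/local the field's
  published comparisons used is often unstated) or of the local
  reference dose.  Points below 10% of the maximum are excluded by
  default; γ ≤ 1 passes.
* **DVH** — cumulative volume fraction receiving at least each dose
  edge, with the final edge exactly at the maximum dose.  `D_p` (dose
  received by at least p% of the volume) inverts the curve with linear
  interpolation in the crossing bin; a plateau of the curve exactly at
  the requested level (a tie between discrete dose levels) resolves to
  the plateau midpoint — so a half-1 Gy/half-3 Gy structure has
  D50 = 2 Gy.  `Dmean` is the arithmetic voxel mean.

## Synthetic fixtures and their scope

Real cone/jaw/leaf-filter tables are proprietary machine data, so the
fixtures generate structurally faithful stand-ins: a peaked cone
(`1 − drop·(|x|/half_width)^p`, zero outside the collimated field),
error-function jaw windows whose 50% widths match the nominal jaw
settings at 85 cm, and leaf filters that are indicator windows narrowed
by a Gaussian tongue-and-groove dip (depth `tg_dip`, width
`leaf_sigma`) at every edge that faces a *closed* MLC neighbour.  Edges
facing an open neighbour (or the collimator, at the outer edges of
leaves 1 and 64) stay ideal, which makes open apertures tile seamlessly
and the all-open projection map equal the open-field map exactly; the
delivered-dose penumbra then comes from the focal spot, its physical
origin.  With `tg_dip = 0` the three stored profiles coincide.

Standard validation geometries are provided as fixtures: a water tank
(surface at a chosen SSD), the 5 cm water / 15 cm of 0.1 g/cm³ /
5 cm water slab stack (SSD 75 cm, 2.5×2.5 cm² central-four-leaf
field), the 30 cm diameter × 18 cm solid-water "cheese" DQA cylinder on
its standard 256×256×58 CT grid (1.953×1.953×3 mm³ voxels), the
picket-fence tongue-and-groove pattern (even leaves open through 34,
odd leaves from 35), and helical plans (default pitch 0.22, jaw 2.5 cm,
51 projections per rotation).

Passing tests on these fixtures demonstrates the *mechanics* — fluence
composition, geometry, transport physics, statistics, analytics — under
realistic shapes and magnitudes.  They do not certify dosimetric
accuracy against a real machine: that requires the machine's own beam
data dropped into the model container (the file layout accepts them
without code change) plus measured PDDs/profiles/films.

## Problem sizes and numerical choices

Simulation-based checks run at 10⁶ histories for the water-tank PDD
(build-up maximum and monotone falloff on 1-cm depth bins averaged over
the central region), the slab log-slope comparison, the picket-fence
stripe pattern and narrow-beam attenuation; 3×10⁵ histories per dip for
the tongue-and-groove contrast sweep; 2×10⁵ for reproducibility; 10⁶
samples for the spectral chi-square and positional-uniformity checks.
At these sizes each check resolves its effect with comfortable margin
(e.g. ~0.3% binned PDD noise against a ~4%/cm falloff).

Other fixed choices: profile grids at 0.001 tangent resolution with
bilinear interpolation; spectrum sampling by inverse-CDF lookup on a
32768-point grid; bisection/Brent root finding to 10⁻⁶ MeV for the
spectral endpoint; fluence-map sampling via a flattened-CDF binary
search; `max_step = 0.25 cm` for electrons; degenerate inputs (empty
maps, empty masks, zero-density phantoms, beams that miss the phantom)
raise or warn as documented in the API.

## Known limitations

* Single water material (density scaling only): no Z-dependent
  photoelectric/pair enhancement in bone, no tissue spectra.
* Free-electron Compton (no binding/Doppler), forward photoelectrons,
  uniform pair splits, forward bremsstrahlung, Gaussian multiple
  scattering: penumbra and build-up are approximate at the millimetre
  level.
* The leaf-filter approach cannot represent interleaf leakage, and the
  latency correction is an affine per-leaf stand-in for the
  machine-specific compressed-air behaviour.
* The synthetic spectrum is a fit whose mean (≈1.7 MeV) is slightly
  harder than published tomotherapy spectra (≈1.5 MeV); commissioning
  against measured PDDs would tune the tail, as is standard practice.
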