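# Methods

This note records the models behind each analyzer, the default
parameters and why they were chosen, what the synthetic generators
emulate (and what they deliberately do not), the numerical choices, and
the known limitations. Nothing here claims an empirical result that is
not computed by the test suite or `scripts/acceptance.py`.

## 1. Rheology

### Gel point (`detect_gel_point`)

**Model.** During in-situ crosslinking both moduli rise; the material is
liquid-like (G″ > G′) before the gel point and solid-like after. The gel
point is the first *sustained* crossing of G′ above G″: the difference
must stay non-negative for at least two consecutive samples, so a single
noise-flipped sample cannot trigger detection. The crossing time is
interpolated linearly in (time, log G′ − log G″) between the bracketing
samples — moduli grow multiplicatively, so interpolation in log-modulus
is the natural linearization; time stays linear because sweeps are
sampled linearly in time.

**Failure modes.** A sweep that never crosses returns a "not gelled"
result rather than raising; fewer than 4 samples is rejected as
insufficient to distinguish a crossing from noise.

### Yield point (`detect_yield_point`)

Same sustained-crossing logic applied to a stress amplitude sweep, with
two changes: the crossing direction is G″ overtaking G′, and the
interpolation is log-log (amplitude grids are log-spaced, and moduli
decay as power laws of stress near yield). A sweep that starts with
G″ ≥ G′ has no solid regime at all — that is a different physical
situation from "no yield within the window", so it raises a dedicated
`NoSolidRegimeError`.

### Recovery (`compute_recovery`)

Three-interval protocol: 0–100 s low strain, 100–300 s high strain,
300–400 s low strain. The recovery fraction is the ratio of the median
G′ over the last half of interval 3 to the same statistic of interval 1.
Medians over the last half make the statistic insensitive to the
transient after each step. All three intervals must contain data.

### LVE summary (`summarize_lve`) and power-law fit (`fit_power_law`)

LVE averages G′, G″ and tan δ over the 0.1–22.5 Hz band (the common
plate-rheometer protocol range); points outside the band are an input
error. The flow-curve fit is ordinary least squares of log η on log γ̇:
exact on noiseless power-law data and minimum-variance under
multiplicative log-normal noise, which is the error structure the
generator produces and a reasonable model of rheometer noise.

### Tabular I/O

CSV with explicit `test_type`, abscissa units and SI modulus columns.
Units are normalized on read (e.g. seconds → minutes). Unknown columns
and missing moduli are rejected loudly; out-of-order rows are sorted
with a warning — silent reordering hides instrument export bugs.

## 2. Drop spreading

**Model.** A dispensed drop of volume V (µL ≡ mm³) either stays
near-spherical or relaxes into a spherical cap of contact diameter D_eq
and height h with V = (πh/6)(3a² + h²), a = D_eq/2. Gravity-driven
sagging, contact-angle hysteresis and evaporation are not modeled: the
cap is the equilibrium shape for a small sessile drop and the paper-style
protocol measures only the footprint diameter.

* `S0 = D_eq / (6V/π)^(1/3)`; S0 = 1 means no spreading, S0 > 1 outward
  flow. `S0 = 0` (no wetting) is a separate flagged case.
* The cap height is found by `brentq` on (0, a + D_ideal] with
  `xtol = 1e-12`. The cubic is strictly increasing in h, so the root is
  unique; the bracket bound a + D_ideal exceeds any physical height.
* The cap model applies only for D_eq ≥ D_ideal; below that the drop has
  not spread and h is reported as undefined rather than extrapolated.
* Time courses are classified into the two processability windows:
  `self_spreading` strictly before the gel point, `shape_retaining` from
  the gel point on (solid behavior *starts* at the gel point, so the
  boundary is closed on the gel side). S0 increasing over time
  contradicts monotone crosslinking and is warned about, not rejected —
  real data can contain such records and the user should see them.

## 3. Fidelity scoring

The five scores are pure algebra over measured fiber diameters and
printed pore sides (see README for the formulas). Choices worth
recording:

* **Sample SD (ddof = 1)** everywhere, matching rheometer and
  image-analysis software conventions.
* **U reduces to 1 + SD/mean** — the needle diameter cancels. It is kept
  in the needle-referenced form because that is how the score is defined
  operationally (via S and L_ideal).
* A single-point fiber measurement has undefined dispersion; U is
  reported as 1 with a warning instead of NaN-poisoning P.
* Pe and Pr bracket the printed geometry from outside and inside; both
  are exactly 1 for a dispersion-free, perfectly adherent print, which
  is the identity the acceptance suite checks.
* `suitable_for_ebb` uses |P − 1| ≤ 0.10, the conventional band for
  "slight displacement from the optimum".
* Grid measurements may carry NaN CAD sides (images alone do not know
  the design); score functions that need the CAD refuse to run on NaN
  rather than producing NaN scores.

### Extrusion pressure

Default model: ΔP = 2 L τ_y / R — the pressure at which the wall shear
stress of a cylindrical needle reaches the yield stress. It is a force
balance, independent of the constitutive law, and is a *lower bound*:
it ignores entrance effects, the barrel taper and the pressure needed to
maintain flow above yield. The `power_law_flow` variant
(Rabinowitsch–Mooney) estimates the pressure to drive a prescribed
volumetric flow rate; its Newtonian limit (n = 1) collapses to
Hagen–Poiseuille, which the tests verify. For a 22G × 12.5 mm needle and
τ_y ≈ 205 Pa the wall-stress model gives ≈ 25 kPa — published printing
pressures for comparable inks are ~2× higher, consistent with the model
being a lower bound.

## 4. Image measurement

* **Segmentation** — Otsu by default (a deterministic stand-in for the
  manual thresholding of interactive tools), fixed-value override, with
  optional inversion and minimum object area. A constant image is all
  background unless saturated white.
* **Drop diameter** — equivalent-area-circle diameter of the largest
  8-connected object; multiple objects warn, none raises.
* **Fiber width** — twice the Euclidean distance transform at
  seeded-random points on each fiber's skeleton, restricted to the
  central ridge (EDT within 1.5 px of that fiber's maximum) because
  skeletons of capped strands sprout end spurs where the width estimate
  is biased low. Assumes near-constant-width fibers — exactly the
  printed-strand use case. Accuracy is ±1 px by construction.
* **Grid pores** — background components under 4-connectivity that do
  not touch the image border; each pore contributes its bounding-box
  width (x side) and height (y side). Bounding boxes are robust for the
  near-rectangular pores of grid infill but would overestimate strongly
  concave pores.
* **Granulometry** — equivalent diameters of connected components above
  a 7 px² debris floor; an empty field is a flagged result, not an
  error, because empty powder images are routine.
* **Cell coverage** — the image is thresholded so cells are white; the
  black fraction is measured and subtracted from unity (the
  formulation used by the standard protocol). Plane homogeneity compares
  top/middle/bottom planes: homogeneous iff the relative spread
  (max − min)/mean is below 0.20 at both time points; a bottom plane
  several-fold denser than the top is the sedimentation signature.

## 5. Synthetic generators

The generators exist to give every analyzer a ground truth. They emulate
the *geometry and error structure* of instrument output, not the
underlying physics:

* **Gelation sweep** — saturating exponentials for both moduli with the
  G″ timescale solved (τ″ = −t_c / log1p(−r), with
  r = (G′_pl/G″_pl)(1 − exp(−t_c/τ′))) so the noiseless curves cross
  *exactly* at the requested time; infeasible parameter combinations
  (crossing above the loss plateau) are rejected at construction. This
  is not a crosslinking-kinetics model — it is a curve family with an
  exactly known crossover.
* **Yield sweep** — tan δ = (σ/σ_y)^k with k chosen from the end-point
  moduli, G′ decaying as a Lorentzian in σ/σ_y. Noise is *common-mode*
  (applied to both moduli identically) so the crossing stress is
  preserved under noise; independent noise would move the ground truth
  itself, making "recovery within tolerance" untestable.
* **Recovery trace** — exponential transitions (τ = 5 s) between plateau,
  yielded and recovered levels, sampled at 2 s midpoints.
* **Flow curve** — exact power law with optional multiplicative
  log-normal noise.
* **Print images** — binary 8-bit micrographs at 10 µm/px (fibers) and
  25 µm/px (grid). Fibers are sinusoidally wavy with the vertical
  half-thickness inflated by sqrt(1 + slope²) so the *perpendicular*
  width stays constant; rasterization uses strict inequalities so a
  50 px fiber spans 49–50 rows and the EDT estimate lands within 1 px.
  The grid is a 4 × 4-pore lattice with jittered interior strand
  positions and fixed borders; the per-pore truth is stored so SD
  comparisons are fair.
* **Drop frames** — filled disks approaching D_eq as (1 − u)², ending
  exactly at D_eq.
* **Particle/nuclei fields** — non-overlapping disks placed by rejection
  sampling; nuclei planes stop placing spots when the requested area
  fraction is reached (within half a spot).

All randomness flows through `numpy.random.default_rng(seed)`; every
generator is bit-reproducible for a given parameter set.

## 6. Pipeline and determinism

`RunConfig` is a fully serializable description of a run; its SHA-256
hash (first 16 hex digits) is recorded in the report. Per-stage seeds
derive from the base seed as
`(base·1_000_003 + material_index·1_009 + stage) mod (2³¹ − 1)` so
stages are decorrelated but reproducible. Reports serialize to sorted,
indented JSON; two runs of the same config are byte-identical, which the
acceptance suite asserts. Stage failures are re-raised as
`PipelineError` tagged `[material/stage]`.

Default demo config: three materials with gel points 120/60/60 min and
yield stresses 205/155/121 Pa (a fast-gelling composite ink vs two
faster-gelling references — the 2× gel-point pattern reported for such
systems), a 22G × 12.5 mm needle, 20 × 20 mm CAD grid, 100 µL drops
observed every 30 min, 5% nominal cell coverage, and a particle
population of 100/147.9/200 µm.

## 7. Limitations

* The gel and yield points are *crossover* estimates; true critical gel
  points (Winter–Chambon) require multi-frequency data the protocol does
  not collect.
* The spherical-cap model ignores gravity (valid below the capillary
  length, ~2.7 mm for water-like inks; 100 µL drops exceed it, so h is a
  geometric summary, not a hydrostatic prediction).
* The wall-stress pressure is a lower bound (see §3).
* Image accuracy is 1 px by design; sub-pixel methods are out of scope.
* Bounding-box pore sides assume near-rectangular pores.
* Generators share a curve family with the analyzers' assumptions by
  construction; recovery tests therefore validate the *implementation*,
  not the physical adequacy of the models.
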