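# Methods

## The measurement model

The package treats quantitative emission-tomography phantom analysis as
three layers:

1. **Geometry.** The NEMA IEC body phantom is described analytically:
   six spheres (37, 28, 22, 17, 13, 10 mm inner diameter) with centres
   equally spaced at 60° on a 114.4-mm-diameter circle in one
   transaxial plane, inside a torso-shaped body compartment. The body
   cross-section is the standard simplified torso — two half-circle
   shoulders of radius `height/2` joined by a rectangle, 300 × 230 mm
   overall, extruded 180 mm axially — with an elliptical-cylinder mode
   for fast tests. The exact interior dimensions enter no reported
   metric; both modes satisfy the mask-partition identity. The physical
   phantom's central lung insert is omitted because no metric reads it;
   a cold cylinder can be added later without touching any contract.

2. **Acquisition + reconstruction (the synthetic scanner).** A
   parallel-beam projector, Poisson counting noise, and ordered-subset
   expectation maximization with optional resolution modeling,
   attenuation and a flat scatter term.

3. **Quantitation.** Counts → activity via the scalar factor
   `QF = 1/(Cs·Δt·V_voxel)`; recovery coefficients, ratio-normalized
   contrast `C = (VOI_m/VOI_b)/A`, background noise CV, line profiles
   and apparent sizes.

Units are explicit everywhere: lengths mm, times s, activity
concentrations kBq/mL (internal activity bookkeeping in Bq), and every
`Volume` declares its unit (`counts`, `kBq/mL`, …) which is checked at
each operation boundary — contrast accepts either unit (it is a ratio
of ratios), recovery requires concentration.

## Coordinate and mask conventions

Indices are ordered (axial, anterior-posterior, left-right); the
phantom frame origin sits at the sphere-plane centre and grids are
centred on it by default. VOI masks use the voxel-centre-in-sphere
rule (mirroring binary segmentation of a known geometry), while
activity rasterization uses fractional sub-voxel occupancy
(`supersample`³ points per voxel, default 4³). Consequences that the
tests quantify rather than hide:

* the background VOI (body contour minus sphere VOIs, zero margins by
  default) tiles the body exactly with the sphere masks;
* a sphere-mask mean of the rasterized truth is biased low by roughly
  0.34·spacing/radius (partially filled edge voxels), ≈7% for the
  10-mm sphere at 1-mm spacing — identity tests use a tolerance of
  0.5·spacing/radius, and metric comparisons against the analytic
  oracle (below) are unaffected because both sides use the same mask.

## The projector and why it is exact where it matters

Each view rotates the in-plane coordinates and lets every voxel deposit
its full value into the two detector bins bracketing its rotated
position (linear splatting); detector rows are axial slices. The
per-view deposit matrix is sparse and cached; back-projection is its
transpose. Three exactness properties follow by construction:

* **adjointness** — forward and back projection pass a dot-product test
  at machine precision, so the EM update uses a true adjoint pair;
* **per-view activity conservation** — deposit weights sum to one per
  voxel and the detector array is padded beyond the grid diagonal plus
  the blur kernel support, so total expected counts equal total
  activity × Cs × Δt to ~1e-15 (the exact inverse of QF);
* **EM count conservation** — with one subset, total image counts equal
  total measured counts after every full iteration to ~1e-14.

Calibration convention: a view acquired for `Δt_view` by a system of
sensitivity `Cs` (shared equally among heads) sees
`line integral (Bq) × Cs/n_heads × Δt_view` expected counts; with
`Δt = views_per_head × Δt_view` (heads acquire simultaneously) the
totals close. The SPECT default is two heads, 64 views × 27 s over
180° each (128 projections); PET is emulated as one 360° sweep of 128
views with a narrower detector response and higher sensitivity — no
time-of-flight or vendor modeling is attempted, or needed for any
contracted property.

The detector response is a distance-independent Gaussian applied along
the detector-bin axis (zero-padded, hence self-adjoint). Attenuation,
off by default, uses a uniform water-equivalent coefficient inside the
body contour; per-view survival factors are integrated numerically on
the central transaxial slice (the map is axially invariant where there
is activity) and enter forward and back projection symmetrically.
Scatter, off by default, is a flat additive sinogram term of
`scatter_fraction × mean(true counts)` with the matched term added in
the OSEM model denominator ("scatter correction").

## OSEM

Standard multiplicative update over view-interleaved subsets (subset k
takes views k, k+subsets, … within each head's sweep; ascending subset
order), uniform positive initialization, per-subset sensitivity images,
1e-12 guard on model denominators, non-negativity inherent. Resolution
modeling includes the detector blur in the system model; the Gaussian
post-filter (σ = FWHM/2.3548, default FWHM 8.40 mm) is applied after
the final iteration — in iteration sweeps each checkpoint is filtered
on output while the recursion continues unfiltered, so all checkpoints
share one run and one noise realization.

Reconstructed volumes are returned in counts (summing to the measured
total for a matched 1-subset model) so that applying QF is a real,
checkable calibration step rather than a formality.

Observed behaviour the tests pin down: RC rises with iterations and
plateaus (22-mm sphere changes <2% — measured ≈0.3% — between 16 and
32 iterations at 4 subsets; the 10-mm sphere converges slowest, ≈2.6%);
Poisson-driven background variance (noisy minus matched noise-free run)
grows monotonically with iterations, while the *plain* background CV
first falls as deterministic convergence transients fade — which is why
the noise property is tested on the excess variance; with resolution
modeling the 37-mm profile peak overshoots the true concentration by
~12% (Gibbs/edge ringing) versus ~1% discretization ripple without it
(thresholds 1.05/1.02 in the tests).

## Line profiles and apparent size

Profiles are trilinear samples along a segment through a sphere centre
(default axis: transaxial left-right, step = half the smallest voxel
spacing). Apparent size is the FWHM of the background-subtracted
profile, crossings located by linear interpolation, outermost crossings
on ties; the resolution curve plots apparent size against true diameter
with the identity line as the ideal. "Relative intensity" defaults to
normalization by the true sphere concentration (per-figure max
normalization is available); both choices are recorded in the profile
object, never implicit.

An analytic subtlety the closed form (uniform sphere convolved with an
isotropic Gaussian, integrated with `scipy.integrate.quad`) makes
explicit: apparent FWHM is **not** monotone in blur width. For light
blur the blurred peak drops faster than the wings widen, so the
apparent size of small spheres first *shrinks* (10-mm sphere: 9.7 mm at
2-mm blur, 8.9 mm at 4-mm, 13.2 mm at 12-mm). The implementation
reproduces the closed form to ~0.1%, so the tests assert the analytic
behaviour: near-identity at PET-like blur, a resolution floor (three
smallest spheres within 20% of each other, closed form 17.3%) far above
identity at SPECT-like 12-mm blur, and monotonicity only in the
resolution-limited regime.

## What the simulator does and does not emulate

It emulates: the acquisition geometry and count level of a dual-head
body-contour SPECT protocol; Poisson statistics; iteration-dependent
contrast recovery; partial-volume loss; background noise growth; edge
overshoot under resolution modeling; attenuation and flat-scatter
correction plumbing. It does not emulate: Monte-Carlo photon
transport, septal penetration, energy spectra or window-based scatter,
randoms, dead time, time-of-flight, distance-dependent collimator
response (hook present but off), or any vendor reconstruction. Passing
tests therefore certify the *analysis* chain and the qualitative
physics phenomena, not clinical-scanner RC values; clinical headline
numbers depend on hardware specifics deliberately out of scope.

## Defaults and problem sizes

Per-isotope constants (half-lives from standard nuclear data;
photopeaks/windows as used clinically: 140 keV ±15% for 99mTc, 279 and
208 keV ±20% for 203Pb/177Lu, 435–585 keV PET window; positron
fractions 0.97/0.23/0.17 for 18F/89Zr/64Cu) ship in a versioned TSV.
Default simulator resolution classes (8 mm for 99mTc low-energy
collimation, 10 mm for medium-energy 203Pb/177Lu, 4.5–6 mm for PET by
positron range) are free parameters with documented defaults, not
claims about any scanner. Fills follow the six study presets
(e.g. 236/23.7 kBq/mL for 99mTc, 66.3/5.9 for 18F). System sensitivity
defaults (1e-4 cps/Bq SPECT, 5e-3 PET) give realistic total counts
(~4×10⁷ for the warm 99mTc scan).

Grids: simulations default to 4.8-mm isotropic voxels (96² in-plane ×
48 slices, wide enough that nothing leaves the field of view in any
rotation); analytic-oracle comparisons use a 1-mm grid over the sphere
plane; fast end-to-end tests use 48² in-plane. These sizes keep each
property check to seconds-to-minutes on one CPU while leaving every
tested phenomenon comfortably resolved; they are package defaults, all
configurable.

Seeding: one master seed expands to per-stage seeds through
`numpy.random.SeedSequence`; identical config + seed reproduces
sinograms, reconstructions and metric tables bit for bit.

## Known limitations

* Exact geometric masks replace CT-derived VOIs; any CT-segmentation
  bias present in scanner studies is intentionally absent here.
* The ratio-normalized contrast is the primary definition; comparisons
  with literature using NU2 percent contrast must use the explicit
  `nu2_percent_contrast` variant.
* Decay correction between assay and scan time is available but off by
  default.
* The attenuation path integral assumes an axially invariant medium;
  strongly sloped phantoms would need a full 3-D integrator.
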