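# nemaiq

Quantitative image-quality analysis for SPECT and PET on the NEMA IEC
body phantom, with a built-in synthetic scanner so the whole chain can
be exercised and validated without scanner data.

## Who this is for

Medical physicists and imaging scientists who evaluate emission-
tomography systems for quantitative (theranostic) applications: how
accurately does a given scanner + isotope + reconstruction setting
recover a known activity concentration, and how does that accuracy
depend on object size, iteration count and resolution modeling?

The package analyses either

* volumes produced by its own simulator (rasterized phantom →
  parallel-beam projection → Poisson counting noise → OSEM →
  Gaussian post-filter), or
* externally reconstructed volumes supplied as NIfTI, with the phantom
  geometry and fill described in a YAML config.

## The quantities it computes

**Count-to-activity calibration.** Reconstructed counts are converted
to activity concentration with a scalar quantitative factor

    QF = 1 / (Cs · Δt · V_voxel)

where `Cs` is the system sensitivity (counts·s⁻¹ per Bq), `Δt` the
total acquisition time and `V_voxel` the reconstructed voxel volume.

**Recovery coefficient (RC).** For each hot sphere (37, 28, 22, 17, 13,
10 mm), the mean measured concentration over the exact geometric sphere
VOI divided by the true filled concentration. RC = 1 is perfect
quantification; RC may exceed 1 under resolution modeling.

**Contrast.** The ratio-normalized form

    C = (VOI_m / VOI_b) / A

with `VOI_m` the sphere-VOI mean, `VOI_b` the background-VOI mean (full
body contour minus the sphere VOIs) and `A` the known true
sphere-to-background ratio, always computed from the actual fill
(e.g. A = 236/23.7 ≈ 9.96, not a nominal 10). A sphere
indistinguishable from background scores 1/A, perfect recovery scores
1. The NU2-style percent contrast `(H/B − 1)/(A − 1)` is available
behind an explicit flag.

**Spatial resolution.** Line profiles through the sphere centres of
cold-background scans; apparent size = profile FWHM (background
subtracted, crossings by linear interpolation); the apparent-size vs
true-diameter curve with the identity line as the ideal; and percent
differences of normalized profile maxima between sphere pairs.

## Worked example

```python
import nemaiq as nq

spec = nq.default_nema_spec(nq.PhantomFill("99mTc", 236.0, 23.7))
grid = nq.VoxelGrid((48, 96, 96), (4.8, 4.8, 4.8))
study = nq.simulate_scan(spec, nq.ScanProtocol(),
                         nq.ReconSettings(iterations=8, subsets=4),
                         grid, seed=17)
conc = nq.counts_to_concentration(study.reconstruction,
                                  nq.qf_for(nq.ScanProtocol(), grid))
for r in nq.recovery_coefficients(conc, nq.sphere_masks(spec, grid), spec):
    print(f"{r.diameter_mm:5.0f} mm  RC = {r.rc:5.3f}")
```

prints (dual-head protocol: 64 views × 27 s per head over 180°, 8-mm
detector response, OSEM 8i/4s with the 8.40-mm post-filter):

```
   37 mm  RC = 0.710
   28 mm  RC = 0.638
   22 mm  RC = 0.573
   17 mm  RC = 0.411
   13 mm  RC = 0.367
   10 mm  RC = 0.238
```

Recovery falls with sphere diameter — the partial-volume spill-out that
makes small lesions read low — and the per-sphere values sit close to
the closed-form sphere ⊛ Gaussian prediction for the effective system
blur. The `examples/` directory walks through each capability
(phantom/VOIs, isotope catalog, simulation + recovery, iteration
sweeps, profiles/resolution, full pipeline); each script prints its
numbers with a line on what they mean.

A thin CLI wraps the same functions:

```bash
nemaiq simulate --preset 99mTc --seed 17 --out runs/tc99m
nemaiq analyze --image recon.nii.gz --preset 177Lu --out runs/lu177
nemaiq isotopes list
```

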