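"""Simulate one warm-background SPECT acquisition and quantify it.

The chain is: rasterize the phantom -> parallel-beam projection with an
8-mm detector response (64 views x 27 s per head, two heads over 180
degrees) -> Poisson counting noise -> OSEM (8 iterations, 4 subsets,
8.40-mm Gaussian post-filter) -> counts-to-activity conversion with the
quantitative factor QF = 1/(Cs x dt x V_voxel) -> per-sphere recovery.
"""

import nemaiq as nq

spec = nq.default_nema_spec(nq.PhantomFill("99mTc", 236.0, 23.7))
grid = nq.VoxelGrid((48, 96, 96), (4.8, 4.8, 4.8))
protocol = nq.ScanProtocol()          # the dual-head defaults above
settings = nq.ReconSettings(iterations=8, subsets=4)

study = nq.simulate_scan(spec, protocol, settings, grid, seed=17)
print(f"acquired {study.sinogram.total_counts:.3g} counts over "
      f"{protocol.n_projections} projections "
      f"(dt = {protocol.total_time_s:.0f} s)")

qf = nq.qf_for(protocol, grid)
print(f"QF = {qf.value:.4g} Bq/mL per count "
      f"(Cs {qf.cs_cps_per_bq:g} cps/Bq, dt {qf.dt_s:.0f} s, "
      f"V_voxel {qf.v_voxel_ml:.4f} mL)")

conc = nq.counts_to_concentration(study.reconstruction, qf)
masks = nq.sphere_masks(spec, grid)
print("\ndiameter  measured   true    RC")
for r in nq.recovery_coefficients(conc, masks, spec):
    print(f"{r.diameter_mm:5.0f} mm  {r.measured_kbq_ml:7.1f}  {r.true_kbq_ml:6.1f}  "
          f"{r.rc:5.3f}")
print("-> recovery falls with diameter: spill-out of counts from spheres "
      "near the system resolution (partial-volume effect)")
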