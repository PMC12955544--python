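"""Line profiles through the sphere centres of a cold-background scan,
apparent sizes, and the largest-vs-smallest intensity split.

A SPECT-like 12-mm blur flattens the small spheres into the resolution
floor; a PET-like 3-mm blur leaves every profile near its true plateau.
"""

import nemaiq as nq

spec = nq.default_nema_spec(nq.PhantomFill("99mTc", 236.0, 0.0))  # cold
grid = nq.VoxelGrid((56, 212, 212), (1.0, 1.0, 1.0))
truth = nq.voxelize(spec, grid, supersample=4)

for label, blur in (("SPECT-like (12 mm)", 12.0), ("PET-like (3 mm)", 3.0)):
    image = nq.blur_model(truth, blur)
    curve = nq.resolution_curve(image, spec)
    profs = nq.sphere_profiles(image, spec)
    diffs = nq.max_relative_intensity_difference(profs, reference=236.0)
    head = diffs[(diffs.diameter_large_mm == 37.0)
                 & (diffs.diameter_small_mm == 10.0)]
    print(f"\n{label}")
    print("  diameter -> apparent size (profile FWHM):")
    for d, a in zip(curve.diameters_mm, curve.apparent_mm):
        print(f"   {d:5.0f} mm -> {a:5.1f} mm")
    print(f"  peak-intensity difference, 37 mm vs 10 mm: "
          f"{head['difference_percent'].iloc[0]:.1f}%")

print("\n-> under heavy blur the three smallest spheres read nearly the same "
      "apparent size (the system resolution, not the object, sets the width)")
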