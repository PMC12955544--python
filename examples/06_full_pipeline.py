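"""Run the end-to-end pipeline from a config and compare two modalities.

A RunConfig bundles phantom fill, acquisition protocol, reconstruction
sweep and analysis options; `run` executes simulate -> quantify ->
profile and returns tidy tables (also writable to a directory together
with figures and a provenance record).
"""

import nemaiq as nq

base = {
    "grid": {"shape": [32, 80, 80], "spacing_mm": [4.8, 4.8, 4.8]},
    "recon": {"iterations": [8]},
    "noise": False,
}
spect = nq.RunConfig.model_validate(
    {**base, "label": "SPECT-like",
     "protocol": {"modality": "SPECT", "detector_fwhm_mm": 12.0}})
pet = nq.RunConfig.model_validate(
    {**base, "label": "PET-like",
     "protocol": {"modality": "PET", "detector_fwhm_mm": 3.0}})

reports = [nq.run(cfg) for cfg in (pet, spect)]
table = nq.compare_runs(reports)
wide = table.pivot_table(index="diameter_mm", columns="label", values="rc",
                         aggfunc="first").sort_index(ascending=False)
print("recovery coefficient at 8 iterations / 4 subsets:")
print(wide.round(3).to_string())
print("\n-> the narrow-response 360-degree system recovers more activity in "
      "every sphere; the gap widens as the spheres shrink")

# the same analysis runs on an externally reconstructed NIfTI volume by
# setting input_image in the config (the simulation stage is skipped)
print("\npreset configs shipped:",
      ", ".join(n for n in ("99mTc", "203Pb", "177Lu", "18F", "89Zr", "64Cu")))
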