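# warm-background 18F PET study: 66.3 / 5.9 kBq/mL fill (A = 11.24, not 10)
label: 18F-PET
phantom:
  isotope: 18F
  sphere_concentration_kbq_ml: 66.3
  background_concentration_kbq_ml: 5.9
protocol:
  modality: PET
recon:
  iterations: [4]
  subsets: 4
  post_filter_fwhm_mm: 0.0
  resolution_modeling: true
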