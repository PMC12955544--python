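# warm-background 64Cu PET study: 149.1 / 15.5 kBq/mL fill
label: 64Cu-PET
phantom:
  isotope: 64Cu
  sphere_concentration_kbq_ml: 149.1
  background_concentration_kbq_ml: 15.5
protocol:
  modality: PET
recon:
  iterations: [4]
  subsets: 4
  post_filter_fwhm_mm: 0.0
  resolution_modeling: true
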