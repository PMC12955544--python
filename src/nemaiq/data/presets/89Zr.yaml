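# warm-background 89Zr PET study: 102.4 / 10.2 kBq/mL fill
label: 89Zr-PET
phantom:
  isotope: 89Zr
  sphere_concentration_kbq_ml: 102.4
  background_concentration_kbq_ml: 10.2
protocol:
  modality: PET
recon:
  iterations: [4]
  subsets: 4
  post_filter_fwhm_mm: 0.0
  resolution_modeling: true
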