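# warm-background 203Pb SPECT study: 88.2 / 8.7 kBq/mL fill
label: 203Pb-SPECT
phantom:
  isotope: 203Pb
  sphere_concentration_kbq_ml: 88.2
  background_concentration_kbq_ml: 8.7
protocol:
  modality: SPECT
recon:
  iterations: [1, 2, 4, 8, 16, 32]
  subsets: 4
  post_filter_fwhm_mm: 8.40
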