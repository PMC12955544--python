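# warm-background 99mTc SPECT study: 236 / 23.7 kBq/mL fill
label: 99mTc-SPECT
phantom:
  isotope: 99mTc
  sphere_concentration_kbq_ml: 236.0
  background_concentration_kbq_ml: 23.7
protocol:
  modality: SPECT
recon:
  iterations: [1, 2, 4, 8, 16, 32]
  subsets: 4
  post_filter_fwhm_mm: 8.40
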