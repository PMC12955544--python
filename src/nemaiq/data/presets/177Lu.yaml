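# warm-background 177Lu SPECT study: 661.2 / 64.9 kBq/mL fill
label: 177Lu-SPECT
phantom:
  isotope: 177Lu
  sphere_concentration_kbq_ml: 661.2
  background_concentration_kbq_ml: 64.9
protocol:
  modality: SPECT
recon:
  iterations: [1, 2, 4, 8, 16, 32]
  subsets: 4
  post_filter_fwhm_mm: 8.40
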