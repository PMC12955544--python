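# nemaiq isotope catalog, v1
# half-lives from standard nuclear data (NNDC); photopeaks/windows and positron
# fractions as used clinically for these tracers; default_psf_fwhm_mm is the
# synthetic scanner's reconstructed-image resolution default for the isotope
# (collimator class for SPECT, positron range class for PET), not a claim
# about any clinical system.
name	modality	half_life_h	photopeak_kev	window_fraction	pet_window_lo_kev	pet_window_hi_kev	positron_fraction	default_psf_fwhm_mm
99mTc	SPECT	6.01	140	0.15	-	-	-	8.0
203Pb	SPECT	51.92	279	0.20	-	-	-	10.0
177Lu	SPECT	159.5	208	0.20	-	-	-	10.0
18F	PET	1.829	-	-	435	585	0.97	4.5
89Zr	PET	78.4	-	-	435	585	0.23	5.5
64Cu	PET	12.70	-	-	435	585	0.17	6.0
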