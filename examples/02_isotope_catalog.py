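"""Query the isotope catalog and decay-correct an assayed activity.

The catalog carries the physical constants the analysis needs per
isotope: half-life, photopeak and energy window (SPECT) or coincidence
window and positron fraction (PET), and the simulator's default
resolution class.
"""

import nemaiq as nq

for rec in nq.list_isotopes():
    lo, hi = rec.energy_window_kev
    extra = (f"positron fraction {rec.positron_fraction:.2f}"
             if rec.modality == "PET" else
             f"photopeak {rec.photopeak_kev:.0f} keV +/- {rec.window_fraction:.0%}")
    print(f"{rec.name:>6} {rec.modality:<5} T1/2 {rec.half_life_h:7.2f} h   "
          f"window {lo:.0f}-{hi:.0f} keV   {extra}")

tc = nq.get_isotope("99mTc")
assayed = 236.0  # kBq/mL at dose-calibrator assay time
at_scan = nq.decay_correct(assayed, tc, elapsed_h=3.0)
print(f"\n236.0 kBq/mL of 99mTc assayed 3 h before the scan is "
      f"{at_scan:.1f} kBq/mL at scan time (factor 2^(-3/6.01))")
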