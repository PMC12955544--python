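"""Per-isotope physical constants and decay correction.

The catalog ships as a plain-text TSV so the physics lives in data, not
code.  SPECT records carry a photopeak and fractional energy window
(e.g. 140 keV +/- 15% for 99mTc); PET records carry the coincidence
window and positron fraction — never both.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .phantom import PhantomFill

_CATALOG: dict[str, "IsotopeRecord"] | None = None


@dataclass(frozen=True)
class IsotopeRecord:
    name: str
    modality: str                 # "SPECT" | "PET"
    half_life_h: float
    photopeak_kev: float | None = None      # SPECT only
    window_fraction: float | None = None    # SPECT only, e.g. 0.15 for +/-15%
    pet_window_kev: tuple[float, float] | None = None  # PET only
    positron_fraction: float | None = None  # PET only
    default_psf_fwhm_mm: float = 8.0

    def __post_init__(self):
        if self.half_life_h <= 0:
            raise ValueError("half-life must be positive")
        if self.modality == "SPECT":
            if self.photopeak_kev is None or self.window_fraction is None:
                raise ValueError(f"{self.name}: SPECT record needs photopeak and window")
            if self.pet_window_kev is not None or self.positron_fraction is not None:
                raise ValueError(f"{self.name}: SPECT record must not carry PET fields")
        elif self.modality == "PET":
            if self.pet_window_kev is None or self.positron_fraction is None:
                raise ValueError(f"{self.name}: PET record needs window and positron fraction")
            if not 0 < self.positron_fraction <= 1:
                raise ValueError(f"{self.name}: positron fraction outside (0, 1]")
            if self.pet_window_kev[0] >= self.pet_window_kev[1]:
                raise ValueError(f"{self.name}: PET window bounds out of order")
            if self.photopeak_kev is not None or self.window_fraction is not None:
                raise ValueError(f"{self.name}: PET record must not carry SPECT fields")
        else:
            raise ValueError(f"{self.name}: modality must be SPECT or PET")

    @property
    def energy_window_kev(self) -> tuple[float, float]:
        """Acceptance window bounds in keV for either modality."""
        if self.modality == "PET":
            return self.pet_window_kev
        half = self.photopeak_kev * self.window_fraction / 2.0
        return (self.photopeak_kev - half, self.photopeak_kev + half)


def _parse(value: str) -> float | None:
    return None if value == "-" else float(value)


def _load_catalog() -> dict[str, IsotopeRecord]:
    global _CATALOG
    if _CATALOG is None:
        text = resources.files("nemaiq.data").joinpath("isotopes.tsv").read_text()
        rows = [ln.split("\t") for ln in text.splitlines()
                if ln.strip() and not ln.startswith("#")]
        header, records = rows[0], {}
        assert header[0] == "name"
        for r in rows[1:]:
            d = dict(zip(header, r))
            lo, hi = _parse(d["pet_window_lo_kev"]), _parse(d["pet_window_hi_kev"])
            records[d["name"]] = IsotopeRecord(
                name=d["name"], modality=d["modality"],
                half_life_h=float(d["half_life_h"]),
                photopeak_kev=_parse(d["photopeak_kev"]),
                window_fraction=_parse(d["window_fraction"]),
                pet_window_kev=None if lo is None else (lo, hi),
                positron_fraction=_parse(d["positron_fraction"]),
                default_psf_fwhm_mm=float(d["default_psf_fwhm_mm"]),
            )
        _CATALOG = records
    return _CATALOG


def list_isotopes() -> list[IsotopeRecord]:
    return list(_load_catalog().values())


def get_isotope(name: str) -> IsotopeRecord:
    catalog = _load_catalog()
    if name not in catalog:
        raise KeyError(
            f"unknown isotope {name!r}; supported: {', '.join(sorted(catalog))}")
    return catalog[name]


def decay_correct(activity: float, isotope: IsotopeRecord, elapsed_h: float) -> float:
    """Decay an activity forward by ``elapsed_h`` hours (negative values
    back-correct to an earlier assay time): A * 2^(-t / T_half)."""
    return activity * 2.0 ** (-elapsed_h / isotope.half_life_h)


def true_ratio(fill: PhantomFill) -> float:
    """The known sphere-to-background activity ratio A used to normalize
    contrast; raises for a cold background where A is undefined."""
    return fill.true_ratio
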