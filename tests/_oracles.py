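"""Independent closed-form oracles used by the tests.

These deliberately avoid the package's own convolution/mask code paths:
the sphere-blur values come from the analytic radial profile of a
uniform sphere convolved with an isotropic Gaussian, integrated with
scipy.integrate.quad.
"""

import numpy as np
from scipy.integrate import quad
from scipy.special import erf

SIGMA_PER_FWHM = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def sphere_gauss_value(r: float, radius: float, fwhm: float) -> float:
    """Value at distance r from the centre of a unit-concentration sphere
    of given radius after 3-D isotropic Gaussian blur (closed form)."""
    sig = fwhm * SIGMA_PER_FWHM
    if r < 1e-9:
        return erf(radius / (sig * np.sqrt(2))) - \
            radius * np.sqrt(2 / np.pi) / sig * np.exp(-radius ** 2 / (2 * sig ** 2))
    a = 0.5 * (erf((radius - r) / (sig * np.sqrt(2)))
               + erf((radius + r) / (sig * np.sqrt(2))))
    b = sig / (r * np.sqrt(2 * np.pi)) * (
        np.exp(-(radius - r) ** 2 / (2 * sig ** 2))
        - np.exp(-(radius + r) ** 2 / (2 * sig ** 2)))
    return a - b


def sphere_gauss_mean(diameter: float, fwhm: float) -> float:
    """Mean of the blurred unit sphere over its own (true) volume — the
    recovery coefficient a pure-Gaussian system would produce."""
    radius = diameter / 2.0
    val, _ = quad(lambda r: sphere_gauss_value(r, radius, fwhm) * r ** 2, 0, radius)
    return 3.0 * val / radius ** 3


def sphere_gauss_fwhm(diameter: float, fwhm: float) -> float:
    """Closed-form apparent size: full width at half maximum of the
    blurred sphere's radial profile (half of the *blurred* peak, which
    sits below the true concentration for small spheres)."""
    from scipy.optimize import brentq

    radius = diameter / 2.0
    half = sphere_gauss_value(0.0, radius, fwhm) / 2.0
    upper = radius + 4.0 * fwhm
    x = brentq(lambda r: sphere_gauss_value(r, radius, fwhm) - half, 1e-9, upper)
    return 2.0 * x
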