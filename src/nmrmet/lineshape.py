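"""Pseudo-Voigt (additive mixed Gauss-Lorentz) line shape.

The profile used throughout for rendering and deconvolution:

    pV(x) = A * [ eta * G(x) + (1 - eta) * L(x) ]

with a common center ``c`` and full width at half maximum ``w`` for both
components, unit apex height, and Gaussian fraction ``eta`` in [0, 1]:

    G(x) = exp(-4 ln2 (x - c)^2 / w^2)
    L(x) = 1 / (1 + 4 (x - c)^2 / w^2)

The analytic area is ``A * w * [eta * sqrt(pi / (4 ln2)) + (1 - eta) * pi / 2]``,
which is what the quantification stage reports as signal intensity
(areas, unlike apex heights, stay proportional to concentration when the
width varies).
"""

from __future__ import annotations

import numpy as np

__all__ = ["pseudo_voigt", "peak_area", "amplitude_for_area", "AREA_GAUSS", "AREA_LORENTZ"]

_LN2 = np.log(2.0)
# area of a unit-apex, unit-FWHM component
AREA_GAUSS = float(np.sqrt(np.pi / (4.0 * _LN2)))
AREA_LORENTZ = float(np.pi / 2.0)


def pseudo_voigt(
    x: np.ndarray, center: float, amplitude: float, fwhm: float, eta: float
) -> np.ndarray:
    """Evaluate the additive pseudo-Voigt profile on ``x``."""
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    u2 = np.square((np.asarray(x, dtype=float) - center) / fwhm)
    gauss = np.exp(-4.0 * _LN2 * u2)
    lorentz = 1.0 / (1.0 + 4.0 * u2)
    return amplitude * (eta * gauss + (1.0 - eta) * lorentz)


def peak_area(amplitude: float, fwhm: float, eta: float) -> float:
    """Closed-form integral of the pseudo-Voigt profile."""
    return amplitude * fwhm * (eta * AREA_GAUSS + (1.0 - eta) * AREA_LORENTZ)


def amplitude_for_area(area: float, fwhm: float, eta: float) -> float:
    """Apex height giving the requested analytic area."""
    return area / (fwhm * (eta * AREA_GAUSS + (1.0 - eta) * AREA_LORENTZ))
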