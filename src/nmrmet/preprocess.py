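"""Spectrum-level preprocessing: QC, scaling, baseline, ppm calibration.

Order in the pipeline: quality control -> receiver-sensitivity scaling
-> constant-baseline subtraction -> calibration of the ppm axis on the
anomeric alpha-D-glucose resonance (5.23 ppm) -> regrid to the batch
master grid.  Alignment (correlation-optimized warping) lives in
:mod:`nmrmet.cow`, JRES handling in :mod:`nmrmet.jres`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import Spectrum1D, JresProjection

__all__ = [
    "QCConfig",
    "qc_spectra",
    "scale_receiver_sensitivity",
    "subtract_constant_baseline",
    "calibrate_ppm",
    "regrid",
    "median_reference",
    "GLUCOSE_ANOMERIC_PPM",
]

GLUCOSE_ANOMERIC_PPM = 5.23


@dataclass
class QCConfig:
    """Spectroscopic-parameter QC thresholds.

    ``max_water_rel``: reject when the residual-water intensity exceeds
    this multiple of the batch median (poor water suppression).
    ``max_shim_hz``: absolute linewidth-proxy ceiling (poor shimming).
    """

    max_water_rel: float = 5.0
    max_shim_hz: float = 2.5


def qc_spectra(
    spectra: list[Spectrum1D], config: QCConfig | None = None
) -> pd.DataFrame:
    """Flag each spectrum pass/fail with a reason string.

    Returns a DataFrame indexed by sample id with columns ``passed``
    (bool) and ``reason`` ('' when passed; 'water' and/or 'shim').
    Empty input yields an empty table.
    """
    config = config or QCConfig()
    if not spectra:
        return pd.DataFrame(columns=["passed", "reason"])
    water = np.array([s.water_intensity for s in spectra])
    shim = np.array([s.shim_proxy for s in spectra])
    med_water = np.median(water)
    rows = {}
    for s, w, h in zip(spectra, water, shim):
        reasons = []
        if med_water > 0 and w > config.max_water_rel * med_water:
            reasons.append("water")
        if h > config.max_shim_hz:
            reasons.append("shim")
        rows[s.sample_id] = {"passed": not reasons, "reason": "+".join(reasons)}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


def scale_receiver_sensitivity(
    spectrum: Spectrum1D, reference_pulse_length_us: float
) -> Spectrum1D:
    """Undo receiver-coil sensitivity differences between samples.

    Sensitivity is inversely proportional to the calibrated pulse
    length, so intensities are multiplied by
    ``pulse_length / reference_pulse_length``.
    """
    if reference_pulse_length_us <= 0:
        raise ValueError("reference pulse length must be positive")
    factor = spectrum.pulse_length_us / reference_pulse_length_us
    return spectrum.with_intensity(spectrum.intensity * factor)


def subtract_constant_baseline(
    spectrum: Spectrum1D, signal_free_windows: list[tuple[float, float]]
) -> tuple[Spectrum1D, float]:
    """Subtract the median intensity over signal-free ppm windows."""
    if not signal_free_windows:
        raise ValueError("need at least one signal-free window")
    mask = np.zeros(spectrum.ppm.size, dtype=bool)
    for lo, hi in signal_free_windows:
        if lo > hi:
            lo, hi = hi, lo
        mask |= (spectrum.ppm >= lo) & (spectrum.ppm <= hi)
    if not mask.any():
        raise ValueError("signal-free windows fall outside the ppm range")
    constant = float(np.median(spectrum.intensity[mask]))
    return spectrum.with_intensity(spectrum.intensity - constant), constant


def _parabolic_apex(ppm: np.ndarray, y: np.ndarray, i: int) -> float:
    """Apex ppm by 3-point parabola through the maximum and neighbours."""
    if i == 0 or i == y.size - 1:
        return float(ppm[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return float(ppm[i])
    di = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(ppm[i] + di * (ppm[i + 1] - ppm[i]))


def calibrate_ppm(
    spectrum: Spectrum1D,
    target_ppm: float = GLUCOSE_ANOMERIC_PPM,
    search_halfwidth_ppm: float = 0.05,
    noise_floor_mads: float = 5.0,
) -> tuple[Spectrum1D, float]:
    """Shift the ppm axis so the reference apex sits at ``target_ppm``.

    The anomeric alpha-D-glucose resonance is located as the largest
    local maximum inside ``target +- halfwidth`` lying above a robust
    noise floor (window median + ``noise_floor_mads`` x MAD); the apex
    is refined by 3-point parabolic interpolation.  Returns the
    calibrated spectrum and the applied shift (added to the axis).
    """
    win = (spectrum.ppm >= target_ppm - search_halfwidth_ppm) & (
        spectrum.ppm <= target_ppm + search_halfwidth_ppm
    )
    idx = np.flatnonzero(win)
    if idx.size < 3:
        raise ValueError("search window too narrow for the grid")
    y = spectrum.intensity[idx]
    floor = np.median(y) + noise_floor_mads * np.median(np.abs(y - np.median(y)))
    j = int(np.argmax(y))
    if y[j] <= floor:
        raise ValueError("calibration peak not found")
    apex = _parabolic_apex(spectrum.ppm[idx], y, j)
    shift = target_ppm - apex
    return spectrum.with_ppm(spectrum.ppm + shift), shift


def regrid(
    spectrum: Spectrum1D | JresProjection, grid: np.ndarray
) -> Spectrum1D | JresProjection:
    """Cubic re-interpolation onto a common descending master grid.

    Cubic (rather than linear) interpolation keeps sub-grid calibration
    shifts from attenuating narrow peaks, which would bias fitted areas.
    Points outside the original range are zero-filled.
    """
    from scipy.interpolate import CubicSpline

    grid = np.asarray(grid, dtype=float)
    x_asc = spectrum.ppm[::-1]
    y_asc = spectrum.intensity[::-1]
    spline = CubicSpline(x_asc, y_asc, extrapolate=False)
    new = spline(grid[::-1])
    new[~np.isfinite(new)] = 0.0
    out = spectrum.with_intensity(new[::-1])
    return out.with_ppm(grid)


def median_reference(spectra: list[Spectrum1D]) -> Spectrum1D:
    """Point-wise median spectrum of QC-passed samples (alignment target)."""
    if not spectra:
        raise ValueError("no spectra to build a reference from")
    mat = np.vstack([s.intensity for s in spectra])
    ref = spectra[0].with_intensity(np.median(mat, axis=0))
    ref.sample_id = "__reference__"
    return ref
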