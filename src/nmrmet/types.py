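"""Core in-memory containers shared across the pipeline.

Spectra are stored on an explicit, strictly descending ppm axis (the NMR
display convention).  Tabular objects (cohorts, signal tables) are thin
wrappers around :class:`pandas.DataFrame` with the column contract
documented and validated here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum1D",
    "JresProjection",
    "JresMatrix",
    "WarpPath",
    "PeakModel",
    "SignalTable",
    "COHORT_COLUMNS",
    "validate_cohort",
]


def _check_axis(ppm: np.ndarray, intensity: np.ndarray) -> None:
    if ppm.ndim != 1 or intensity.ndim != 1:
        raise ValueError("ppm and intensity must be 1-D")
    if ppm.size != intensity.size:
        raise ValueError("ppm and intensity must have equal length")
    if ppm.size < 16:
        raise ValueError("spectrum needs at least 16 points")
    if not np.all(np.diff(ppm) < 0):
        raise ValueError("ppm axis must be strictly decreasing")
    if not np.all(np.isfinite(intensity)):
        raise ValueError("intensities must be finite")


@dataclass
class Spectrum1D:
    """One sample's 1-D spectrum plus the acquisition metadata QC needs.

    Parameters
    ----------
    sample_id : str
    ppm : ndarray
        Strictly descending chemical-shift axis (ppm).
    intensity : ndarray
        Same length as ``ppm``; arbitrary intensity units.
    pulse_length_us : float
        Calibrated 90-degree pulse length; receiver sensitivity is
        inversely proportional to it, so it drives intensity scaling.
    water_intensity : float
        Integrated residual-water intensity; a QC covariate.
    shim_proxy : float
        Linewidth-style shim-quality estimate (Hz); a QC covariate.
    """

    sample_id: str
    ppm: np.ndarray
    intensity: np.ndarray
    pulse_length_us: float = 10.0
    water_intensity: float = 0.0
    shim_proxy: float = 1.0

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        _check_axis(self.ppm, self.intensity)
        if self.pulse_length_us <= 0 or not np.isfinite(self.pulse_length_us):
            raise ValueError("pulse_length_us must be positive and finite")
        if self.water_intensity < 0 or self.shim_proxy < 0:
            raise ValueError("water_intensity and shim_proxy must be nonnegative")

    def with_intensity(self, intensity: np.ndarray) -> "Spectrum1D":
        return replace(self, intensity=np.asarray(intensity, dtype=float))

    def with_ppm(self, ppm: np.ndarray) -> "Spectrum1D":
        return replace(self, ppm=np.asarray(ppm, dtype=float))


@dataclass
class JresProjection:
    """Sum projection of a tilted, symmetrized 2-D J-resolved matrix.

    Shares the ppm grid of the sample's 1-D spectrum; peak widths are
    narrower because J-splitting has been collapsed into the indirect
    dimension.
    """

    sample_id: str
    ppm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        _check_axis(self.ppm, self.intensity)

    def with_intensity(self, intensity: np.ndarray) -> "JresProjection":
        return replace(self, intensity=np.asarray(intensity, dtype=float))


@dataclass
class JresMatrix:
    """2-D J-resolved data block: rows = indirect (J) dimension."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("JRES data must be 2-D")
        if self.data.shape[0] % 2 != 0:
            raise ValueError("JRES row count must be even")

    @property
    def rows(self) -> int:
        return self.data.shape[0]


@dataclass
class WarpPath:
    """Piecewise-linear warp from correlation-optimized warping.

    Boundary index lists cover the full grid (both start at 0 and end at
    the last index).  Segment ``i`` maps sample indices
    ``[sample_boundaries[i], sample_boundaries[i + 1]]`` linearly onto
    reference indices ``[reference_boundaries[i], reference_boundaries[i + 1]]``.
    """

    reference_boundaries: list[int]
    sample_boundaries: list[int]
    segment_length: int
    slack: int
    score: float = float("nan")

    def __post_init__(self) -> None:
        r, s = self.reference_boundaries, self.sample_boundaries
        if len(r) != len(s) or len(r) < 2:
            raise ValueError("boundary lists must have equal length >= 2")
        if r[0] != 0 or s[0] != 0 or r[-1] != s[-1]:
            raise ValueError("warp must fix both endpoints")
        if any(b <= a for a, b in zip(r, r[1:])) or any(
            b <= a for a, b in zip(s, s[1:])
        ):
            raise ValueError("boundaries must be strictly increasing")

    @property
    def n_segments(self) -> int:
        return len(self.reference_boundaries) - 1

    def is_identity(self) -> bool:
        return self.reference_boundaries == self.sample_boundaries

    def to_dict(self) -> dict:
        return {
            "reference_boundaries": list(map(int, self.reference_boundaries)),
            "sample_boundaries": list(map(int, self.sample_boundaries)),
            "segment_length": int(self.segment_length),
            "slack": int(self.slack),
            "score": float(self.score),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WarpPath":
        return cls(
            reference_boundaries=list(d["reference_boundaries"]),
            sample_boundaries=list(d["sample_boundaries"]),
            segment_length=int(d["segment_length"]),
            slack=int(d["slack"]),
            score=float(d.get("score", float("nan"))),
        )


@dataclass
class PeakModel:
    """Pseudo-Voigt peak: additive Gauss/Lorentz mix with shared FWHM."""

    signal_id: str
    center_ppm: float
    amplitude: float = 0.0
    fwhm_ppm: float = 0.01
    eta: float = 0.5  # Gaussian fraction in [0, 1]

    def __post_init__(self) -> None:
        if self.fwhm_ppm <= 0:
            raise ValueError("fwhm_ppm must be positive")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")


# Provenance states a SignalTable cell can carry.
PROVENANCE_STATES = ("fitted", "pls_predicted", "discarded", "missing", "fit_failed")


class SignalTable:
    """Samples x signals intensity matrix with per-cell provenance.

    ``values`` and ``provenance`` are aligned DataFrames (rows = sample
    ids, columns = signal ids).  ``signals`` is indexed by signal id and
    carries ``shift_ppm`` plus the metabolite ``assignment``.  Cells whose
    provenance is ``discarded``/``missing``/``fit_failed`` hold NaN.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        provenance: pd.DataFrame,
        signals: pd.DataFrame,
    ) -> None:
        if not values.index.equals(provenance.index) or not values.columns.equals(
            provenance.columns
        ):
            raise ValueError("values and provenance must be aligned")
        if not values.columns.equals(signals.index):
            raise ValueError("signals metadata must cover every column")
        if "shift_ppm" not in signals.columns:
            raise ValueError("signals metadata needs a shift_ppm column")
        bad = set(np.unique(provenance.to_numpy())) - set(PROVENANCE_STATES)
        if bad:
            raise ValueError(f"unknown provenance states: {sorted(bad)}")
        self.values = values.astype(float)
        self.provenance = provenance
        self.signals = signals.copy()
        if "assignment" not in self.signals.columns:
            self.signals["assignment"] = "unknown"
        # hide numeric values for cells not usable downstream
        dead = ~provenance.isin(["fitted", "pls_predicted"])
        self.values = self.values.mask(dead)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def signal_ids(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "SignalTable":
        return SignalTable(
            self.values.copy(), self.provenance.copy(), self.signals.copy()
        )


COHORT_COLUMNS = (
    "subject_id",
    "family_id",
    "age",
    "sex",
    "bmi",
    "smoking",
    "lifetime",
    "active",
)


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Validate the cohort-table column contract and endpoint nesting.

    ``sex``/``smoking``/``lifetime``/``active`` are 0/1 integers with
    ``active`` a subset of ``lifetime`` (active migraine is defined only
    among lifetime cases).
    """
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if cohort["subject_id"].duplicated().any():
        raise ValueError("duplicate subject ids")
    for c in ("sex", "smoking", "lifetime", "active"):
        if not set(np.unique(cohort[c])) <= {0, 1}:
            raise ValueError(f"column {c} must be 0/1")
    if int((cohort["active"] & ~cohort["lifetime"].astype(bool)).sum()):
        raise ValueError("active cases must be a subset of lifetime cases")
    return cohort


def spectra_to_matrix(spectra: Iterable[Spectrum1D | JresProjection]) -> pd.DataFrame:
    """Stack spectra sharing one grid into a samples x ppm DataFrame."""
    spectra = list(spectra)
    if not spectra:
        return pd.DataFrame()
    ppm = spectra[0].ppm
    for s in spectra[1:]:
        if s.ppm.shape != ppm.shape or not np.allclose(s.ppm, ppm):
            raise ValueError("spectra are not on a common ppm grid")
    return pd.DataFrame(
        np.vstack([s.intensity for s in spectra]),
        index=[s.sample_id for s in spectra],
        columns=ppm,
    )
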