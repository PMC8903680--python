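"""Signal-table assembly: robust discard, PLS rescue, assignment.

After per-sample deconvolution, each signal's intensity vector is
screened with a median +- 3*IQR rule (the simplex occasionally lands in
a local minimum); discarded and failed cells are then re-predicted by a
partial-least-squares model trained to map the non-warped spectrum
directly onto the retained intensities, so every QC-passed sample ends
with a complete row.  Finally signals are assigned to metabolites by
nearest reference chemical shift, cross-checked by the between-signal
Pearson correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .types import SignalTable

logger = logging.getLogger(__name__)

__all__ = [
    "discard_fit_outliers",
    "tukey_iqr",
    "fit_pls_intensity_model",
    "predict_intensities",
    "load_reference_shifts",
    "assign_metabolites",
    "build_signal_table",
]


def tukey_iqr(values: np.ndarray) -> float:
    """Interquartile range from hinges: medians of the lower/upper half
    of the sorted data, the halves excluding the sample median when the
    length is odd (so {1..10, 1000} gives hinges 3 and 9, IQR 6)."""
    xs = np.sort(np.asarray(values, dtype=float))
    n = xs.size
    half = n // 2
    if half == 0:
        return 0.0
    lower = xs[:half]
    upper = xs[n - half :]
    return float(np.median(upper) - np.median(lower))


def discard_fit_outliers(values: np.ndarray) -> np.ndarray:
    """Mask (True = discard) of cells farther than 3*IQR from the median.

    Median and IQR are computed once on the full vector (NaNs ignored).
    A zero IQR discards only strictly positive distances, so a constant
    vector keeps every cell.  Vectors shorter than 4 are left unchanged.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 4:
        return np.zeros(x.shape, dtype=bool)
    med = float(np.median(x[finite]))
    iqr = tukey_iqr(x[finite])
    mask = np.zeros(x.shape, dtype=bool)
    mask[finite] = np.abs(x[finite] - med) > 3.0 * iqr
    return mask


def fit_pls_intensity_model(
    nonwarped_spectra: pd.DataFrame,
    intensities: pd.DataFrame,
    n_components: int = 10,
) -> PLSRegression:
    """PLS map from non-warped spectrum bins to all signal intensities.

    Training rows are the samples whose deconvolution fully succeeded
    (no NaN anywhere in ``intensities``); predictions never feed back
    into training.
    """
    complete = intensities.dropna(axis=0)
    if len(complete) <= n_components:
        raise ValueError(
            f"{len(complete)} complete training rows for {n_components} components"
        )
    X = nonwarped_spectra.loc[complete.index].to_numpy()
    model = PLSRegression(n_components=n_components, scale=False)
    model.fit(X, complete.to_numpy())
    model._signal_columns = list(complete.columns)  # type: ignore[attr-defined]
    return model


def predict_intensities(
    model: PLSRegression, nonwarped_spectrum: np.ndarray
) -> pd.Series:
    """Per-signal predictions for one sample's non-warped spectrum."""
    pred = model.predict(np.asarray(nonwarped_spectrum, float)[None, :])[0]
    return pd.Series(pred, index=model._signal_columns)  # type: ignore[attr-defined]


def load_reference_shifts() -> pd.DataFrame:
    """Shipped chemical-shift reference table (literature assignments)."""
    with resources.files("nmrmet.data").joinpath("reference_shifts.tsv").open() as fh:
        ref = pd.read_csv(fh, sep="\t")
    return ref


def assign_metabolites(
    table: SignalTable,
    reference: pd.DataFrame | None = None,
    correlation_threshold: float = 0.5,
) -> SignalTable:
    """Assign each signal the nearest reference metabolite by shift.

    A signal gets the reference entry whose chemical shift is nearest
    within that entry's tolerance, else ``"unknown"``.  Signals mapped
    to the same named metabolite must correlate pairwise at
    ``>= correlation_threshold`` across samples (they share one
    underlying concentration); a later-listed signal failing the check
    reverts to ``"unknown"`` with a warning.  Placeholder ``Unknown``
    reference rows are exempt from the correlation rule.
    """
    if reference is None:
        reference = load_reference_shifts()
    out = table.copy()
    if reference.empty:
        out.signals["assignment"] = "unknown"
        return out

    shifts = reference["shift_ppm"].to_numpy(float)
    assignments = {}
    for sid, row in out.signals.iterrows():
        d = np.abs(shifts - float(row["shift_ppm"]))
        j = int(np.argmin(d))
        tol = float(reference["tolerance_ppm"].iloc[j])
        assignments[sid] = (
            str(reference["metabolite"].iloc[j]) if d[j] <= tol else "unknown"
        )

    by_met: dict[str, list[str]] = {}
    for sid in out.signal_ids:
        name = assignments[sid]
        if name in ("unknown", "Unknown"):
            continue
        kept = by_met.setdefault(name, [])
        ok = True
        for other in kept:
            r = out.values[sid].corr(out.values[other])
            if not np.isfinite(r) or r < correlation_threshold:
                ok = False
                break
        if ok:
            kept.append(sid)
        else:
            logger.warning(
                "signal %s at %.5f ppm fails the correlation check for %s; "
                "reverting to unknown",
                sid,
                out.signals.loc[sid, "shift_ppm"],
                name,
            )
            assignments[sid] = "unknown"
    out.signals["assignment"] = pd.Series(assignments)
    return out


def build_signal_table(
    areas: pd.DataFrame,
    status: pd.DataFrame,
    signals: pd.DataFrame,
    nonwarped_spectra: pd.DataFrame,
    n_components: int = 10,
    reference: pd.DataFrame | None = None,
    correlation_threshold: float = 0.5,
) -> SignalTable:
    """Deconvolution output -> complete, assigned SignalTable.

    ``areas``/``status`` are samples x signals (status 'fitted' or
    'fit_failed').  Applies the 3*IQR discard per signal, trains the
    PLS rescue on fully-fitted rows and fills every discarded or failed
    cell with a ``pls_predicted`` value, then assigns metabolites.
    """
    values = areas.copy().astype(float)
    provenance = status.copy()
    values = values.mask(provenance != "fitted")
    for sid in values.columns:
        discard = discard_fit_outliers(values[sid].to_numpy())
        if discard.any():
            provenance.loc[values.index[discard], sid] = "discarded"
            values.loc[values.index[discard], sid] = np.nan

    needs_rescue = provenance.isin(["fit_failed", "discarded"])
    if needs_rescue.to_numpy().any():
        n_complete = len(values.dropna(axis=0))
        if n_complete - 1 < n_components:
            logger.warning(
                "only %d complete training rows; reducing PLS components "
                "from %d to %d",
                n_complete,
                n_components,
                max(n_complete - 1, 1),
            )
            n_components = max(n_complete - 1, 1)
        model = fit_pls_intensity_model(nonwarped_spectra, values, n_components)
        for sample in values.index[needs_rescue.any(axis=1)]:
            pred = predict_intensities(
                model, nonwarped_spectra.loc[sample].to_numpy()
            )
            for sid in values.columns[needs_rescue.loc[sample]]:
                values.loc[sample, sid] = pred[sid]
                provenance.loc[sample, sid] = "pls_predicted"

    table = SignalTable(values, provenance, signals)
    return assign_metabolites(table, reference, correlation_threshold)
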