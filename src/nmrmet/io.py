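"""Text file formats: spectra matrices, signal tables, reports.

The spectra-matrix format is a TSV whose header row is the descending
ppm grid and whose first column is the sample id, with a sidecar
metadata TSV (pulse_length_us, water_intensity, shim_proxy) keyed by
sample id.  Values are written at 17 significant digits, so a
write/read round trip is lossless at 1e-12 relative precision.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .types import JresProjection, Spectrum1D, SignalTable

logger = logging.getLogger(__name__)

__all__ = [
    "write_spectra_matrix",
    "read_spectra_matrix",
    "write_signal_table",
    "read_signal_table",
    "write_json",
    "read_json",
]

_FMT = "%.17g"


def write_spectra_matrix(
    spectra: list[Spectrum1D] | list[JresProjection],
    path: str | Path,
    metadata_path: str | Path | None = None,
) -> None:
    """Write spectra sharing one grid; optionally the metadata sidecar."""
    path = Path(path)
    with path.open("w") as fh:
        if not spectra:
            fh.write("sample_id\n")
            return
        ppm = spectra[0].ppm
        fh.write("sample_id\t" + "\t".join(_FMT % v for v in ppm) + "\n")
        for s in spectra:
            if s.ppm.shape != ppm.shape or not np.array_equal(s.ppm, ppm):
                raise ValueError(f"{s.sample_id}: not on the common grid")
            fh.write(s.sample_id + "\t" + "\t".join(_FMT % v for v in s.intensity) + "\n")
    if metadata_path is not None:
        meta = pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in spectra],
                "pulse_length_us": [getattr(s, "pulse_length_us", np.nan) for s in spectra],
                "water_intensity": [getattr(s, "water_intensity", np.nan) for s in spectra],
                "shim_proxy": [getattr(s, "shim_proxy", np.nan) for s in spectra],
            }
        )
        meta.to_csv(metadata_path, sep="\t", index=False, float_format=_FMT)


def read_spectra_matrix(
    path: str | Path,
    metadata_path: str | Path | None = None,
    as_projection: bool = False,
) -> list[Spectrum1D] | list[JresProjection]:
    """Read a spectra matrix; specific errors for malformed input."""
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.open() if ln.strip()]
    if len(lines) <= 1:
        warnings.warn(f"{path}: no spectra found", stacklevel=2)
        return []
    header = lines[0].split("\t")
    ppm = np.array([float(v) for v in header[1:]])
    if not np.all(np.diff(ppm) < 0):
        raise ValueError(f"{path}: header ppm grid is not strictly descending")

    meta = None
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", float_precision="round_trip").set_index("sample_id")

    seen: set[str] = set()
    out = []
    for ln in lines[1:]:
        fields = ln.split("\t")
        sid = fields[0]
        if len(fields) != len(header):
            raise ValueError(f"{path}: ragged row for sample {sid!r}")
        if sid in seen:
            raise ValueError(f"{path}: duplicate sample id {sid!r}")
        seen.add(sid)
        intensity = np.array([float(v) for v in fields[1:]])
        if as_projection:
            out.append(JresProjection(sample_id=sid, ppm=ppm, intensity=intensity))
        else:
            kw = {}
            if meta is not None and sid in meta.index:
                row = meta.loc[sid]
                kw = {
                    "pulse_length_us": float(row["pulse_length_us"]),
                    "water_intensity": float(row["water_intensity"]),
                    "shim_proxy": float(row["shim_proxy"]),
                }
            out.append(Spectrum1D(sample_id=sid, ppm=ppm, intensity=intensity, **kw))
    return out


def write_signal_table(table: SignalTable, prefix: str | Path) -> None:
    """Write values, provenance sidecar and signal metadata as TSVs."""
    prefix = Path(prefix)
    table.values.to_csv(f"{prefix}_values.tsv", sep="\t", float_format=_FMT)
    table.provenance.to_csv(f"{prefix}_provenance.tsv", sep="\t")
    table.signals.to_csv(f"{prefix}_signals.tsv", sep="\t", float_format=_FMT)


def read_signal_table(prefix: str | Path) -> SignalTable:
    prefix = Path(prefix)
    values = pd.read_csv(f"{prefix}_values.tsv", sep="\t", index_col=0, float_precision="round_trip")
    provenance = pd.read_csv(f"{prefix}_provenance.tsv", sep="\t", index_col=0, float_precision="round_trip")
    signals = pd.read_csv(f"{prefix}_signals.tsv", sep="\t", index_col=0, float_precision="round_trip")
    return SignalTable(values, provenance, signals)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
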