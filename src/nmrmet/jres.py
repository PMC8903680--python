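"""2-D J-resolved matrix handling: tilt, symmetrization, projection.

Multiplets in a J-resolved experiment appear skewed at 45 degrees in
the (F1, F2) plane.  Tilting shifts each row k (1-based over R rows) by
``0.4992 * (R/2 - k)`` points along the direct dimension, which stands
the multiplets upright; symmetrization about the central horizontal
lines (averaging each row with its mirror) suppresses residual
asymmetric artifacts; the sum projection over the indirect dimension
then yields a proton-decoupled-like 1-D trace in which each multiplet
collapses to a single peak at its chemical-shift center.
"""

from __future__ import annotations

import numpy as np

from .types import JresMatrix, JresProjection

__all__ = ["tilt_and_symmetrize_jres", "project_jres", "TILT_FACTOR"]

TILT_FACTOR = 0.4992


def tilt_and_symmetrize_jres(
    matrix: JresMatrix, tilt_factor: float = TILT_FACTOR
) -> JresMatrix:
    """Tilt rows by ``tilt_factor * (R/2 - k)`` points, then symmetrize.

    Fractional shifts use linear interpolation with zero fill at the
    edges; symmetrization replaces the data by the average of each row
    with its mirror row (k <-> R + 1 - k, 1-based).  Row count must be
    even (it is the zero-filled indirect dimension).
    """
    data = matrix.data
    rows, n = data.shape
    half = rows // 2
    cols = np.arange(n, dtype=float)
    tilted = np.empty_like(data)
    for k in range(1, rows + 1):  # 1-based row index, as conventional
        shift = tilt_factor * (half - k)
        # new[j] = old[j - shift]: content moves by +shift points
        tilted[k - 1] = np.interp(cols - shift, cols, data[k - 1], left=0.0, right=0.0)
    return JresMatrix(data=0.5 * (tilted + tilted[::-1, :]))


def project_jres(
    matrix: JresMatrix,
    ppm: np.ndarray | None = None,
    sample_id: str = "",
) -> JresProjection | np.ndarray:
    """Sum projection along the indirect dimension (column sums).

    With a ppm axis supplied the result is wrapped as a
    :class:`JresProjection`; otherwise the raw vector is returned.
    """
    proj = matrix.data.sum(axis=0)
    if ppm is None:
        return proj
    return JresProjection(sample_id=sample_id, ppm=np.asarray(ppm, float), intensity=proj)
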