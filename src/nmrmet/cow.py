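"""Correlation-optimized warping (COW) of spectra to a reference.

The reference axis is cut into near-equal segments; the sample's
segment boundaries may deviate from the reference boundaries by at most
``slack`` points per segment (so at most the cumulative slack overall,
optionally capped by ``max_drift``).  Each candidate sample segment is
linearly interpolated onto the reference segment length and scored by
its Pearson correlation with the reference segment; dynamic programming
over boundary positions maximizes the summed per-segment correlation.
Endpoints are fixed and the warped spectrum keeps the grid length.

Determinism on score ties: the path with the smallest cumulative
absolute boundary displacement wins, and remaining ties resolve to the
smallest boundary indices (compared from the last internal boundary
backwards, matching the backtracking order).
"""

from __future__ import annotations

import numpy as np

from .types import Spectrum1D, JresProjection, WarpPath

__all__ = ["cow_align", "apply_warp", "warp_intensity", "segment_correlation"]


def _reference_boundaries(n: int, segment_length: int) -> list[int]:
    n_seg = max(1, int(round((n - 1) / segment_length)))
    return [int(round(i * (n - 1) / n_seg)) for i in range(n_seg + 1)]


def segment_correlation(ref_seg: np.ndarray, samp: np.ndarray, a: int, b: int) -> float:
    """Pearson correlation of sample[a..b] (interpolated to the
    reference segment length) with the reference segment; zero-variance
    segments contribute 0."""
    m = ref_seg.size
    xs = np.linspace(a, b, m)
    vals = np.interp(xs, np.arange(samp.size), samp)
    sv = vals.std()
    sr = ref_seg.std()
    if sv == 0.0 or sr == 0.0:
        return 0.0
    return float(np.mean((vals - vals.mean()) * (ref_seg - ref_seg.mean())) / (sv * sr))


def _pair_scores(
    ref_seg: np.ndarray,
    samp: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
) -> np.ndarray:
    """Vectorized segment correlations for candidate (start, end) pairs."""
    m = ref_seg.size
    w = np.linspace(0.0, 1.0, m)
    pos = starts[:, None] + (ends - starts)[:, None] * w[None, :]
    vals = np.interp(pos.ravel(), np.arange(samp.size), samp).reshape(len(starts), m)
    vc = vals - vals.mean(axis=1, keepdims=True)
    rc = ref_seg - ref_seg.mean()
    denom = np.linalg.norm(vc, axis=1) * np.linalg.norm(rc)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = (vc @ rc) / denom
    scores[~np.isfinite(scores)] = 0.0
    scores[denom == 0] = 0.0
    return scores


def _offsets(i: int, n_seg: int, slack: int, bound: int, n: int, max_drift: int | None):
    lo = max(-i * slack, -(n_seg - i) * slack, -bound)
    hi = min(i * slack, (n_seg - i) * slack, n - 1 - bound)
    if max_drift is not None and 0 < i < n_seg:
        lo, hi = max(lo, -max_drift), min(hi, max_drift)
    return np.arange(lo, hi + 1)


def _dp_optimize(
    ref: np.ndarray,
    samp: np.ndarray,
    bounds: list[int],
    slack: int,
    max_drift: int | None = None,
) -> tuple[list[int], float]:
    """DP over sample boundary offsets; returns boundaries and score."""
    n = ref.size
    n_seg = len(bounds) - 1
    prev_off = _offsets(0, n_seg, slack, bounds[0], n, max_drift)
    score = {0: 0.0}
    disp = {0: 0}
    backs: list[dict[int, int]] = []
    for i in range(1, n_seg + 1):
        ref_seg = ref[bounds[i - 1] : bounds[i] + 1]
        L = bounds[i] - bounds[i - 1]
        cur_off = _offsets(i, n_seg, slack, bounds[i], n, max_drift)
        ends = bounds[i] + cur_off
        starts = bounds[i - 1] + prev_off
        d = ends[:, None] - starts[None, :]
        adm = (np.abs(d - L) <= slack) & (d >= 1)
        ui, vi = np.nonzero(adm)
        seg = np.full(adm.shape, np.nan)
        if ui.size:
            seg[ui, vi] = _pair_scores(ref_seg, samp, starts[vi], ends[ui])

        new_score: dict[int, float] = {}
        new_disp: dict[int, int] = {}
        back: dict[int, int] = {}
        for uj, u in enumerate(cur_off):
            best = None
            for vj, v in enumerate(prev_off):
                if not adm[uj, vj] or int(v) not in score:
                    continue
                s = score[int(v)] + seg[uj, vj]
                dd = disp[int(v)] + abs(int(u))
                cand = (s, -dd)
                if best is None or cand > best:
                    best = cand
                    back[int(u)] = int(v)
            if best is not None:
                new_score[int(u)] = best[0]
                new_disp[int(u)] = -best[1]
        score, disp = new_score, new_disp
        backs.append(back)
        prev_off = cur_off
    if 0 not in score:
        raise RuntimeError("no admissible warp (check slack/segment settings)")
    us = [0]
    for i in range(n_seg, 0, -1):
        us.append(backs[i - 1][us[-1]])
    us.reverse()
    boundaries = [bounds[i] + u for i, u in enumerate(us)]
    return boundaries, score[0]


def warp_intensity(path: WarpPath, y: np.ndarray) -> np.ndarray:
    """Interpolate y from the sample frame into the reference frame."""
    if y.size - 1 != path.reference_boundaries[-1]:
        raise ValueError("spectrum length incompatible with warp path")
    out = np.empty_like(y, dtype=float)
    idx = np.arange(y.size)
    for (r0, r1), (s0, s1) in zip(
        zip(path.reference_boundaries, path.reference_boundaries[1:]),
        zip(path.sample_boundaries, path.sample_boundaries[1:]),
    ):
        xs = np.linspace(s0, s1, r1 - r0 + 1)
        out[r0 : r1 + 1] = np.interp(xs, idx, y)
    return out


def cow_align(
    sample: Spectrum1D,
    reference: Spectrum1D,
    segment_length: int = 50,
    slack: int = 5,
    max_drift: int | None = None,
) -> tuple[Spectrum1D, WarpPath]:
    """Align ``sample`` to ``reference`` by COW.

    ``max_drift`` optionally caps the absolute boundary displacement
    (the cumulative-slack bound can allow large drifts on long grids
    that calibration has already ruled out).  Falls back to the
    identity warp in the degenerate case where the optimized warp would
    lower the global correlation with the reference (summed segment
    correlations do not formally bound it).
    """
    if sample.ppm.shape != reference.ppm.shape or not np.allclose(
        sample.ppm, reference.ppm
    ):
        raise ValueError("sample and reference must share one ppm grid")
    if segment_length < 4:
        raise ValueError("segment_length must be >= 4")
    if not 0 <= slack < segment_length:
        raise ValueError("slack must satisfy 0 <= slack < segment_length")

    bounds = _reference_boundaries(sample.ppm.size, segment_length)
    boundaries, score = _dp_optimize(
        reference.intensity, sample.intensity, bounds, slack, max_drift
    )
    path = WarpPath(
        reference_boundaries=bounds,
        sample_boundaries=boundaries,
        segment_length=segment_length,
        slack=slack,
        score=score,
    )
    warped = warp_intensity(path, sample.intensity)

    def _corr(a, b):
        if a.std() == 0 or b.std() == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    if _corr(warped, reference.intensity) < _corr(
        sample.intensity, reference.intensity
    ) - 1e-12:
        path = WarpPath(bounds, list(bounds), segment_length, slack, score=score)
        warped = sample.intensity.copy()
    return sample.with_intensity(warped), path


def apply_warp(
    path: WarpPath, spectrum: Spectrum1D | JresProjection
) -> Spectrum1D | JresProjection:
    """Apply a previously computed warp (e.g. the CPMG path to the
    paired JRES projection) with the identical interpolation rule."""
    return spectrum.with_intensity(warp_intensity(path, spectrum.intensity))
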