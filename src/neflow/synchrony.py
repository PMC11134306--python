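"""NE synchrony: sliding local:global correlation, regime split, distance profiles.

"NE synchrony" of a cell is the Pearson correlation between its local
(annulus) NE trace and its global NE trace inside a sliding window (default
30 s, dense 1-frame stride, window-centered). Averaging synchrony traces
across cells yields a run-level trace whose dips mark epochs when local NE
fields decouple from the shared field; frames below the run-average trace's
own mean define the "low synchrony" regime used to split regression fits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .preprocess import TraceSet

logger = logging.getLogger(__name__)


@dataclass
class RegimeSegmentation:
    average: np.ndarray  # run-average synchrony per frame (NaN at edges)
    high: np.ndarray  # bool, frames of high synchrony
    low: np.ndarray  # bool, frames of low synchrony
    low_period_s: np.ndarray  # lengths of contiguous low runs, seconds
    frame_hz: float


def sliding_correlation(
    x: np.ndarray,
    y: np.ndarray,
    frame_hz: float,
    window_s: float = 30.0,
) -> np.ndarray:
    """Windowed Pearson correlation of two traces, centered, dense stride.

    Frames where the full window does not fit (edges) and windows with zero
    variance are NaN.
    """
    x = np.asarray(x, np.float64)
    y = np.asarray(y, np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D traces")
    w = int(round(window_s * frame_hz))
    n = x.size
    if w < 3 or n < w:
        raise ValueError("trace shorter than the sliding window")
    csum = lambda a: np.concatenate([[0.0], np.cumsum(a)])
    sx, sy = csum(x), csum(y)
    sxx, syy, sxy = csum(x * x), csum(y * y), csum(x * y)
    win = lambda s: s[w:] - s[:-w]  # sums over each length-w window
    mx, my = win(sx) / w, win(sy) / w
    vx = win(sxx) / w - mx**2
    vy = win(syy) / w - my**2
    cxy = win(sxy) / w - mx * my
    out = np.full(n, np.nan)
    denom = vx * vy
    valid = denom > 1e-24
    n_zero = int((~valid).sum())
    if n_zero:
        logger.info("sliding correlation: %d zero-variance windows -> NaN",
                    n_zero)
    r = np.full(mx.size, np.nan)
    r[valid] = cxy[valid] / np.sqrt(denom[valid])
    np.clip(r, -1.0, 1.0, out=r)
    start = (w - 1) // 2  # window [t - start, t - start + w) centered on t
    out[start: start + r.size] = r
    return out


def synchrony_traces(
    traceset: TraceSet, window_s: float = 30.0
) -> np.ndarray:
    """Per-cell sliding local:global NE correlation, (n_cells, T)."""
    return np.stack([
        sliding_correlation(traceset.local_ne[i], traceset.global_ne[i],
                            traceset.frame_hz, window_s)
        for i in range(traceset.n_cells)
    ])


def segment_regimes(
    synchrony: np.ndarray, frame_hz: float
) -> RegimeSegmentation:
    """Split frames into high/low NE synchrony regimes.

    The run-average synchrony trace is compared with its own temporal mean:
    frames strictly below the mean are "low", the remaining defined frames
    are "high". The two masks partition the defined frames exactly.
    """
    syn = np.atleast_2d(np.asarray(synchrony, np.float64))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN edges
        avg = np.nanmean(syn, axis=0)
    defined = np.isfinite(avg)
    mean = np.nanmean(avg)
    low = defined & (avg < mean)
    high = defined & ~low
    # contiguous low runs in seconds
    padded = np.concatenate([[False], low, [False]])
    edges = np.diff(padded.astype(int))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    low_period_s = (ends - starts) / frame_hz
    return RegimeSegmentation(average=avg, high=high, low=low,
                              low_period_s=low_period_s, frame_hz=frame_hz)


def synchrony_distance_profile(
    synchrony: np.ndarray,
    centers_rc_px: np.ndarray,
    px_um: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise correlation of synchrony traces vs inter-cell distance.

    NaN frames (window edges) are excluded pairwise. Returns matched arrays
    (distance um, Pearson r), one entry per unordered cell pair.
    """
    syn = np.asarray(synchrony, np.float64)
    centers = np.asarray(centers_rc_px, np.float64)
    n = syn.shape[0]
    if n < 3:
        raise ValueError("need at least 3 cells")
    dists, rs = [], []
    for i in range(n):
        for j in range(i + 1, n):
            ok = np.isfinite(syn[i]) & np.isfinite(syn[j])
            if ok.sum() < 3:
                continue
            a, b = syn[i][ok], syn[j][ok]
            if a.std() == 0 or b.std() == 0:
                continue
            rs.append(float(np.corrcoef(a, b)[0, 1]))
            dists.append(float(np.linalg.norm(centers[i] - centers[j]) * px_um))
    return np.asarray(dists), np.asarray(rs)
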