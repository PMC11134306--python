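"""Spatial autocorrelation of the NE channel and field-correlation statistics.

The spatial structure of the sensor signal is summarized two ways:

* a grid autocorrelation: the FOV is tiled into small square patches
  (default 10 um), each patch's mean trace is correlated with every other
  patch's, and the correlations are binned by inter-patch distance. The
  decay of correlation with distance is summarized by a double-exponential
  fit, whose short length scale tracks the diffusive spread of release
  plumes.
* field correlation distributions: pairwise correlations among per-cell
  local NE traces versus each cell's local:global correlation, compared with
  a two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .preprocess import TraceSet, standardize

logger = logging.getLogger(__name__)


@dataclass
class AutocorrProfile:
    patch_um: float
    distances_um: np.ndarray  # binned center-to-center distances (0 first)
    r: np.ndarray  # mean Pearson r per distance bin
    n_pairs: np.ndarray = None  # pairs per bin
    standardized: bool = True
    fit: tuple[float, float, float, float] | None = None  # (a1, l1, a2, l2)
    fit_rss: float | None = None


def grid_autocorrelation(
    ne_movie: np.ndarray,
    px_um: float,
    frame_hz: float,
    patch_um: float = 10.0,
    standardized: bool = True,
    kernel_s: float = 1.0,
) -> AutocorrProfile:
    """Tile the FOV into ``patch_um`` squares and correlate patch traces.

    Each patch's pixel-mean trace is (optionally) detrended, smoothed and
    z-scored exactly like the regression predictors; all pairwise Pearson
    correlations are binned by center-to-center distance rounded to 1 um.
    The zero-distance (self) bin is included and is identically 1.
    """
    T, H, W = ne_movie.shape
    p = int(round(patch_um / px_um))
    if p < 2:
        raise ValueError("patch smaller than 2x2 px")
    nh, nw = H // p, W // p
    if nh * nw < 2:
        raise ValueError("FOV too small for more than one patch")
    crop = ne_movie[:, : nh * p, : nw * p]
    patches = crop.reshape(T, nh, p, nw, p).mean(axis=(2, 4)).reshape(T, nh * nw)
    traces = patches.T.astype(np.float64)
    if standardized:
        traces = np.stack([standardize(x, frame_hz, kernel_s) for x in traces])
    cmat = np.corrcoef(traces)
    centers = np.array([((i + 0.5) * p, (j + 0.5) * p)
                        for i in range(nh) for j in range(nw)])
    d = np.sqrt(((centers[:, None] - centers[None]) ** 2).sum(-1)) * px_um
    iu = np.triu_indices(nh * nw, k=0)
    dist = np.round(d[iu]).astype(int)
    rvals = cmat[iu]
    ok = np.isfinite(rvals)
    dist, rvals = dist[ok], rvals[ok]
    bins = np.unique(dist)
    mean_r = np.array([rvals[dist == b].mean() for b in bins])
    n_pairs = np.array([(dist == b).sum() for b in bins])
    return AutocorrProfile(patch_um=patch_um, distances_um=bins.astype(float),
                           r=mean_r, n_pairs=n_pairs, standardized=standardized)


def _double_exp(d, a1, l1, a2, l2):
    return a1 * np.exp(-d / l1) + a2 * np.exp(-d / l2)


def fit_double_exponential(
    profile: AutocorrProfile | tuple[np.ndarray, np.ndarray],
) -> tuple[float, float, float, float]:
    """Least-squares fit of r(d) = a1 exp(-d/l1) + a2 exp(-d/l2).

    Multi-start over length-scale initializations; the returned tuple is
    ordered so l1 <= l2. Raises if no start converges, carrying the best
    residual seen. A profile with no decay (all r equal) converges to
    a1 + a2 ~ r with unconstrained length scales; this degenerate case is
    flagged by a warning in the log.
    """
    if isinstance(profile, AutocorrProfile):
        d, r = profile.distances_um, profile.r
    else:
        d, r = profile
    d = np.asarray(d, float)
    r = np.asarray(r, float)
    if d.size < 6:
        raise ValueError("need at least 6 distance bins")
    span = max(d.max(), 1.0)
    starts = [(s1, s2) for s1, s2 in
              ((span / 20, span / 2), (span / 50, span / 5),
               (span / 10, span), (span / 5, span * 2))]
    best, best_rss = None, np.inf
    for l1_0, l2_0 in starts:
        try:
            popt, _ = optimize.curve_fit(
                _double_exp, d, r,
                p0=(r[0] * 0.6, l1_0, r[0] * 0.4, l2_0),
                bounds=([-2, 1e-6, -2, 1e-6], [2, 1e6, 2, 1e6]),
                maxfev=20000,
            )
            rss = float(((r - _double_exp(d, *popt)) ** 2).sum())
            if rss < best_rss:
                best, best_rss = popt, rss
        except RuntimeError:
            continue
    if best is None:
        raise RuntimeError("double-exponential fit failed from all starts; "
                           f"best residual = {best_rss}")
    a1, l1, a2, l2 = best
    if l1 > l2:
        a1, l1, a2, l2 = a2, l2, a1, l1
    if np.ptp(r) < 1e-12:
        logger.warning("flat correlation profile: length scales degenerate")
    if isinstance(profile, AutocorrProfile):
        profile.fit = (float(a1), float(l1), float(a2), float(l2))
        profile.fit_rss = best_rss
    return float(a1), float(l1), float(a2), float(l2)


def dominant_length_scale(fit: tuple[float, float, float, float]) -> float:
    """Length scale of the component with the larger amplitude weight."""
    a1, l1, a2, l2 = fit
    return l1 if abs(a1) >= abs(a2) else l2


def field_correlation_distributions(
    traceset: TraceSet,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Local:local vs local:global correlation samples and their KS test.

    Returns all pairwise Pearson r between local NE traces, each cell's
    local-vs-its-global r, and the two-sample KS statistic and p-value
    comparing the two samples. Constant traces are skipped with a log entry.
    """
    n = traceset.n_cells
    if n < 2:
        raise ValueError("need at least 2 cells")
    local = traceset.local_ne
    glob = traceset.global_ne
    ok = local.std(axis=1) > 0
    if not ok.all():
        logger.info("skipping %d constant local traces", int((~ok).sum()))
    ll = []
    for i, j in itertools.combinations(range(n), 2):
        if ok[i] and ok[j]:
            ll.append(float(np.corrcoef(local[i], local[j])[0, 1]))
    lg = []
    for i in range(n):
        if ok[i] and glob[i].std() > 0:
            lg.append(float(np.corrcoef(local[i], glob[i])[0, 1]))
    ll, lg = np.asarray(ll), np.asarray(lg)
    if np.ptp(ll) == 0 and np.ptp(lg) == 0 and ll[0] == lg[0]:
        return ll, lg, 0.0, 1.0
    ks, p = stats.ks_2samp(ll, lg)
    return ll, lg, float(ks), float(p)
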