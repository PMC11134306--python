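"""Raw two-channel movies to registered, cross-talk-corrected, standardized traces.

The processing chain mirrors common practice for dual-color two-photon
recordings of a green extracellular neuromodulator sensor and a red somatic
calcium indicator:

1. per-pixel 3-frame median filter and 2-frame mean binning (~30 -> ~15 Hz),
2. rigid translation registration against an early-segment average,
3. per-pixel cross-channel bleed-through removal by OLS residualization,
4. field geometry: soma mask, perisomatic annulus ("local" field), and the
   remaining field of view ("global" field) per cell,
5. mask-averaged traces, each detrended, temporally smoothed and z-scored.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from scipy.ndimage import gaussian_filter1d
from skimage.registration import phase_cross_correlation

logger = logging.getLogger(__name__)

GREEN, RED = 0, 1  # channel order: green = NE sensor, red = Ca sensor


@dataclass
class TwoChannelMovie:
    """Calibrated T x H x W x 2 stack. Channel 0 is green (NE), 1 is red (Ca)."""

    data: np.ndarray
    frame_hz: float
    px_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4 or self.data.shape[-1] != 2:
            raise ValueError("movie data must be T x H x W x 2")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("movie contains non-finite values")
        if self.frame_hz <= 0 or self.px_um <= 0:
            raise ValueError("frame_hz and px_um must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape_hw(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    def channel(self, idx: int) -> np.ndarray:
        return self.data[..., idx]


@dataclass
class FieldGeometry:
    """Per-cell soma, local-annulus and global masks over one field of view.

    Masks satisfy: soma_i and annulus_i are disjoint; annuli of different
    cells never share a pixel (overlap pixels are removed from the
    later-indexed cell); global_i = FOV - soma_i - annulus_i.
    """

    soma: np.ndarray  # (n_cells, H, W) bool
    annulus: np.ndarray  # (n_cells, H, W) bool
    radius_um: float
    px_um: float
    centroids: np.ndarray = field(default=None)  # (n_cells, 2) as (row, col)

    def __post_init__(self) -> None:
        if self.centroids is None:
            self.centroids = np.array(
                [np.argwhere(m).mean(axis=0) for m in self.soma]
            )

    @property
    def n_cells(self) -> int:
        return self.soma.shape[0]

    def global_mask(self, i: int) -> np.ndarray:
        return ~(self.soma[i] | self.annulus[i])


@dataclass
class TraceSet:
    """Standardized per-cell traces: soma Ca, local NE, global NE, population Ca.

    The population Ca trace of cell i is the mean of all *other* cells' soma
    traces. Every trace is detrended, temporally smoothed and z-scored; raw
    (unstandardized) mask means are kept for diagnostics.
    """

    ca: np.ndarray  # (n_cells, T)
    local_ne: np.ndarray
    global_ne: np.ndarray
    pop_ca: np.ndarray
    frame_hz: float
    raw_ca: np.ndarray = None
    raw_local_ne: np.ndarray = None
    raw_global_ne: np.ndarray = None

    @property
    def n_cells(self) -> int:
        return self.ca.shape[0]

    @property
    def n_frames(self) -> int:
        return self.ca.shape[1]


def median_filter_and_bin(movie: TwoChannelMovie) -> TwoChannelMovie:
    """3-frame running median per pixel, then non-overlapping 2-frame mean binning.

    Halves the frame rate (~30 Hz acquisition -> ~15 Hz analysis rate). An odd
    trailing frame is dropped and logged.
    """
    data = movie.data
    if data.shape[0] < 3:
        raise ValueError("need at least 3 frames for the temporal median filter")
    filtered = ndimage.median_filter(data, size=(3, 1, 1, 1), mode="nearest")
    T = filtered.shape[0]
    if T % 2:
        logger.info("dropping odd trailing frame before 2-frame binning")
        filtered = filtered[: T - 1]
    binned = filtered.reshape(T // 2, 2, *filtered.shape[1:]).mean(axis=1)
    return TwoChannelMovie(binned, frame_hz=movie.frame_hz / 2, px_um=movie.px_um)


def register_translation(
    movie: TwoChannelMovie,
    reference: np.ndarray | None = None,
    reference_s: float = 300.0,
    upsample_factor: int = 10,
    channel: int | None = RED,
) -> tuple[TwoChannelMovie, np.ndarray]:
    """Rigid-translation registration of every frame to a reference image.

    Shifts are estimated on the structural (red, somatic) channel by default
    — the NE channel's plumes move on their own and would hijack the
    correlation peak — and applied identically to both channels. The
    reference defaults to the temporal average of the first ``reference_s``
    seconds (or the whole movie if shorter). A shift exceeding 10% of the
    FOV is clamped and the frame flagged with a warning.

    Returns the registered movie and the (T, 2) per-frame (row, col) shifts
    that were *applied* (i.e., minus the estimated displacement).
    """
    data = movie.data
    T, H, W = data.shape[:3]
    combined = data.sum(axis=-1) if channel is None else data[..., channel]
    # estimate on lightly blurred frames: suppresses pixel noise that
    # otherwise dominates the correlation peak; shifts are applied to the
    # raw data
    combined = ndimage.gaussian_filter(combined, sigma=(0, 1.5, 1.5))
    if reference is None:
        n_ref = max(1, min(T, int(round(reference_s * movie.frame_hz))))
        reference = combined[:n_ref].mean(axis=0)
    limit = 0.1 * min(H, W)
    shifts = np.zeros((T, 2))
    out = np.empty_like(data)
    for t in range(T):
        shift, _, _ = phase_cross_correlation(
            reference, combined[t], upsample_factor=upsample_factor,
            normalization=None,
        )
        if np.any(np.abs(shift) > limit):
            warnings.warn(
                f"frame {t}: estimated shift {shift} exceeds 10% of FOV; clamped"
            )
            shift = np.clip(shift, -limit, limit)
        # snap near-integer estimates: avoids needless interpolation blur
        # and makes integer translations exactly reversible
        near_int = np.round(shift)
        if np.abs(shift - near_int).max() < 0.15:
            shift = near_int
        shifts[t] = shift
        if np.allclose(shift, 0):
            out[t] = data[t]
        else:
            for c in range(2):
                out[t, ..., c] = ndimage.shift(
                    data[t, ..., c], shift, order=1, mode="nearest"
                )
    return TwoChannelMovie(out, movie.frame_hz, movie.px_um), shifts


def _disk(shape: tuple[int, int], center_rc: tuple[float, float], radius_px: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center_rc[0]) ** 2 + (cc - center_rc[1]) ** 2 <= radius_px**2


def soma_masks_from_labels(labels: np.ndarray) -> np.ndarray:
    """Split a label image (0 = background) into a (n, H, W) boolean stack."""
    ids = np.unique(labels)
    ids = ids[ids > 0]
    return np.stack([labels == i for i in ids])


def build_fields(
    soma_masks: np.ndarray,
    radius_um: float = 15.0,
    px_um: float = 1.47,
) -> FieldGeometry:
    """Build the local-annulus and global field for each soma mask.

    The local field is the disk of ``radius_um`` around the soma centroid,
    excluding the soma itself, any other cell's soma, and any pixel already
    claimed by a lower-indexed cell's annulus (overlaps are removed, not
    split). The global field is everything else in the FOV for that cell.
    """
    soma = np.asarray(soma_masks).astype(bool)
    if soma.ndim == 2:
        soma = soma_masks_from_labels(soma_masks)
    n, H, W = soma.shape
    any_soma = soma.any(axis=0)
    radius_px = radius_um / px_um
    claimed = np.zeros((H, W), bool)
    annuli = np.zeros_like(soma)
    centroids = np.array([np.argwhere(m).mean(axis=0) for m in soma])
    for i in range(n):
        ann = _disk((H, W), tuple(centroids[i]), radius_px) & ~any_soma & ~claimed
        if not ann.any():
            raise ValueError(
                f"cell {i}: annulus of radius {radius_um} um fully consumed "
                "by soma/annulus overlaps"
            )
        annuli[i] = ann
        claimed |= ann
    return FieldGeometry(soma=soma, annulus=annuli, radius_um=radius_um,
                         px_um=px_um, centroids=centroids)


def bleedthrough_correct(movie: TwoChannelMovie) -> TwoChannelMovie:
    """Remove cross-channel contamination by per-pixel OLS residualization.

    For every pixel, each channel's time series is replaced by the residual
    of its least-squares regression on the *original* other channel's series
    at the same pixel. Residuals are zero-mean by construction; pixels whose
    regressor has zero variance keep their centered original series.
    """
    g = movie.data[..., GREEN]
    r = movie.data[..., RED]
    gm = g.mean(axis=0, dtype=np.float64)
    rm = r.mean(axis=0, dtype=np.float64)
    var_g = np.einsum("tij,tij->ij", g, g, dtype=np.float64) / g.shape[0] - gm**2
    var_r = np.einsum("tij,tij->ij", r, r, dtype=np.float64) / r.shape[0] - rm**2
    cov = np.einsum("tij,tij->ij", g, r, dtype=np.float64) / g.shape[0] - gm * rm
    slope_g_on_r = np.where(var_r > 0, cov / np.where(var_r > 0, var_r, 1), 0.0)
    slope_r_on_g = np.where(var_g > 0, cov / np.where(var_g > 0, var_g, 1), 0.0)
    n_degenerate = int((var_r == 0).sum() + (var_g == 0).sum())
    if n_degenerate:
        logger.info("bleed-through: %d zero-variance regressor pixels; residual "
                    "= centered original there", n_degenerate)
    dt = np.float32 if movie.data.dtype == np.float32 else np.float64
    out = np.empty_like(movie.data, dtype=dt)
    out[..., GREEN] = g - gm.astype(dt)
    out[..., GREEN] -= slope_g_on_r.astype(dt) * (r - rm.astype(dt))
    out[..., RED] = r - rm.astype(dt)
    out[..., RED] -= slope_r_on_g.astype(dt) * (g - gm.astype(dt))
    return TwoChannelMovie(out, movie.frame_hz, movie.px_um)


def standardize(
    trace: np.ndarray,
    frame_hz: float,
    kernel_s: float = 1.0,
    detrend_order: int = 1,
) -> np.ndarray:
    """Detrend, Gaussian-smooth (sigma = kernel_s seconds) and z-score a trace."""
    x = np.asarray(trace, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("standardize expects a 1-D trace")
    if not np.all(np.isfinite(x)):
        raise ValueError("trace contains non-finite values")
    n = x.size
    if n <= max(3, int(kernel_s * frame_hz)):
        raise ValueError("trace shorter than the smoothing kernel")
    if detrend_order == 1:
        x = signal.detrend(x, type="linear")
    elif detrend_order == 0:
        x = x - x.mean()
    else:
        t = np.arange(n, dtype=np.float64)
        coef = np.polynomial.polynomial.polyfit(t, x, detrend_order)
        x = x - np.polynomial.polynomial.polyval(t, coef)
    if kernel_s > 0:
        x = gaussian_filter1d(x, sigma=kernel_s * frame_hz, mode="nearest")
    sd = x.std()
    scale = max(float(np.abs(trace).max()), 1.0)
    if sd < 1e-10 * scale or not np.isfinite(sd):
        raise ValueError("zero variance after detrending; cannot z-score")
    x = (x - x.mean()) / sd
    # exact unit moments, robust to accumulated float error
    x = (x - x.mean()) / x.std()
    return x


def extract_traces(
    movie: TwoChannelMovie,
    geometry: FieldGeometry,
    kernel_s: float = 1.0,
    detrend_order: int = 1,
) -> TraceSet:
    """Mask-averaged traces per cell, each standardized after averaging.

    Per cell: soma-mean red (Ca), annulus-mean green (local NE), global-mask
    mean green (global NE) and the mean of all other cells' soma Ca traces
    (population Ca).
    """
    H, W = movie.shape_hw
    if geometry.soma.shape[1:] != (H, W):
        raise ValueError("geometry masks do not match movie shape")
    g = movie.data[..., GREEN]
    r = movie.data[..., RED]
    n = geometry.n_cells
    T = movie.n_frames
    raw_ca = np.stack([r[:, geometry.soma[i]].mean(axis=1) for i in range(n)])
    raw_local = np.stack([g[:, geometry.annulus[i]].mean(axis=1) for i in range(n)])
    # global-mask mean = (FOV sum - soma sum - annulus sum) / n_global px,
    # avoiding a full-FOV copy per cell
    g_total = g.sum(axis=(1, 2), dtype=np.float64)
    n_px = H * W
    raw_global = np.empty((n, T))
    for i in range(n):
        n_excl = int(geometry.soma[i].sum() + geometry.annulus[i].sum())
        excl = (g[:, geometry.soma[i]].sum(axis=1, dtype=np.float64)
                + g[:, geometry.annulus[i]].sum(axis=1, dtype=np.float64))
        raw_global[i] = (g_total - excl) / (n_px - n_excl)
    pop = np.empty((n, T))
    if n == 1:
        logger.info("single cell: population Ca trace undefined, set to 0")
        pop[:] = 0.0
    else:
        for i in range(n):
            others = np.delete(np.arange(n), i)
            pop[i] = raw_ca[others].mean(axis=0)
    std = lambda x: standardize(x, movie.frame_hz, kernel_s=kernel_s,
                                detrend_order=detrend_order)
    pop_z = (np.zeros((n, T)) if n == 1
             else np.stack([std(x) for x in pop]))
    return TraceSet(
        ca=np.stack([std(x) for x in raw_ca]),
        local_ne=np.stack([std(x) for x in raw_local]),
        global_ne=np.stack([std(x) for x in raw_global]),
        pop_ca=pop_z,
        frame_hz=movie.frame_hz,
        raw_ca=raw_ca,
        raw_local_ne=raw_local,
        raw_global_ne=raw_global,
    )
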