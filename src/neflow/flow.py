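"""Optic-flow extraction of NE release and reuptake events.

Release and reuptake are read out of the NE channel as flow patterns: a
growing region of fluorescence produces outward flow (a *source* critical
point), a receding region inward flow (a *sink*). A source whose center
fluorescence is more than ``z_thresh`` SD above the pixel mean, followed by
a nearby high-fluorescence sink, is one *release* event; the low-fluorescence
analog is one *reuptake* event.

Pipeline: spatially blur and temporally smooth the movie, detrend and
z-score per pixel; Horn-Schunck flow between consecutive frames; critical
points of each flow field classified by the Jacobian eigenvalues (source,
sink, saddle, spiral-in, spiral-out); per-frame points linked into pattern
tracks; typed tracks paired source -> sink into events. Spatial and temporal
release/reuptake correlations, an expression-heterogeneity control and a
permutation noise control complete the analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal, stats

logger = logging.getLogger(__name__)

PATTERN_TYPES = ("source", "sink", "saddle", "spiral-in", "spiral-out")


@dataclass
class PatternEvent:
    """One critical point of one frame's flow field."""

    type: str
    frame: int
    y: float  # row, px
    x: float  # col, px
    z: float  # preprocessed (z-scored) fluorescence at the center


@dataclass
class PatternTrack:
    """A persistent critical point: same-type points linked across frames.

    ``z_ext`` is the center z-value of largest magnitude over the track's
    lifetime — temporal smoothing makes patterns appear before/after the
    fluorescence transient peaks, so the extreme (not the mean) identifies
    the event phase. ``frames``/``zs`` keep the per-point samples for
    threshold-crossing timing.
    """

    type: str
    t_start: int
    t_end: int
    y: float  # position at the extreme-z point
    x: float
    z_ext: float
    frames: np.ndarray
    zs: np.ndarray
    n_points: int

    @property
    def z(self) -> float:
        return self.z_ext

    def first_crossing(self, thresh: float, sign: int) -> int | None:
        """Earliest frame where sign * z >= thresh."""
        hit = np.flatnonzero(sign * self.zs >= thresh)
        return int(self.frames[hit[0]]) if hit.size else None

    def last_crossing(self, thresh: float, sign: int) -> int | None:
        hit = np.flatnonzero(sign * self.zs >= thresh)
        return int(self.frames[hit[-1]]) if hit.size else None

    @property
    def t_ext(self) -> int:
        """Frame of the extreme center z."""
        return int(self.frames[int(np.argmax(np.abs(self.zs)))])


@dataclass
class NEEvent:
    """A paired source -> sink episode classified as release or reuptake."""

    kind: str  # "release" | "reuptake"
    onset: int  # frame of the source track start
    offset: int  # frame of the sink track end
    y: float
    x: float
    duration_s: float


@dataclass
class EventPipelineResult:
    events: list[NEEvent]
    unpaired: list[PatternTrack]
    tracks: list[PatternTrack]
    release_map: np.ndarray | None
    reuptake_map: np.ndarray | None
    spatial_r: float
    temporal_r: float
    n_frames: int


def preprocess_for_flow(
    ne_movie: np.ndarray,
    frame_hz: float,
    sigma_px: float = 12.0,
    kernel_s: float = 5.0,
    detrend: bool = True,
    min_sd_frac: float = 0.02,
) -> np.ndarray:
    """Blur, smooth, detrend and z-score the NE movie for optic flow.

    Spatial Gaussian of ``sigma_px``; temporal Gaussian of ``kernel_s``
    seconds; per-pixel linear detrend; per-pixel z-score over time. Pixels
    with (near-)zero temporal variance — below ``min_sd_frac`` of the 99th
    percentile pixel SD — are set to zero and excluded downstream: z-scoring
    a signal-free pixel would amplify numerically negligible fluctuations
    into unit-variance structure.
    """
    m = np.asarray(ne_movie, np.float32)
    if m.ndim != 3:
        raise ValueError("expected a single-channel T x H x W movie")
    out = ndimage.gaussian_filter(m, sigma=(0, sigma_px, sigma_px),
                                  mode="nearest")
    if kernel_s > 0:
        out = ndimage.gaussian_filter1d(out, sigma=kernel_s * frame_hz,
                                        axis=0, mode="nearest")
    out = out.astype(np.float64)
    if detrend:
        out = signal.detrend(out, axis=0, type="linear")
    else:
        out -= out.mean(axis=0)
    sd = out.std(axis=0)
    floor = min_sd_frac * float(np.percentile(sd, 99))
    eps = 1e-6 * float(max(np.abs(m).max(), 1e-12))
    bad = sd <= max(floor, eps)
    if bad.any():
        logger.info("flow preprocessing: %d (near-)zero-variance pixels "
                    "set to 0", int(bad.sum()))
    sd[bad] = 1.0
    out /= sd
    out[:, bad] = 0.0
    return out.astype(np.float32)


_AVG_KERNEL = np.array([[1 / 12, 1 / 6, 1 / 12],
                        [1 / 6, 0.0, 1 / 6],
                        [1 / 12, 1 / 6, 1 / 12]], dtype=np.float32)


def horn_schunck(
    f0: np.ndarray,
    f1: np.ndarray,
    alpha: float = 1.0,
    n_iter: int = 200,
    tol: float = 1e-4,
) -> np.ndarray:
    """Horn-Schunck flow between two frames; returns (H, W, 2) as (vy, vx).

    Minimizes the brightness-constancy residual plus ``alpha**2`` times a
    smoothness penalty via the classical Jacobi iteration with 3x3
    neighborhood averages; stops when the mean absolute update falls below
    ``tol`` or after ``n_iter`` iterations. As ``alpha`` grows the solution
    approaches a globally uniform translation.
    """
    f0 = np.asarray(f0, np.float32)
    f1 = np.asarray(f1, np.float32)
    if f0.shape != f1.shape or f0.ndim != 2:
        raise ValueError("need two same-shape 2-D frames")
    if not (np.all(np.isfinite(f0)) and np.all(np.isfinite(f1))):
        raise ValueError("non-finite input frames")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    favg = 0.5 * (f0 + f1)
    ey, ex = np.gradient(favg)
    et = f1 - f0
    den = (np.float32(alpha) ** 2 + ex**2 + ey**2).astype(np.float32)
    u = np.zeros_like(f0)  # vy
    v = np.zeros_like(f0)  # vx
    for _ in range(n_iter):
        ubar = ndimage.convolve(u, _AVG_KERNEL, mode="nearest")
        vbar = ndimage.convolve(v, _AVG_KERNEL, mode="nearest")
        t = (ey * ubar + ex * vbar + et) / den
        un = ubar - ey * t
        vn = vbar - ex * t
        delta = np.abs(un - u).mean() + np.abs(vn - v).mean()
        u, v = un, vn
        if delta < tol:
            break
    return np.stack([u, v], axis=-1)


def flow_series(
    movie: np.ndarray,
    alpha: float = 1.0,
    n_iter: int = 200,
    tol: float = 1e-4,
) -> np.ndarray:
    """Per-frame-pair Horn-Schunck flow: (T-1, H, W, 2) as (vy, vx).

    Each pair iterates independently with its own early stop: quiet frames
    converge within a handful of Jacobi sweeps.
    """
    T = movie.shape[0]
    out = np.empty((T - 1, *movie.shape[1:], 2), dtype=np.float32)
    for t in range(T - 1):
        out[t] = horn_schunck(movie[t], movie[t + 1], alpha, n_iter, tol)
    return out


def find_critical_points(
    flow: np.ndarray,
    frame: int = 0,
    z_frame: np.ndarray | None = None,
    min_speed: float = 0.0,
) -> list[PatternEvent]:
    """Locate and classify critical points of one (H, W, 2) flow field.

    Candidates are 2x2 plaquettes where both velocity components change
    sign; adjacent candidate plaquettes are merged and their centroid taken
    as the (sub-pixel) critical point. The local Jacobian's eigenvalues
    classify the point: both real parts positive -> source, negative ->
    sink, real of opposite sign -> saddle, complex with positive/negative
    real part -> spiral-out / spiral-in. ``z_frame`` supplies the
    preprocessed fluorescence sampled at the center. ``min_speed`` gates
    candidates on the peak flow speed in their 7x7 neighborhood: a genuine
    source or sink drives strong flow nearby, whereas sign flips in
    near-zero (noise-level) flow do not.
    """
    u = flow[..., 0]
    v = flow[..., 1]
    if not np.all(np.isfinite(flow)):
        raise ValueError("non-finite flow field")
    speed = np.hypot(u, v)
    if min_speed > 0:
        local_max = ndimage.maximum_filter(speed, size=7)
    su, sv = np.sign(u), np.sign(v)

    def _mixed(s):
        mx = np.maximum(np.maximum(s[:-1, :-1], s[:-1, 1:]),
                        np.maximum(s[1:, :-1], s[1:, 1:]))
        mn = np.minimum(np.minimum(s[:-1, :-1], s[:-1, 1:]),
                        np.minimum(s[1:, :-1], s[1:, 1:]))
        # a zero corner counts as a crossing when the other sign is present
        # (exact zero lines occur in analytic fields)
        return ((mx > 0) & (mn <= 0)) | ((mx >= 0) & (mn < 0))

    cand = _mixed(su) & _mixed(sv)
    if not cand.any():
        return []
    labels, n = ndimage.label(cand)
    centroids = ndimage.center_of_mass(cand, labels, np.arange(1, n + 1))
    duy, dux = np.gradient(u)
    dvy, dvx = np.gradient(v)
    H, W = u.shape
    out = []
    for cy, cx in centroids:
        yy, xx = cy + 0.5, cx + 0.5  # plaquette (i,j) spans corners i..i+1
        iy, ix = int(round(yy)), int(round(xx))
        iy = min(max(iy, 0), H - 1)
        ix = min(max(ix, 0), W - 1)
        if min_speed > 0 and local_max[iy, ix] < min_speed:
            continue
        jac = np.array([[duy[iy, ix], dux[iy, ix]],
                        [dvy[iy, ix], dvx[iy, ix]]])
        eig = np.linalg.eigvals(jac)
        re = eig.real
        if np.abs(eig.imag).max() > 1e-9:
            ptype = "spiral-out" if re.mean() > 0 else "spiral-in"
        elif re[0] > 0 and re[1] > 0:
            ptype = "source"
        elif re[0] < 0 and re[1] < 0:
            ptype = "sink"
        else:
            ptype = "saddle"
        z = float(z_frame[iy, ix]) if z_frame is not None else np.nan
        out.append(PatternEvent(type=ptype, frame=frame, y=float(yy),
                                x=float(xx), z=z))
    return out


def detect_patterns(
    processed: np.ndarray,
    flows: np.ndarray,
    speed_gate_frac: float = 0.3,
    edge_exclude: int = 0,
) -> list[PatternEvent]:
    """Critical points for every frame pair, tagged with center z-values.

    ``speed_gate_frac`` scales a movie-level speed threshold (fraction of
    the 99th percentile flow speed) below which candidate critical points
    are discarded as noise-level sign flips. ``edge_exclude`` drops the
    first/last frames, where the temporal smoother and detrend are edge-
    distorted; the speed threshold is computed on the retained frames only.
    """
    t0, t1 = edge_exclude, flows.shape[0] - edge_exclude
    if t1 <= t0:
        raise ValueError("edge_exclude leaves no frames")
    min_speed = 0.0
    if speed_gate_frac > 0:
        sample = np.hypot(flows[t0:t1, ..., 0], flows[t0:t1, ..., 1])
        min_speed = speed_gate_frac * float(np.percentile(sample, 99))
    pats: list[PatternEvent] = []
    for t in range(t0, t1):
        pats.extend(find_critical_points(flows[t], frame=t,
                                         z_frame=processed[t],
                                         min_speed=min_speed))
    return pats


def merge_events(
    events: list[NEEvent],
    frame_hz: float,
    px_um: float,
    merge_dist_um: float = 15.0,
    merge_gap_s: float = 2.0,
) -> list[NEEvent]:
    """Non-maximum suppression of duplicate detections.

    One plume can shed several fragmented source/sink tracks and hence
    several near-identical events. Events of the same kind whose centers lie
    within ``merge_dist_um`` and whose spans overlap (onset inside the
    earlier event's interval extended by ``merge_gap_s``) are merged into
    the earliest one.
    """
    out: list[NEEvent] = []
    gap_f = merge_gap_s * frame_hz
    dist_px = merge_dist_um / px_um
    for e in sorted(events, key=lambda e: e.onset):
        merged = False
        for kept in out:
            if kept.kind != e.kind:
                continue
            if (e.onset <= kept.offset + gap_f
                    and np.hypot(e.y - kept.y, e.x - kept.x) <= dist_px):
                kept.offset = max(kept.offset, e.offset)
                kept.duration_s = (kept.offset - kept.onset) / frame_hz
                merged = True
                break
        if not merged:
            out.append(NEEvent(**e.__dict__))
    return out


def track_patterns(
    patterns: list[PatternEvent],
    link_dist_px: float = 10.0,
    max_gap_frames: int = 3,
    min_persist: int = 2,
) -> list[PatternTrack]:
    """Link same-type critical points across frames into pattern tracks.

    Greedy nearest-neighbor linking within ``link_dist_px`` and a frame gap
    of at most ``max_gap_frames``. A same-frame point within linking
    distance of a track's head is absorbed as a duplicate detection of the
    same structure. Tracks with fewer than ``min_persist`` points are
    discarded as flicker.
    """
    tracks: list[list[PatternEvent]] = []
    open_tracks: list[list[PatternEvent]] = []
    for p in sorted(patterns, key=lambda p: p.frame):
        best, best_d = None, np.inf
        duplicate = False
        for tr in open_tracks:
            last = tr[-1]
            if last.type != p.type:
                continue
            if p.frame - last.frame > max_gap_frames:
                continue
            d = np.hypot(p.y - last.y, p.x - last.x)
            if d > link_dist_px:
                continue
            if p.frame == last.frame:
                duplicate = True
                continue
            if d < best_d:
                best, best_d = tr, d
        if best is not None:
            best.append(p)
        elif not duplicate:
            tr = [p]
            tracks.append(tr)
            open_tracks.append(tr)
        open_tracks = [tr for tr in open_tracks
                       if p.frame - tr[-1].frame <= max_gap_frames]
    out = []
    for tr in tracks:
        if len(tr) < min_persist:
            continue
        zs = np.array([p.z for p in tr], float)
        k = int(np.nanargmax(np.abs(zs)))
        out.append(PatternTrack(
            type=tr[0].type,
            t_start=tr[0].frame,
            t_end=tr[-1].frame,
            y=float(tr[k].y),
            x=float(tr[k].x),
            z_ext=float(zs[k]),
            frames=np.array([p.frame for p in tr]),
            zs=zs,
            n_points=len(tr),
        ))
    return out


def classify_and_pair(
    tracks: list[PatternTrack],
    frame_hz: float,
    px_um: float,
    z_thresh: float = 1.0,
    max_gap_s: float = 30.0,
    max_dist_um: float = 20.0,
) -> tuple[list[NEEvent], list[PatternTrack]]:
    """Pair high-fluorescence sources with subsequent high sinks (release),
    and low sources with low sinks (reuptake).

    Greedy earliest-source-first; each candidate sink is used at most once;
    among sinks inside ``max_dist_um`` the earliest subsequent one (extreme
    z after the source onset, within ``max_gap_s``) is taken. Event onset is
    the frame where the source's center z first crosses the threshold (the
    raw track start is smeared earlier by the temporal smoothing); the
    offset is the frame where the sink's center z last crosses it. Unpaired
    typed tracks are returned, not dropped.
    """
    events: list[NEEvent] = []
    unpaired: list[PatternTrack] = []
    max_gap_f = max_gap_s * frame_hz
    max_dist_px = max_dist_um / px_um
    for sign in (+1, -1):
        kind = "release" if sign > 0 else "reuptake"
        sources = [t for t in tracks
                   if t.type == "source" and sign * t.z_ext >= z_thresh]
        sinks = [t for t in tracks
                 if t.type == "sink" and sign * t.z_ext >= z_thresh]
        sources.sort(key=lambda t: t.first_crossing(z_thresh, sign))
        sinks.sort(key=lambda t: t.t_ext)
        used = [False] * len(sinks)
        for src in sources:
            onset = src.first_crossing(z_thresh, sign)
            chosen = None
            for k, snk in enumerate(sinks):
                if used[k] or snk.t_ext <= onset:
                    continue
                if snk.t_ext - onset > max_gap_f:
                    break
                if np.hypot(snk.y - src.y, snk.x - src.x) <= max_dist_px:
                    chosen = k
                    break
            if chosen is None:
                unpaired.append(src)
            else:
                used[chosen] = True
                snk = sinks[chosen]
                offset = snk.last_crossing(z_thresh, sign)
                events.append(NEEvent(
                    kind=kind, onset=onset, offset=offset,
                    y=0.5 * (src.y + snk.y), x=0.5 * (src.x + snk.x),
                    duration_s=(offset - onset) / frame_hz,
                ))
        unpaired.extend(s for k, s in enumerate(sinks) if not used[k])
    return sorted(events, key=lambda e: e.onset), unpaired


def event_maps_and_correlations(
    events: list[NEEvent],
    shape: tuple[int, int],
    n_frames: int,
    splat_sigma_px: float = 2.0,
) -> tuple[np.ndarray | None, np.ndarray | None, float, float]:
    """Occurrence heatmaps and the release/reuptake spatial and temporal r.

    Spatial r: each event splats a Gaussian (sigma = ``splat_sigma_px``) at
    its center; the two normalized maps are linearized and Pearson-
    correlated. Temporal r: Pearson correlation between the per-frame counts
    of active (onset <= t <= offset) release vs reuptake events. Undefined
    quantities (no events of a kind, or a constant map/count series) are
    returned as NaN.
    """
    def _map(kind):
        sel = [e for e in events if e.kind == kind]
        if not sel:
            return None, None
        m = np.zeros(shape)
        counts = np.zeros(n_frames)
        for e in sel:
            iy = min(max(int(round(e.y)), 0), shape[0] - 1)
            ix = min(max(int(round(e.x)), 0), shape[1] - 1)
            m[iy, ix] += 1
            counts[e.onset: min(e.offset, n_frames - 1) + 1] += 1
        m = ndimage.gaussian_filter(m, splat_sigma_px, mode="constant")
        s = m.sum()
        if s > 0:
            m = m / s
        return m, counts

    rel_map, rel_counts = _map("release")
    reup_map, reup_counts = _map("reuptake")
    spatial_r = np.nan
    temporal_r = np.nan
    if rel_map is not None and reup_map is not None:
        a, b = rel_map.ravel(), reup_map.ravel()
        if a.std() > 0 and b.std() > 0:
            spatial_r = float(np.corrcoef(a, b)[0, 1])
        else:
            logger.info("degenerate event map: spatial correlation undefined")
        if rel_counts.std() > 0 and reup_counts.std() > 0:
            temporal_r = float(np.corrcoef(rel_counts, reup_counts)[0, 1])
        else:
            logger.info("constant count series: temporal correlation undefined")
    return rel_map, reup_map, spatial_r, temporal_r


def run_event_pipeline(
    ne_movie: np.ndarray,
    frame_hz: float,
    px_um: float,
    sigma_px: float = 12.0,
    kernel_s: float = 5.0,
    alpha: float = 1.0,
    n_iter: int = 200,
    tol: float = 1e-4,
    z_thresh: float = 1.0,
    max_gap_s: float = 30.0,
    max_dist_um: float = 20.0,
    link_dist_px: float = 10.0,
    max_gap_frames: int = 3,
    min_persist: int = 2,
    splat_sigma_px: float = 2.0,
    speed_gate_frac: float = 0.3,
    merge_dist_um: float = 15.0,
    merge_gap_s: float = 2.0,
) -> EventPipelineResult:
    """Full movie -> events -> correlation statistics chain.

    Frames within twice the temporal smoothing kernel of the movie edges
    are excluded from pattern detection (filter edge effects).
    """
    processed = preprocess_for_flow(ne_movie, frame_hz, sigma_px, kernel_s)
    flows = flow_series(processed, alpha=alpha, n_iter=n_iter, tol=tol)
    edge = min(int(round(2 * kernel_s * frame_hz)),
               max(0, (flows.shape[0] - 10) // 2))
    patterns = detect_patterns(processed, flows, speed_gate_frac,
                               edge_exclude=edge)
    tracks = track_patterns(patterns, link_dist_px=link_dist_px,
                            max_gap_frames=max_gap_frames,
                            min_persist=min_persist)
    events, unpaired = classify_and_pair(
        tracks, frame_hz, px_um, z_thresh=z_thresh,
        max_gap_s=max_gap_s, max_dist_um=max_dist_um)
    events = merge_events(events, frame_hz, px_um,
                          merge_dist_um=merge_dist_um,
                          merge_gap_s=merge_gap_s)
    rel_map, reup_map, spatial_r, temporal_r = event_maps_and_correlations(
        events, ne_movie.shape[1:], ne_movie.shape[0],
        splat_sigma_px=splat_sigma_px)
    return EventPipelineResult(
        events=events, unpaired=unpaired, tracks=tracks,
        release_map=rel_map, reuptake_map=reup_map,
        spatial_r=spatial_r, temporal_r=temporal_r,
        n_frames=ne_movie.shape[0],
    )


def distance_to_event(
    events: list[NEEvent],
    center_rc_px: tuple[float, float],
    n_frames: int,
    px_um: float,
    kind: str = "release",
) -> np.ndarray:
    """Distance (um) from a cell to the nearest active event at each frame.

    An event is active while onset <= t <= offset; frames with no active
    event are NaN.
    """
    sel = [e for e in events if e.kind == kind]
    if not sel:
        raise ValueError(f"no {kind} events")
    out = np.full(n_frames, np.inf)
    cy, cx = center_rc_px
    for e in sel:
        d = np.hypot(e.y - cy, e.x - cx) * px_um
        lo, hi = max(0, e.onset), min(n_frames - 1, e.offset)
        np.minimum(out[lo: hi + 1], d, out=out[lo: hi + 1])
    out[np.isinf(out)] = np.nan
    return out


def log_regression_synchrony(
    distance_um: np.ndarray,
    synchrony: np.ndarray,
) -> tuple[float, float, float, float]:
    """OLS of synchrony on ln(distance + 1 um).

    Returns (intercept, slope, slope p-value, R^2), computed over frames
    where both series are defined; requires >= 30 such frames.
    """
    import statsmodels.api as sm

    d = np.asarray(distance_um, float)
    s = np.asarray(synchrony, float)
    ok = np.isfinite(d) & np.isfinite(s)
    if ok.sum() < 30:
        raise ValueError("fewer than 30 paired defined frames")
    x = np.log(d[ok] + 1.0)
    if np.ptp(x) == 0:
        raise ValueError("degenerate distances: all equal")
    X = sm.add_constant(x)
    fit = sm.OLS(s[ok], X).fit()
    return (float(fit.params[0]), float(fit.params[1]),
            float(fit.pvalues[1]), float(fit.rsquared))


def expression_control(
    map_a: np.ndarray,
    map_b: np.ndarray,
    mean_fluorescence: np.ndarray,
) -> float:
    """Partial spatial correlation of two event maps given sensor expression.

    Both linearized maps are residualized (OLS with intercept) on the
    linearized time-mean fluorescence map; the Pearson correlation of the
    residuals is returned. A constant fluorescence map reduces to the plain
    correlation; zero-variance residuals yield NaN.
    """
    a = np.asarray(map_a, float).ravel()
    b = np.asarray(map_b, float).ravel()
    f = np.asarray(mean_fluorescence, float).ravel()
    if not (a.shape == b.shape == f.shape):
        raise ValueError("maps must share a shape")
    if np.ptp(f) == 0:
        logger.info("constant expression map: partial r equals plain r")
        return float(np.corrcoef(a, b)[0, 1])

    def _resid(y):
        X = np.column_stack([np.ones_like(f), f])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return y - X @ beta

    ra, rb = _resid(a), _resid(b)
    if ra.std() < 1e-8 * max(a.std(), 1e-300) or \
            rb.std() < 1e-8 * max(b.std(), 1e-300):
        logger.warning("zero-variance residuals after expression control")
        return float("nan")
    return float(np.corrcoef(ra, rb)[0, 1])


def make_null_movie(
    template: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Random movie matching the template's per-pixel mean, SD and value
    distribution: each pixel's time series is independently permuted."""
    return rng.permuted(np.asarray(template), axis=0)


@dataclass
class NoiseControlResult:
    null: dict[str, np.ndarray]
    p: dict[str, float]
    n: int


def noise_control(
    observed: dict[str, float],
    template_movie: np.ndarray,
    frame_hz: float,
    px_um: float,
    n: int = 500,
    rng: np.random.Generator | None = None,
    **pipeline_kwargs,
) -> NoiseControlResult:
    """Permutation noise control for event-correlation statistics.

    Generates ``n`` random movies matched to the template's per-pixel
    mean/SD/distribution (time-permuted pixels), runs the full
    flow -> event -> correlation pipeline on each, and returns the null
    distribution and a two-tailed p-value per observed statistic:
    ``p = (1 + #{|null| >= |observed|}) / (n_finite + 1)``. NaN null draws
    (runs without both event kinds) are excluded from the count.
    """
    if n < 20:
        raise ValueError("n < 20 gives too coarse a p-value resolution")
    if rng is None:
        rng = np.random.default_rng()
    null: dict[str, list[float]] = {k: [] for k in observed}
    for _ in range(n):
        movie = make_null_movie(template_movie, rng)
        res = run_event_pipeline(movie, frame_hz, px_um, **pipeline_kwargs)
        for k in observed:
            null[k].append(getattr(res, k))
    arrays = {k: np.asarray(v, float) for k, v in null.items()}
    p = {}
    for k, obs in observed.items():
        vals = arrays[k]
        finite = vals[np.isfinite(vals)]
        if finite.size == 0 or not np.isfinite(obs):
            p[k] = float("nan")
        else:
            p[k] = float((1 + (np.abs(finite) >= abs(obs)).sum())
                         / (finite.size + 1))
    return NoiseControlResult(null=arrays, p=p, n=n)
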