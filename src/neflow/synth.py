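"""Synthetic two-channel movie generator with known ground truth.

Emulates the statistical structure of dual-color two-photon recordings of an
extracellular norepinephrine (NE) sensor (green) and a somatic calcium
indicator (red):

* a tonic NE baseline plus a slow shared ("global") drive,
* localized diffusive release plumes from point sources (axonal
  varicosities), rising then clearing with a first-order time constant,
* reuptake dips that preferentially revisit previously used release sites
  with a temporal lag,
* neuronal Ca traces coupled to perisomatic (annulus-mean) NE and to a
  shared population signal, convolved with a calcium kernel,
* rendering to two fluorescence channels with cross-channel bleed-through,
  Gaussian sensor noise and optional slow rigid drift,
* a reuptake-blocked ("desipramine") condition: phasic amplitudes shrink,
  clearance slows, background reuptake nearly vanishes, and a slowly rising
  tonic ramp accumulates across the field.

Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.ndimage import gaussian_filter1d, shift as nd_shift

from .preprocess import GREEN, RED, TwoChannelMovie, _disk, standardize

logger = logging.getLogger(__name__)

CONDITIONS = ("saline", "desipramine")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic recording, with imaging-realistic defaults.

    Geometry/timing defaults follow the acquisition this emulates: a
    256 x 256 px field of view at 1.47 um/px, analyzed at ~15 Hz. Event
    amplitudes are expressed as fractional fluorescence change relative to a
    tonic baseline of 1.
    """

    fov_px: tuple[int, int] = (256, 256)
    px_um: float = 1.47
    frame_hz: float = 15.0
    duration_s: float = 300.0
    n_cells: int = 20
    n_varicosities: int = 40
    release_rate_hz: float = 0.02  # per varicosity, before burst modulation
    diffusion_sigma_um: float = 12.0
    release_amp: float = 1.0
    rise_tau_s: float = 1.0
    reuptake_rate_hz: float = 0.012  # total reuptake-event rate per varicosity
    reuptake_tau_s: float = 4.0
    reuptake_amp_frac: float = 0.7
    colocation_prob: float = 0.8
    reuptake_delay_s: float = 12.0
    burst_on_s: float = 20.0
    burst_off_s: float = 40.0
    burst_gain: float = 4.0
    global_drive_amp: float = 0.1
    global_drive_tau_s: float = 20.0
    beta_local: float = 0.3
    beta_globalCa: float = 0.5
    ca_rectification: float = 0.1
    gain_modulation: float = 0.0  # shared-drive gain on the local coupling
    beta_interaction: float = 0.0  # local x global NE coupling (coupled epochs)
    cell_noise_tau_s: float = 4.0
    ca_tau_s: float = 1.0
    sensor_tau_s: float = 1.0  # NE sensor response kinetics; 0 = instantaneous
    annulus_radius_um: float = 15.0
    soma_radius_um: float = 4.5
    bleedthrough_frac: float = 0.1
    noise_sd: float = 0.15
    structured_noise_sd: float = 0.01  # slow, ~16 px-scale background noise
    structured_noise_tau_s: float = 5.0
    soma_green_suppression: float = 0.9  # NE sensor expresses on neuropil
    drift_px_per_min: float = 0.0
    varicosities_at_cells: bool = False  # release sites inside each annulus
    sites_per_cell: int = 1  # perisomatic sites per cell (varicosities_at_cells)
    site_radius_um: float | None = None  # max site distance from soma center
    burst_per_site: bool = False  # independent (asynchronous) bursts per site
    condition: str = "saline"
    seed: int = 0
    # desipramine condition scalings
    desipramine_amp_scale: float = 0.25
    desipramine_drive_scale: float = 0.3
    desipramine_reuptake_scale: float = 0.1
    desipramine_tau_scale: float = 8.0
    desipramine_ramp_amp: float = 1.0
    desipramine_ramp_tau_s: float = 300.0
    desipramine_coupling_scale: float = 0.5  # receptor desensitization

    def __post_init__(self) -> None:
        self.fov_px = tuple(int(v) for v in self.fov_px)
        if any(v < 8 for v in self.fov_px):
            raise ValueError("fov_px too small")
        for name in ("px_um", "frame_hz", "duration_s", "diffusion_sigma_um",
                     "release_amp", "rise_tau_s", "reuptake_tau_s",
                     "reuptake_amp_frac", "reuptake_delay_s", "burst_on_s",
                     "burst_off_s", "burst_gain", "global_drive_tau_s",
                     "cell_noise_tau_s", "ca_tau_s", "annulus_radius_um",
                     "soma_radius_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("release_rate_hz", "reuptake_rate_hz", "global_drive_amp",
                     "noise_sd", "drift_px_per_min", "ca_rectification"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.bleedthrough_frac < 0.5:
            raise ValueError("bleedthrough_frac must lie in [0, 0.5)")
        if not 0 <= self.colocation_prob <= 1:
            raise ValueError("colocation_prob must lie in [0, 1]")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_hz))

    def effective(self) -> "SimulationConfig":
        """Condition-resolved parameters (desipramine scalings applied)."""
        if self.condition == "saline":
            return self
        return replace(
            self,
            release_amp=self.release_amp * self.desipramine_amp_scale,
            global_drive_amp=self.global_drive_amp * self.desipramine_drive_scale,
            reuptake_rate_hz=self.reuptake_rate_hz * self.desipramine_reuptake_scale,
            reuptake_tau_s=self.reuptake_tau_s * self.desipramine_tau_scale,
            condition="saline",  # marker: already resolved
        )


@dataclass
class EventTruth:
    kind: str  # "release" | "reuptake"
    onset: int  # frame
    offset: int  # frame (exclusive of decay tail below 5% of peak)
    x: float  # column, px
    y: float  # row, px
    amp: float

    def center(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass
class GroundTruth:
    events: list[EventTruth]
    cell_centers: np.ndarray = None  # (n_cells, 2) as (row, col) px
    planted_betas: np.ndarray = None  # (n_cells, 2): (beta_local, beta_globalCa)
    diffusion_sigma_um: float = 0.0
    soma_labels: np.ndarray = None  # (H, W) uint16 label image
    drift_shifts: np.ndarray = None  # (T, 2) planted (row, col) shifts
    global_drive: np.ndarray = None  # (T,) shared slow NE drive component
    burst_state: np.ndarray = None  # (T,) bool, shared release-volley state

    def events_of(self, kind: str) -> list[EventTruth]:
        return [e for e in self.events if e.kind == kind]

    def to_json(self) -> str:
        d = {
            "events": [asdict(e) for e in self.events],
            "cell_centers": None if self.cell_centers is None
            else np.asarray(self.cell_centers).tolist(),
            "planted_betas": None if self.planted_betas is None
            else np.asarray(self.planted_betas).tolist(),
            "diffusion_sigma_um": self.diffusion_sigma_um,
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, s: str) -> "GroundTruth":
        d = json.loads(s)
        return cls(
            events=[EventTruth(**e) for e in d["events"]],
            cell_centers=None if d["cell_centers"] is None
            else np.asarray(d["cell_centers"]),
            planted_betas=None if d["planted_betas"] is None
            else np.asarray(d["planted_betas"]),
            diffusion_sigma_um=d["diffusion_sigma_um"],
        )


def _ou(T: int, dt: float, tau_s: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Ornstein-Uhlenbeck sample path."""
    a = math.exp(-dt / tau_s)
    x = np.empty(T)
    x[0] = rng.standard_normal()
    innov = rng.standard_normal(T - 1) * math.sqrt(1 - a * a)
    for t in range(1, T):
        x[t] = a * x[t - 1] + innov[t - 1]
    return x


class _PlumeModel:
    """Diffusing, clearing Gaussian plume from a point source.

    A release of total mass ``M(dt) = (1 - exp(-dt/rise)) * exp(-dt/tau)``
    spreads as a 2-D Gaussian whose scale grows diffusively,
    ``sigma(dt)^2 = sigma0^2 + 2 D dt``, with D set so the plume reaches the
    configured ``diffusion_sigma_um`` one clearance time after onset. The
    spatial integral is proportional to M(dt): constant once the release
    transient finishes and until clearance removes mass. The center-amplitude
    profile is normalized so its temporal peak equals ``amp``.
    """

    def __init__(self, sigma_target_px: float, rise_s: float, tau_s: float,
                 dt: float, max_frames: int | None = None):
        self.sigma0 = max(1.0, sigma_target_px / 3.0)
        self.diff = max((sigma_target_px**2 - self.sigma0**2) / (2 * tau_s), 0.0)
        self.rise_s = rise_s
        self.tau_s = tau_s
        self.dt = dt
        # center amplitude before normalization: M(t) * sigma0^2 / sigma(t)^2
        n_max = int(round((rise_s + 8 * tau_s) / dt)) + 1
        if max_frames is not None:
            n_max = min(n_max, max(int(max_frames), 2))
        t = np.arange(n_max) * dt
        self.sigma2 = self.sigma0**2 + 2 * self.diff * t
        mass = (1.0 - np.exp(-t / rise_s)) * np.exp(-t / tau_s)
        center = mass * self.sigma0**2 / self.sigma2
        peak = center.max()
        self.center_amp = center / peak  # unit peak
        peak_i = int(np.argmax(self.center_amp))
        below = np.flatnonzero(self.center_amp[peak_i:] < 0.05)
        self.offset_len = int(peak_i + (below[0] if below.size else
                                        n_max - peak_i))
        keep = np.flatnonzero(self.center_amp[peak_i:] < 0.01)
        self.n_active = int(peak_i + (keep[0] if keep.size
                                      else n_max - peak_i))

    def sigma_px(self, frame_lag: int | np.ndarray) -> np.ndarray:
        return np.sqrt(self.sigma2[frame_lag])

    @property
    def half(self) -> int:
        return int(math.ceil(3.0 * float(self.sigma_px(self.n_active - 1))))

    def canonical_block(self) -> np.ndarray:
        """Unit-peak (n_active, 2h+1, 2h+1) plume centered on the window.

        All events share this block (scaled by their amplitude); centers are
        pasted at the nearest pixel, a sub-pixel approximation that is small
        against the plume scale.
        """
        if not hasattr(self, "_block"):
            h = self.half
            yy, xx = np.mgrid[-h: h + 1, -h: h + 1]
            r2 = (yy**2 + xx**2).astype(np.float32)
            s2 = self.sigma2[: self.n_active, None, None].astype(np.float32)
            block = np.exp(-r2[None] / (2 * s2))
            block *= self.center_amp[: self.n_active, None, None].astype(
                np.float32)
            self._block = block
        return self._block


def _burst_state(T: int, dt: float, on_s: float, off_s: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Two-state telegraph (1 = bursting) with exponential dwell times."""
    state = np.zeros(T, dtype=bool)
    t = 0
    on = rng.random() < on_s / (on_s + off_s)
    while t < T:
        dwell = max(1, int(round(rng.exponential(on_s if on else off_s) / dt)))
        state[t: t + dwell] = on
        t += dwell
        on = not on
    return state


def simulate_ne_field(config: SimulationConfig,
                      rng: np.random.Generator | None = None,
                      events: list[EventTruth] | None = None,
                      site_centers: np.ndarray | None = None,
                      ) -> tuple[np.ndarray, GroundTruth]:
    """Simulate the latent NE concentration field and its event ground truth.

    The field is ``baseline + global drive + sum(release plumes)
    - sum(reuptake dips)``; each plume is a spatial Gaussian of scale
    ``diffusion_sigma_um`` with a rise-then-clear temporal profile. Release
    times are Poisson per varicosity, modulated by a slow on/off burst state
    (local release arrives in volleys, producing pronounced low-synchrony
    epochs). Each reuptake event revisits a previously used release site with
    probability ``colocation_prob``, lagged by the release clearance plus an
    exponential delay; the remainder occur at random sites and times.

    Under the desipramine condition, phasic amplitudes and the shared drive
    shrink, clearance slows, background reuptake nearly vanishes and a
    saturating tonic ramp is added, emulating transporter blockade.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    eff = config.effective()
    H, W = config.fov_px
    T = config.n_frames
    dt = 1.0 / config.frame_hz
    sigma_px = eff.diffusion_sigma_um / eff.px_um
    margin = max(2.0, 1.5 * sigma_px)

    field_arr = np.ones((T, H, W), dtype=np.float32)
    drive = np.zeros(T)
    if eff.global_drive_amp > 0:
        drive = eff.global_drive_amp * _ou(T, dt, eff.global_drive_tau_s, rng)
        field_arr += drive[:, None, None].astype(np.float32)
    if config.condition == "desipramine":
        t_s = np.arange(T) * dt
        ramp = config.desipramine_ramp_amp * (
            1.0 - np.exp(-t_s / config.desipramine_ramp_tau_s)
        )
        field_arr += ramp[:, None, None].astype(np.float32)

    plume = _PlumeModel(sigma_px, eff.rise_tau_s, eff.reuptake_tau_s,
                        dt, max_frames=T)
    burst = np.zeros(T, dtype=bool)

    def _offset_frame(onset: int) -> int:
        return min(T - 1, onset + plume.offset_len)

    if events is not None:
        events = [replace(e, offset=_offset_frame(e.onset)) for e in events]
    else:
        events = []
        if site_centers is not None:
            sites = np.asarray(site_centers, float)
        else:
            sites = np.column_stack([
                rng.uniform(margin, H - margin, eff.n_varicosities),
                rng.uniform(margin, W - margin, eff.n_varicosities),
            ])
        n_sites = sites.shape[0]

        # release times: per-frame thinning of the burst-modulated rate.
        # burst_gain = 1 disables modulation (homogeneous Poisson);
        # burst_per_site draws an independent telegraph per varicosity
        # (asynchronous local release), else one shared state.
        def _mult(b):
            if eff.burst_gain == 1.0:
                return np.ones(T)
            return np.where(b, eff.burst_gain, 0.2)

        if eff.burst_per_site:
            site_bursts = [_burst_state(T, dt, eff.burst_on_s, eff.burst_off_s,
                                        rng) for _ in range(n_sites)]
            burst = np.zeros(T, dtype=bool)  # shared state unused
        else:
            shared = _burst_state(T, dt, eff.burst_on_s, eff.burst_off_s, rng)
            if eff.burst_gain == 1.0:
                shared = np.zeros(T, dtype=bool)
            site_bursts = None
            burst = shared

        if site_bursts is not None:
            for k in range(n_sites):
                rate_k = eff.release_rate_hz * _mult(site_bursts[k])
                for f in np.flatnonzero(rng.random(T) < rate_k * dt):
                    if f >= T - 2:
                        continue
                    events.append(EventTruth(
                        kind="release", onset=int(f),
                        offset=_offset_frame(int(f)),
                        x=float(sites[k][1]), y=float(sites[k][0]),
                        amp=eff.release_amp,
                    ))
            events.sort(key=lambda e: e.onset)
        else:
            rate = n_sites * eff.release_rate_hz * _mult(burst)
            for f in np.flatnonzero(rng.random(T) < rate * dt):
                if f >= T - 2:
                    continue
                site = sites[rng.integers(n_sites)]
                events.append(EventTruth(
                    kind="release", onset=int(f), offset=_offset_frame(int(f)),
                    x=float(site[1]), y=float(site[0]), amp=eff.release_amp,
                ))

        # reuptake: gated to the burst-off phase (clearance rebounds between
        # release volleys, making release and reuptake counts anti-phase);
        # sites preferentially revisit previously used release locations.
        # With per-site bursts the gate is each site's own off phase.
        reup_amp = eff.reuptake_amp_frac * eff.release_amp
        min_lag_f = int(round(eff.reuptake_delay_s / dt))
        releases = [e for e in events]

        def _add_reuptake(f: int, site_k: int) -> None:
            prior = [e for e in releases if e.onset + min_lag_f <= f]
            if prior and rng.random() < eff.colocation_prob:
                src = prior[rng.integers(len(prior))]
                y, x = src.y, src.x
            else:
                site = sites[site_k]
                y, x = float(site[0]), float(site[1])
            events.append(EventTruth(
                kind="reuptake", onset=int(f), offset=_offset_frame(int(f)),
                x=float(x), y=float(y), amp=-reup_amp,
            ))

        if site_bursts is not None:
            for k in range(n_sites):
                off = ~site_bursts[k]
                off_frac = max(off.sum(), 1) / T
                rate_k = eff.reuptake_rate_hz / off_frac * off.astype(float)
                for f in np.flatnonzero(rng.random(T) < rate_k * dt):
                    if f < T - 2:
                        _add_reuptake(int(f), k)
        else:
            off = ~burst
            off_frac = max(off.sum(), 1) / T
            reup_rate = (n_sites * eff.reuptake_rate_hz / off_frac
                         * off.astype(float))
            for f in np.flatnonzero(rng.random(T) < reup_rate * dt):
                if f < T - 2:
                    _add_reuptake(int(f), int(rng.integers(n_sites)))
        events.sort(key=lambda e: e.onset)

    if not events:
        warnings.warn("duration too short to contain any event at given rates; "
                      "returning an event-free movie")

    # paint plumes into the field: one shared canonical block, scaled
    half = plume.half
    block = plume.canonical_block()
    for e in sorted(events, key=lambda e: e.onset):
        n_active = min(T - e.onset, plume.n_active)
        r0, c0 = int(round(e.y)), int(round(e.x))
        rlo, rhi = max(0, r0 - half), min(H, r0 + half + 1)
        clo, chi = max(0, c0 - half), min(W, c0 + half + 1)
        sub = (slice(None, n_active),
               slice(rlo - (r0 - half), rlo - (r0 - half) + (rhi - rlo)),
               slice(clo - (c0 - half), clo - (c0 - half) + (chi - clo)))
        field_arr[e.onset: e.onset + n_active, rlo:rhi, clo:chi] += (
            np.float32(e.amp) * block[sub]
        )

    np.maximum(field_arr, 0.05, out=field_arr)
    truth = GroundTruth(events=sorted(events, key=lambda e: e.onset),
                        diffusion_sigma_um=eff.diffusion_sigma_um,
                        global_drive=drive, burst_state=burst)
    return field_arr, truth


def place_cell_centers(config: SimulationConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """Jittered grid of soma centers at >= 2 annulus radii separation."""
    H, W = config.fov_px
    sep_px = 2 * config.annulus_radius_um / config.px_um
    margin = config.annulus_radius_um / config.px_um + 2
    rows = np.arange(margin, H - margin + 1e-9, sep_px)
    cols = np.arange(margin, W - margin + 1e-9, sep_px)
    capacity = rows.size * cols.size
    if config.n_cells > capacity:
        raise ValueError(
            f"n_cells={config.n_cells} exceeds the {capacity} centers packable "
            f"at >= 2 annulus radii ({2 * config.annulus_radius_um:g} um) "
            f"separation in a {H}x{W} px FOV"
        )
    grid = np.array([(r, c) for r in rows for c in cols])
    idx = rng.permutation(capacity)[: config.n_cells]
    jitter = rng.uniform(-2, 2, size=(config.n_cells, 2))
    return grid[np.sort(idx)] + jitter


def _annulus_mask(shape, center_rc, r_out_px, r_in_px):
    return _disk(shape, center_rc, r_out_px) & ~_disk(shape, center_rc, r_in_px)


def simulate_cells(
    ne_movie: np.ndarray,
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    centers: np.ndarray | None = None,
) -> np.ndarray:
    """Simulate per-cell calcium traces coupled to the latent NE field.

    Each cell's latent drive is ``beta_local * z(annulus-mean NE)
    + beta_globalCa * z(shared population signal)
    + ca_rectification * (z(annulus NE)^2 - 1)/sqrt(2) + noise``, with the
    noise level set so the latent has unit variance; the trace is then
    convolved with a unit-area single-exponential calcium kernel
    (``ca_tau_s`` decay). The mild quadratic (rectification) term models the
    supralinear fluorescence response of calcium indicators to the underlying
    NE drive. Cell centers, planted betas and soma geometry are written into
    ``truth``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    T, H, W = ne_movie.shape
    dt = 1.0 / config.frame_hz
    if centers is None:
        centers = place_cell_centers(config, rng)
    soma_r_px = config.soma_radius_um / config.px_um
    ann_r_px = config.annulus_radius_um / config.px_um

    pop_sig = _ou(T, dt, 2.0, rng)
    pop_sig = (pop_sig - pop_sig.mean()) / pop_sig.std()

    # supralinear response to the shared NE drive: the quadratic of the
    # slow global drive, orthogonalized against its linear part. During
    # coupled (high-synchrony) epochs the local x global product tracks this
    # convexity; during decoupled epochs local events dominate the product
    # and the quadratic drops out of the fitted interaction.
    zg_c = standardize(ne_movie.mean(axis=(1, 2)).astype(np.float64),
                       config.frame_hz, kernel_s=1.0)
    if truth.global_drive is not None and truth.global_drive.std() > 0:
        s = standardize(truth.global_drive, config.frame_hz, kernel_s=1.0)
    else:
        s = zg_c
    qg = s**2
    qg = qg - qg.mean() - (np.dot(qg - qg.mean(), s) / np.dot(s, s)) * s
    qg_sd = qg.std()
    qg = qg / qg_sd if qg_sd > 0 else qg

    # calcium kernel: unit-area decaying exponential (length >= 1; a very
    # short ca_tau_s degenerates to the identity)
    klen = max(1, int(round(6 * config.ca_tau_s / dt)))
    kern = np.exp(-np.arange(klen) * dt / config.ca_tau_s)
    kern /= kern.sum()

    traces = np.empty((config.n_cells, T))
    eff_b1 = config.beta_local * (
        config.desipramine_coupling_scale
        if config.condition == "desipramine" else 1.0)
    betas = np.tile([eff_b1, config.beta_globalCa], (config.n_cells, 1))
    for i, (r0, c0) in enumerate(centers):
        ann = _annulus_mask((H, W), (r0, c0), ann_r_px, soma_r_px)
        # perisomatic NE as the cell integrates it: detrended, smoothed over
        # ~1 s (receptor/integration timescale), unit variance — the same
        # construction the analysis uses for its local-NE predictor
        zl = standardize(ne_movie[:, ann].mean(axis=1).astype(np.float64),
                         config.frame_hz, kernel_s=1.0)
        # gain modulation: the shared NE state scales the cell's
        # responsiveness to its perisomatic NE, planting a true
        # local x global interaction of strength beta_local * gain_modulation.
        # The modulation saturates during release volleys (receptors near
        # ceiling), so the interaction exists only in the coupled epochs;
        # gain is rectified at a small positive floor.
        mod = config.gain_modulation * s
        off_gate = 1.0
        if truth.burst_state is not None and truth.burst_state.any():
            off_gate = (~truth.burst_state).astype(float)
            mod = mod * off_gate
        gain = np.maximum(1.0 + mod, 0.1)
        b_local = config.beta_local
        if config.condition == "desipramine":
            # sustained tonic NE desensitizes adrenergic receptors,
            # weakening the cell's response to NE fluctuations
            b_local = b_local * config.desipramine_coupling_scale
        det = (b_local * zl * gain
               + config.beta_globalCa * pop_sig
               + config.ca_rectification * qg)
        if config.beta_interaction != 0.0:
            # direct local x global NE interaction drive, present only
            # outside release volleys (during volleys the receptors
            # saturate and the multiplicative coupling collapses)
            inter = zl * zg_c
            inter = (inter - inter.mean()) / inter.std()
            det = det + config.beta_interaction * inter * off_gate
        # noise shares the signals' slow spectrum (OU, cell_noise_tau_s) so
        # that downstream smoothing + z-scoring leaves the planted
        # coefficients on the standardized scale; its variance completes the
        # latent to unit variance
        sd_noise = math.sqrt(max(1.0 - det.var(), 0.0))
        noise = _ou(T, dt, config.cell_noise_tau_s, rng)
        noise = (noise - noise.mean()) / noise.std() * sd_noise
        latent = det + noise
        traces[i] = np.convolve(latent, kern)[:T]

    truth.cell_centers = centers
    truth.planted_betas = betas
    labels = np.zeros((H, W), dtype=np.uint16)
    for i, (r0, c0) in enumerate(centers):
        labels[_disk((H, W), (r0, c0), soma_r_px)] = i + 1
    truth.soma_labels = labels
    return traces


def render_two_channel(
    ne_movie: np.ndarray,
    ca_traces: np.ndarray,
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> TwoChannelMovie:
    """Render the latent NE field and Ca traces into a noisy 2-channel movie.

    Green = NE field scaled by the sensor-expression map (suppressed inside
    somata: the NE sensor expresses on neuropil) + bleed-through from red;
    red = Ca fluorescence painted into soma disks over a constant neuropil
    background + bleed-through from green. Gaussian sensor noise of
    ``noise_sd`` is added per pixel to both channels and an optional slow
    rigid drift is applied; the planted per-frame drift shifts are stored in
    ``truth.drift_shifts``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    T, H, W = ne_movie.shape
    if ca_traces.shape != (truth.cell_centers.shape[0], T):
        raise ValueError("ca_traces shape inconsistent with truth/movie")
    expr = np.where(truth.soma_labels > 0,
                    np.float32(1.0 - config.soma_green_suppression),
                    np.float32(1.0))
    green = ne_movie.astype(np.float32, copy=True)
    if config.sensor_tau_s > 0:
        # the GPCR sensor reports NE through first-order binding kinetics:
        # an exponential low-pass matching the Ca indicator's timescale.
        # Filtered in row chunks to bound the float64 working set; starts
        # from steady state at the first frame (no onset transient).
        from scipy.signal import lfilter

        a = math.exp(-1.0 / (config.sensor_tau_s * config.frame_hz))
        for r0 in range(0, H, 16):
            blk = green[:, r0: r0 + 16]
            zi = (a * blk[0])[None]
            out, _ = lfilter([1 - a], [1, -a], blk, axis=0, zi=zi)
            green[:, r0: r0 + 16] = out
    green *= expr
    red = np.full((T, H, W), 0.2, dtype=np.float32)
    for i in range(ca_traces.shape[0]):
        mask = truth.soma_labels == i + 1
        red[:, mask] = (1.0 + 0.25 * ca_traces[i].astype(np.float32))[:, None]
    btf = np.float32(config.bleedthrough_frac)
    data = np.empty((T, H, W, 2), dtype=np.float32)
    np.multiply(red, btf, out=data[..., GREEN])
    data[..., GREEN] += green
    np.multiply(green, btf, out=data[..., RED])
    data[..., RED] += red
    del green, red
    if config.structured_noise_sd > 0:
        # slow spatially structured background (tissue/optical artifacts):
        # AR(1) in time on a coarse 16 px grid, bilinearly upsampled. Unlike
        # shot noise it does not average away within a mask, setting the
        # noise floor of field traces.
        from scipy.signal import lfilter as _lfilter

        hc, wc = max(2, H // 16), max(2, W // 16)
        a = math.exp(-1.0 / (config.structured_noise_tau_s * config.frame_hz))
        white = rng.standard_normal((T, hc, wc)).astype(np.float32)
        coarse = _lfilter([math.sqrt(1 - a * a)], [1, -a], white, axis=0)
        coarse *= config.structured_noise_sd
        sn = ndimage.zoom(coarse, (1, H / hc, W / wc), order=1,
                          grid_mode=True, mode="nearest").astype(np.float32)
        data[..., GREEN] += sn
        del white, coarse, sn
    if config.noise_sd > 0:
        sd = np.float32(config.noise_sd)
        for c in (GREEN, RED):
            data[..., c] += sd * rng.standard_normal((T, H, W),
                                                     dtype=np.float32)
    shifts = np.zeros((T, 2))
    if config.drift_px_per_min > 0:
        per_frame = config.drift_px_per_min / 60.0 / config.frame_hz
        disp = per_frame * np.arange(T)
        shifts = np.column_stack([disp / math.sqrt(2), disp / math.sqrt(2)])
        for t in range(T):
            if np.any(shifts[t] != 0):
                for c in range(2):
                    data[t, ..., c] = nd_shift(
                        data[t, ..., c], shifts[t], order=1, mode="nearest")
    truth.drift_shifts = shifts
    return TwoChannelMovie(data, frame_hz=config.frame_hz, px_um=config.px_um)


def perisomatic_sites(centers: np.ndarray, config: SimulationConfig,
                      rng: np.random.Generator) -> np.ndarray:
    """Varicosities inside each cell's annulus, at random angles and radii."""
    n = len(centers) * config.sites_per_cell
    base = np.repeat(np.asarray(centers, float), config.sites_per_cell, axis=0)
    r_lo = config.soma_radius_um / config.px_um + 1
    lim_um = (config.site_radius_um if config.site_radius_um is not None
              else config.annulus_radius_um)
    r_hi = lim_um / config.px_um - 1
    radii = rng.uniform(r_lo, max(r_lo + 0.5, r_hi), n)
    theta = rng.uniform(0, 2 * math.pi, n)
    return base + np.column_stack([radii * np.sin(theta),
                                   radii * np.cos(theta)])


def simulate_run(config: SimulationConfig
                 ) -> tuple[TwoChannelMovie, np.ndarray, GroundTruth]:
    """Full deterministic simulation: NE field, cell traces, rendered movie.

    With ``varicosities_at_cells`` the release sites are placed inside the
    cells' annuli (perineuronal release), so every cell's local field
    carries idiosyncratic events that decouple it from the global field
    during release epochs.
    """
    rng = np.random.default_rng(config.seed)
    centers = place_cell_centers(config, rng)
    sites = None
    if config.varicosities_at_cells:
        # one site per cell plus n_varicosities background sites: the
        # background release forms the shared burst envelope of the global
        # field while each cell's own site supplies idiosyncratic local NE
        H, W = config.fov_px
        sigma_px = config.diffusion_sigma_um / config.px_um
        margin = max(2.0, 1.5 * sigma_px)
        extra = np.column_stack([
            rng.uniform(margin, H - margin, config.n_varicosities),
            rng.uniform(margin, W - margin, config.n_varicosities),
        ])
        sites = np.vstack([perisomatic_sites(centers, config, rng), extra])
    ne, truth = simulate_ne_field(config, rng, site_centers=sites)
    ca = simulate_cells(ne, truth, config, rng, centers=centers)
    movie = render_two_channel(ne, ca, truth, config, rng)
    return movie, ne, truth


def write_simulation(out_dir, movie: TwoChannelMovie, truth: GroundTruth,
                     config: SimulationConfig) -> None:
    """Write movie (2-channel TIFF), soma labels (16-bit TIFF), truth (JSON)
    and config (flat key=value text) into ``out_dir``."""
    import pathlib

    import tifffile

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "movie.tif",
                     np.moveaxis(movie.data, -1, 1).astype(np.float32),
                     imagej=True, metadata={"axes": "TCYX"})
    tifffile.imwrite(out / "soma_masks.tif", truth.soma_labels)
    (out / "ground_truth.json").write_text(truth.to_json())
    lines = []
    for k, v in asdict(config).items():
        lines.append(f"{k} = {v}")
    (out / "config.txt").write_text("\n".join(lines) + "\n")
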