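"""Standard ground-truth evaluation scenarios for the synthetic pipeline.

These builders generate the benchmark conditions used to validate each
analysis stage against the generator's ground truth: isolated planted
release/reuptake events for detector recall/precision, matched
saline/desipramine condition pairs for the drug contrast, and an event
matcher that scores detections against planted events.

The ``SYNTHETIC_EVENT_PARAMS`` analysis scales are matched to the
generator's plume scale (~12 um diffusion): a ~4 um spatial Gaussian and a
2 s temporal kernel keep the narrow early phase of a plume detectable,
whereas a 12 px blur at 1.47 um/px suppresses it below the z threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import flow
from .synth import EventTruth, GroundTruth, SimulationConfig, simulate_ne_field

#: flow/event-detection knobs matched to the synthetic generator's scales
SYNTHETIC_EVENT_PARAMS = dict(
    sigma_px=3.0,       # ~4 um at 1.47 um/px
    kernel_s=2.0,
    alpha=1.0,
    n_iter=40,
    z_thresh=1.0,
    speed_gate_frac=0.2,
    min_persist=6,
    link_dist_px=10.0,
    max_gap_s=30.0,
    max_dist_um=20.0,
    merge_dist_um=25.0,
    merge_gap_s=5.0,
)


def planted_event_grid(
    n_events: int = 20,
    fov_px: int = 128,
    n_frames: int = 2000,
    frame_hz: float = 15.0,
    seed: int = 0,
    amp: float = 1.0,
    reuptake_frac_amp: float = 0.7,
    edge_s: float = 12.0,
) -> tuple[np.ndarray, GroundTruth, SimulationConfig]:
    """Noise-free movie with isolated, well-separated planted events.

    Events alternate release/reuptake, sit on a jittered spatial grid and
    are spread uniformly over the usable time span (excluding ``edge_s`` at
    each end, where the temporal filters are edge-distorted). Returns the
    clean NE movie, its ground truth and the generator config.
    """
    rng = np.random.default_rng(seed)
    cfg = SimulationConfig(
        fov_px=(fov_px, fov_px), duration_s=n_frames / frame_hz,
        frame_hz=frame_hz, release_rate_hz=0.0, reuptake_rate_hz=0.0,
        global_drive_amp=0.0, noise_sd=0.0, seed=seed,
    )
    # spatial grid with >= 24 px spacing, jittered
    margin = 18
    n_side = int(np.ceil(np.sqrt(n_events)))
    coords = np.linspace(margin, fov_px - margin, n_side)
    grid = [(y, x) for y in coords for x in coords][:n_events]
    grid = [(y + rng.uniform(-3, 3), x + rng.uniform(-3, 3)) for y, x in grid]
    edge_f = int(edge_s * frame_hz)
    onsets = np.linspace(edge_f, n_frames - edge_f - int(10 * frame_hz),
                         n_events).astype(int)
    order = rng.permutation(n_events)
    events = []
    for k, (y, x) in enumerate(grid):
        kind = "release" if k % 2 == 0 else "reuptake"
        events.append(EventTruth(
            kind=kind, onset=int(onsets[order[k]]), offset=0,
            y=float(y), x=float(x),
            amp=amp if kind == "release" else -reuptake_frac_amp * amp,
        ))
    ne, truth = simulate_ne_field(cfg, rng, events=events)
    return ne, truth, cfg


def match_events(
    truth_events: list[EventTruth],
    detected: list[flow.NEEvent],
    tol_px: float,
    frame_hz: float,
    max_onset_s: float = 2.0,
) -> tuple[float, float, int]:
    """Greedy best-time matching of detections to planted events.

    A detection matches a planted event of the same kind if its center lies
    within ``tol_px`` and its onset within ``max_onset_s``. Each detection
    is used once. Returns (recall, precision, n_matched).
    """
    used = [False] * len(detected)
    n_matched = 0
    for te in truth_events:
        best, best_err = None, np.inf
        for k, de in enumerate(detected):
            if used[k] or de.kind != te.kind:
                continue
            t_err = abs(de.onset - te.onset) / frame_hz
            if (np.hypot(de.y - te.y, de.x - te.x) <= tol_px
                    and t_err <= max_onset_s and t_err < best_err):
                best, best_err = k, t_err
        if best is not None:
            used[best] = True
            n_matched += 1
    recall = n_matched / len(truth_events) if truth_events else float("nan")
    precision = n_matched / len(detected) if detected else float("nan")
    return recall, precision, n_matched


def detect_planted_events(
    ne_movie: np.ndarray,
    cfg: SimulationConfig,
    **overrides,
) -> flow.EventPipelineResult:
    """Run the event pipeline with the generator-matched analysis scales."""
    params = dict(SYNTHETIC_EVENT_PARAMS)
    params.update(overrides)
    return flow.run_event_pipeline(ne_movie, cfg.frame_hz, cfg.px_um, **params)


def beta_recovery_scenario(seed: int, duration_s: float = 600.0
                           ) -> SimulationConfig:
    """Condition for end-to-end planted-coefficient recovery.

    Pure linear coupling (no rectified component), temporally homogeneous
    release and a weak shared drive: burst-synchronized release makes every
    cell's population-Ca predictor carry a global-NE component whose
    compensation biases the collinear local/global split, so the clean
    recovery benchmark uses unsynchronized release. 36 cells give the
    population-Ca proxy enough averaging to stay near the planted scale.
    """
    return SimulationConfig(
        fov_px=(128, 128), duration_s=duration_s, n_cells=36,
        ca_rectification=0.0, global_drive_amp=0.02,
        burst_gain=1.0, release_rate_hz=0.03, seed=seed,
    )


def regime_scenario(seed: int) -> SimulationConfig:
    """Condition for the synchrony-regime interaction logic.

    Alternating shared-drive epochs (coupled: local tracks global) and
    release-volley epochs (decoupled: perisomatic events dominate each
    cell's local field). The local x global interaction drive exists only
    outside the volleys (receptor saturation during release), so a correct
    synchrony segmentation localizes a significant interaction coefficient
    to the high-synchrony fits and none to the low-synchrony fits. Epochs
    are longer than the 30 s synchrony window so the sliding correlation
    can resolve them; event amplitudes are kept moderate because
    misclassified volley frames otherwise dominate the within-regime
    regression through the heavy tails of the product regressor.
    """
    return SimulationConfig(
        fov_px=(96, 96), duration_s=750.0, n_cells=16, n_varicosities=20,
        varicosities_at_cells=True, ca_rectification=0.0,
        beta_interaction=0.85, release_amp=0.6,
        global_drive_amp=0.15, global_drive_tau_s=10.0,
        burst_on_s=40.0, burst_off_s=50.0,
        reuptake_rate_hz=0.0, release_rate_hz=0.03, seed=seed,
    )


def colocation_scenario(seed: int) -> SimulationConfig:
    """Condition for the release/reuptake co-location direction check.

    A sparse varicosity field with bursty release and off-phase reuptake at
    reused sites: release and reuptake are spatially co-located but
    temporally anti-phase, the structure whose direction the event pipeline
    must reproduce (spatial r > 0, temporal r < 0). Sized so that plumes
    rarely overlap and a run stays tractable.
    """
    return SimulationConfig(
        fov_px=(88, 88), duration_s=180.0, n_varicosities=8,
        release_rate_hz=0.02, reuptake_rate_hz=0.022, burst_gain=5.0,
        noise_sd=0.0, seed=seed,
    )


def radius_sweep_scenario(seed: int) -> SimulationConfig:
    """Condition for recovering a planted ~25 um local-coupling scale.

    Each cell couples to the NE averaged over a 25 um perisomatic disk fed
    by three varicosities within 13 um of the soma center (plumes of ~6 um
    scale extend the signal footprint to ~25 um); independent background
    varicosities supply the uncorrelated NE that dilutes larger annuli, so
    the population local-NE coefficient peaks near the planted scale and
    falls off beyond it.
    """
    return SimulationConfig(
        fov_px=(160, 160), duration_s=300.0, n_cells=16,
        n_varicosities=30, varicosities_at_cells=True, sites_per_cell=3,
        annulus_radius_um=25.0, site_radius_um=13.0, diffusion_sigma_um=6.0,
        ca_rectification=0.0, burst_gain=1.0,
        global_drive_amp=0.05, release_rate_hz=0.02,
        reuptake_rate_hz=0.0, seed=seed,
    )


@dataclass
class ConditionPair:
    saline_cfg: SimulationConfig
    desipramine_cfg: SimulationConfig


def matched_condition_pair(seed: int, **overrides) -> ConditionPair:
    """Same-seed saline and desipramine configs differing only in condition."""
    base = dict(seed=seed, **overrides)
    return ConditionPair(
        saline_cfg=SimulationConfig(condition="saline", **base),
        desipramine_cfg=SimulationConfig(condition="desipramine", **base),
    )


def drug_contrast_scenario(seed: int) -> ConditionPair:
    """Matched saline/desipramine pair for the transporter-blockade contrast.

    Pure linear coupling; the structured (slow, local-scale) background
    noise is raised so the weakened desipramine NE signal sits near the
    field-trace noise floor, which is what lowers the detrended field
    correlations under the drug — correlations are scale-invariant, so
    uniform signal shrinkage alone cannot move them.
    """
    return matched_condition_pair(
        seed, fov_px=(128, 128), duration_s=300.0, n_cells=16,
        ca_rectification=0.0, structured_noise_sd=0.025,
    )


def noise_control_template(seed: int = 7, fov_px: int = 40,
                           duration_s: float = 24.0) -> tuple[np.ndarray, SimulationConfig]:
    """Small realistic NE movie used as the permutation-null template."""
    cfg = SimulationConfig(fov_px=(fov_px, fov_px), duration_s=duration_s,
                           n_varicosities=6, release_rate_hz=0.03,
                           reuptake_rate_hz=0.03, noise_sd=0.1, seed=seed)
    rng = np.random.default_rng(seed)
    ne, _ = simulate_ne_field(cfg, rng)
    ne = ne + np.float32(cfg.noise_sd) * rng.standard_normal(
        ne.shape).astype(np.float32)
    return ne, cfg


NOISE_CONTROL_PARAMS = dict(SYNTHETIC_EVENT_PARAMS, n_iter=25)


def noise_control_calibration(
    template: np.ndarray,
    frame_hz: float,
    px_um: float,
    n: int = 100,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
    statistic: str = "spatial_r",
    **pipeline_kwargs,
) -> float:
    """Rejection rate of the permutation control under the null.

    Runs the event pipeline on ``n + 1`` independent permutation-null
    movies; each one in turn plays the observed dataset against the
    remaining ``n`` (leave-one-out), giving exchangeable two-tailed
    p-values whose rejection rate at ``alpha`` must sit near ``alpha``.
    NaN draws (runs without both event kinds) are excluded.
    """
    if rng is None:
        rng = np.random.default_rng()
    params = dict(NOISE_CONTROL_PARAMS)
    params.update(pipeline_kwargs)
    vals = []
    for _ in range(n + 1):
        null = flow.make_null_movie(template, rng)
        res = flow.run_event_pipeline(null, frame_hz, px_um, **params)
        vals.append(getattr(res, statistic))
    vals = np.asarray(vals, float)
    vals = vals[np.isfinite(vals)]
    m = vals.size
    if m < 20:
        raise ValueError("too few defined null statistics for calibration")
    rejections = 0
    for k in range(m):
        others = np.abs(np.delete(vals, k))
        p = (1 + (others >= abs(vals[k])).sum()) / m
        rejections += p <= alpha
    return rejections / m


def simulate_correlation_table(
    effect: float = 0.10,
    n_mice: int = 6,
    cells_per_mouse: int = 40,
    obs_per_cell: int = 17,
    mouse_sd: float = 0.05,
    mouse_slope_sd: float = 0.05,
    cell_sd: float = 0.05,
    cell_slope_sd: float = 0.05,
    resid_sd: float = 0.2,
    base: float = 0.55,
    rng: np.random.Generator | None = None,
):
    """Synthetic pairwise-correlation table with a planted drug effect.

    value = base + effect * drug + u_mouse + s_mouse * drug + a_cell
            + b_cell * drug + noise, with independent Gaussian random
    intercepts/slopes per mouse and per cell, repeated ``obs_per_cell``
    observations per cell and condition (~n_mice * cells_per_mouse * 2 *
    obs_per_cell rows). Columns: value, drug, mouse, cell.
    """
    import pandas as pd

    if rng is None:
        rng = np.random.default_rng()
    rows = []
    cell_id = 0
    for m in range(n_mice):
        u = rng.normal(0, mouse_sd)
        sm = rng.normal(0, mouse_slope_sd)
        for _ in range(cells_per_mouse):
            a = rng.normal(0, cell_sd)
            b = rng.normal(0, cell_slope_sd)
            for drug in (0, 1):
                mean = base + effect * drug + u + sm * drug + a + b * drug
                vals = mean + rng.normal(0, resid_sd, obs_per_cell)
                for v in vals:
                    rows.append({"value": v, "drug": drug,
                                 "mouse": m, "cell": cell_id})
            cell_id += 1
    return pd.DataFrame(rows)
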