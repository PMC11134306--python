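"""Optic flow, critical points, event pairing and controls."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter, shift as nd_shift
from skimage.registration import phase_cross_correlation

from neflow.flow import (
    NEEvent,
    PatternTrack,
    classify_and_pair,
    distance_to_event,
    event_maps_and_correlations,
    expression_control,
    find_critical_points,
    horn_schunck,
    log_regression_synchrony,
    make_null_movie,
    merge_events,
    noise_control,
    preprocess_for_flow,
    run_event_pipeline,
)


def _blob(H=64, W=64, cy=32.0, cx=32.0, sigma=8.0, amp=1.0):
    yy, xx = np.mgrid[:H, :W]
    return amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))


class TestHornSchunck:
    def test_identical_frames_zero_flow(self):
        f = _blob()
        v = horn_schunck(f, f, n_iter=50)
        assert np.abs(v).max() == 0.0

    def test_translated_blob_matches_phase_correlation_oracle(self):
        f0 = _blob()
        f1 = _blob(cy=33.0)  # +1 px along rows
        oracle, _, _ = phase_cross_correlation(f1, f0, upsample_factor=50,
                                               normalization=None)
        assert oracle == pytest.approx([1.0, 0.0], abs=0.05)
        v = horn_schunck(f0, f1, alpha=1.0, n_iter=8000, tol=0.0)
        support = f0 > 0.2
        mean_flow = v[support].mean(axis=0)
        assert mean_flow[0] == pytest.approx(1.0, rel=0.2)
        assert abs(mean_flow[1]) < 0.1

    def test_large_alpha_approaches_uniform_translation(self):
        f0, f1 = _blob(), _blob(cy=33.0)
        spreads = []
        for alpha in (0.5, 2.0, 8.0):
            v = horn_schunck(f0, f1, alpha=alpha, n_iter=400, tol=1e-7)
            support = f0 > 0.2
            spreads.append(v[support, 0].std())
        assert spreads[0] > spreads[1] > spreads[2]

    def test_non_finite_input_rejected(self):
        f = _blob()
        bad = f.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            horn_schunck(f, bad)


class TestCriticalPoints:
    def _field(self, fn, H=33, W=33):
        yy, xx = np.mgrid[:H, :W]
        u, v = fn(yy - 16.0, xx - 16.0)
        return np.stack([u, v], axis=-1)

    @pytest.mark.parametrize("fn,expected", [
        (lambda y, x: (y, x), "source"),
        (lambda y, x: (-y, -x), "sink"),
        (lambda y, x: (y, -x), "saddle"),
        (lambda y, x: (-x - 0.1 * y, y - 0.1 * x), "spiral-in"),
        (lambda y, x: (-x + 0.1 * y, y + 0.1 * x), "spiral-out"),
    ])
    def test_analytic_linear_fields_classified(self, fn, expected):
        flow = self._field(fn)
        pts = find_critical_points(flow)
        assert len(pts) == 1
        assert pts[0].type == expected
        assert np.hypot(pts[0].y - 16, pts[0].x - 16) < 1.0


class TestPreprocessForFlow:
    def test_zscore_invariant(self, rng):
        m = rng.standard_normal((120, 16, 16)).astype(np.float32)
        out = preprocess_for_flow(m, frame_hz=15.0, sigma_px=1.0,
                                  kernel_s=0.2)
        sd = out.std(axis=0)
        assert np.abs(sd[sd > 0] - 1).max() < 1e-5

    def test_impulse_blurred_to_analytic_gaussian(self):
        m = np.zeros((3, 129, 129), np.float32)
        m[1, 64, 64] = 1.0
        out = gaussian_filter(m, sigma=(0, 12, 12), mode="nearest")
        peak = out[1, 64, 64]
        assert peak == pytest.approx(1 / (2 * np.pi * 12**2), rel=1e-3)

    def test_constant_movie_zeroed_not_amplified(self):
        m = np.full((60, 12, 12), 5.0, np.float32)
        out = preprocess_for_flow(m, 15.0, sigma_px=1.0, kernel_s=0.2)
        assert np.abs(out).max() == 0.0


def _track(type_, t0, t1, y, x, z):
    frames = np.arange(t0, t1 + 1)
    return PatternTrack(type=type_, t_start=t0, t_end=t1, y=y, x=x,
                        z_ext=z, frames=frames,
                        zs=np.full(frames.size, z), n_points=frames.size)


class TestPairing:
    def test_high_source_then_high_sink_forms_release(self):
        tracks = [_track("source", 10, 20, 30.0, 30.0, 2.0),
                  _track("sink", 35, 45, 31.0, 30.0, 2.0)]
        events, unpaired = classify_and_pair(tracks, frame_hz=15.0,
                                             px_um=1.47)
        assert len(events) == 1 and not unpaired
        e = events[0]
        assert e.kind == "release" and e.onset == 10 and e.offset == 45

    def test_type_mismatch_leaves_both_unpaired(self):
        tracks = [_track("source", 10, 20, 30.0, 30.0, 2.0),
                  _track("sink", 35, 45, 31.0, 30.0, -2.0)]
        events, unpaired = classify_and_pair(tracks, 15.0, 1.47)
        assert not events and len(unpaired) == 2

    def test_low_pair_forms_reuptake(self):
        tracks = [_track("source", 5, 12, 10.0, 10.0, -1.5),
                  _track("sink", 20, 30, 10.5, 10.0, -1.5)]
        events, _ = classify_and_pair(tracks, 15.0, 1.47)
        assert events[0].kind == "reuptake"

    def test_pairing_conserves_typed_tracks(self, rng):
        tracks = []
        for k in range(20):
            tracks.append(_track(rng.choice(["source", "sink"]),
                                 int(rng.integers(0, 300)),
                                 int(rng.integers(300, 400)),
                                 float(rng.uniform(0, 60)),
                                 float(rng.uniform(0, 60)),
                                 float(rng.choice([-2, 2]))))
        events, unpaired = classify_and_pair(tracks, 15.0, 1.47)
        assert 2 * len(events) + len(unpaired) == len(tracks)

    def test_merge_absorbs_duplicate_detections(self):
        a = NEEvent("release", 10, 40, 20.0, 20.0, 2.0)
        b = NEEvent("release", 15, 50, 22.0, 21.0, 2.3)
        c = NEEvent("release", 300, 330, 20.0, 20.0, 2.0)
        merged = merge_events([a, b, c], 15.0, 1.47)
        assert len(merged) == 2
        assert merged[0].offset == 50


class TestEventMaps:
    def test_identical_locations_give_unit_spatial_r(self):
        ev = [NEEvent("release", 10, 20, 30.0, 30.0, 0.7),
              NEEvent("reuptake", 50, 60, 30.0, 30.0, 0.7)]
        _, _, sr, tr = event_maps_and_correlations(ev, (64, 64), 100)
        assert sr == pytest.approx(1.0)

    def test_disjoint_halves_anticorrelate_spatially(self):
        ev = ([NEEvent("release", i * 10, i * 10 + 5, 20.0, 10.0 + i, 0.3)
               for i in range(5)]
              + [NEEvent("reuptake", i * 10, i * 10 + 5, 50.0, 40.0 + i, 0.3)
                 for i in range(5)])
        _, _, sr, _ = event_maps_and_correlations(ev, (64, 64), 100)
        assert sr < 0

    def test_missing_kind_gives_nan(self):
        ev = [NEEvent("release", 0, 5, 10.0, 10.0, 0.3)]
        _, _, sr, tr = event_maps_and_correlations(ev, (32, 32), 50)
        assert np.isnan(sr) and np.isnan(tr)


class TestDistanceAndRegression:
    def test_event_on_cell_gives_zero_distance(self):
        ev = [NEEvent("release", 10, 20, 16.0, 16.0, 0.7)]
        d = distance_to_event(ev, (16.0, 16.0), 40, px_um=1.47)
        assert d[15] == 0.0
        assert np.isnan(d[0]) and np.isnan(d[30])

    def test_offset_event_distance_is_euclidean(self):
        ev = [NEEvent("release", 0, 39, 10.0, 22.0, 2.0)]
        d = distance_to_event(ev, (10.0, 10.0), 40, px_um=1.47)
        assert d[5] == pytest.approx(12 * 1.47)

    def test_overlapping_events_take_minimum(self):
        ev = [NEEvent("release", 0, 30, 10.0, 20.0, 2.0),
              NEEvent("release", 10, 40, 10.0, 14.0, 2.0)]
        d = distance_to_event(ev, (10.0, 10.0), 50, px_um=1.0)
        assert d[20] == 4.0

    def test_exact_log_relation_recovered(self):
        d = np.linspace(1, 200, 500)
        syn = 0.1 * np.log(d + 1) + 0.2
        icpt, slope, p, r2 = log_regression_synchrony(d, syn)
        assert icpt == pytest.approx(0.2, abs=1e-10)
        assert slope == pytest.approx(0.1, abs=1e-10)
        assert r2 == pytest.approx(1.0)

    def test_null_slopes_reject_at_nominal_rate(self, rng):
        """Synchrony independent of distance: ~5% of cells significant."""
        n_sig = 0
        for _ in range(100):
            d = rng.uniform(1, 150, 400)
            syn = rng.standard_normal(400)
            _, _, p, _ = log_regression_synchrony(d, syn)
            n_sig += p < 0.05
        assert 1 <= n_sig <= 11  # binomial 99% band around 5/100

    def test_degenerate_distances_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            log_regression_synchrony(np.full(100, 5.0),
                                     np.random.default_rng(0).standard_normal(100))


class TestExpressionControl:
    def test_uniform_expression_equals_plain_correlation(self, rng):
        a = rng.random((20, 20))
        b = 0.5 * a + rng.random((20, 20))
        plain = np.corrcoef(a.ravel(), b.ravel())[0, 1]
        assert expression_control(a, b, np.ones((20, 20))) == pytest.approx(
            plain)

    def test_full_confound_flagged_nan(self, rng):
        f = rng.random((16, 16))
        assert np.isnan(expression_control(2 * f, 3 * f, f))

    def test_shared_gradient_confound_reduced(self, rng):
        yy = np.mgrid[:24, :24][0].astype(float)
        a = yy + rng.random((24, 24))
        b = yy + rng.random((24, 24))
        raw = np.corrcoef(a.ravel(), b.ravel())[0, 1]
        controlled = expression_control(a, b, yy)
        assert controlled < raw


class TestNoiseControl:
    def test_small_n_refused(self, rng):
        with pytest.raises(ValueError, match="n < 20"):
            noise_control({"spatial_r": 0.5}, rng.random((10, 8, 8)),
                          15.0, 1.47, n=5)

    def test_null_movie_preserves_pixel_marginals(self, rng):
        m = rng.random((50, 6, 6)).astype(np.float32)
        null = make_null_movie(m, rng)
        assert np.allclose(np.sort(null, axis=0), np.sort(m, axis=0))
        assert not np.array_equal(null, m)

    def test_extreme_observation_hits_continuity_floor(self, rng):
        from neflow.scenarios import noise_control_template

        template, cfg = noise_control_template(fov_px=32, duration_s=16.0)
        res = noise_control({"spatial_r": 50.0}, template, cfg.frame_hz,
                            cfg.px_um, n=20, rng=rng, sigma_px=3.0,
                            kernel_s=2.0, n_iter=20, min_persist=6,
                            speed_gate_frac=0.2)
        # |null| can never reach 50 -> p exactly at the continuity floor
        finite = int(np.isfinite(res.null["spatial_r"]).sum())
        assert res.p["spatial_r"] == pytest.approx(1 / (finite + 1))


def test_pipeline_smoke_on_tiny_movie():
    from neflow.scenarios import SYNTHETIC_EVENT_PARAMS, planted_event_grid

    ne, truth, cfg = planted_event_grid(n_events=4, fov_px=64, n_frames=700,
                                        seed=3)
    params = dict(SYNTHETIC_EVENT_PARAMS, n_iter=25)
    res = run_event_pipeline(ne, cfg.frame_hz, cfg.px_um, **params)
    assert res.n_frames == 700
    for e in res.events:
        assert e.onset < e.offset
        assert 0 <= e.y < 64 and 0 <= e.x < 64
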