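"""Movie preprocessing contracts: filtering, registration, geometry, traces."""

import numpy as np
import pytest
from scipy.ndimage import shift as nd_shift

from neflow.preprocess import (
    TwoChannelMovie,
    bleedthrough_correct,
    build_fields,
    extract_traces,
    median_filter_and_bin,
    register_translation,
    soma_masks_from_labels,
    standardize,
)


def _movie(data, frame_hz=30.0, px_um=1.47):
    return TwoChannelMovie(np.asarray(data, np.float64), frame_hz, px_um)


class TestMedianFilterAndBin:
    def test_constant_movie_unchanged_rate_halved(self):
        m = _movie(np.full((8, 4, 4, 2), 3.0))
        out = median_filter_and_bin(m)
        assert np.allclose(out.data, 3.0)
        assert out.frame_hz == 15.0
        assert out.n_frames == 4

    def test_single_frame_spike_removed(self):
        data = np.zeros((9, 4, 4, 2))
        data[4, 2, 2, 0] = 100.0
        out = median_filter_and_bin(_movie(data))
        assert out.data.max() == 0.0

    def test_ramp_bins_to_pair_means(self):
        # per-pixel ramp 1..8: median preserves the interior ramp, binning
        # averages non-overlapping pairs
        data = np.zeros((8, 2, 2, 2))
        data += np.arange(1, 9, dtype=float)[:, None, None, None]
        out = median_filter_and_bin(_movie(data))
        assert np.allclose(out.data[:, 0, 0, 0], [1.5, 3.5, 5.5, 7.5])

    def test_odd_trailing_frame_dropped(self):
        out = median_filter_and_bin(_movie(np.zeros((9, 4, 4, 2))))
        assert out.n_frames == 4


class TestRegistration:
    def _textured(self, rng, T=20, H=48, W=48, blur=3.0):
        base = rng.random((H, W))
        from scipy.ndimage import gaussian_filter
        base = gaussian_filter(base, blur)
        data = np.repeat(base[None], T, axis=0)
        return np.stack([data, data], axis=-1)

    def test_static_movie_zero_shifts(self, rng):
        m = _movie(self._textured(rng), frame_hz=10)
        _, shifts = register_translation(m, reference_s=1.0)
        assert np.abs(shifts).max() < 0.15

    def test_planted_integer_drift_recovered(self, rng):
        data = self._textured(rng, T=20)
        planted = np.zeros((20, 2))
        planted[10:, 0] = 3.0  # +3 px row shift on the second half
        for t in range(20):
            if planted[t, 0]:
                for c in range(2):
                    data[t, ..., c] = nd_shift(data[t, ..., c], planted[t],
                                               order=1, mode="nearest")
        m = _movie(data, frame_hz=10)
        _, shifts = register_translation(m, reference_s=0.5)
        rms = np.sqrt(((shifts + planted) ** 2).sum(axis=1).mean())
        assert rms < 0.5

    def test_integer_shift_registration_is_lossless_inside(self, rng):
        # fine texture: integer shifts are then estimated exactly (snapped)
        data = self._textured(rng, T=4, blur=1.0)
        shifted = data.copy()
        for c in range(2):
            shifted[2, ..., c] = nd_shift(data[2, ..., c], (2, -1), order=1,
                                          mode="nearest")
            shifted[3, ..., c] = nd_shift(data[3, ..., c], (2, -1), order=1,
                                          mode="nearest")
        m = _movie(shifted, frame_hz=10)
        reg, _ = register_translation(m, reference_s=0.2)
        interior = (slice(None), slice(5, -5), slice(5, -5), slice(None))
        assert np.abs(reg.data[interior] - data[interior]).max() < 1e-6


class TestFieldGeometry:
    def _soma(self, H, W, centers, r=3.0):
        from neflow.preprocess import _disk
        masks = [ _disk((H, W), c, r) for c in centers ]
        return np.stack(masks)

    def test_annulus_pixel_count_matches_disk_area(self):
        soma = self._soma(64, 64, [(32, 32)], r=3.0)
        geom = build_fields(soma, radius_um=15.0, px_um=1.47)
        r_px = 15.0 / 1.47
        expected = np.pi * r_px**2 - soma[0].sum()
        count = geom.annulus[0].sum()
        assert abs(count - expected) < 0.15 * expected

    def test_close_cells_have_disjoint_annuli(self):
        soma = self._soma(64, 64, [(30, 30), (30, 40)])
        geom = build_fields(soma, radius_um=15.0, px_um=1.47)
        assert not (geom.annulus[0] & geom.annulus[1]).any()
        assert not (geom.annulus[0] & geom.soma.any(axis=0)).any()

    def test_global_mask_partition_arithmetic(self):
        soma = self._soma(64, 64, [(20, 20), (44, 44)])
        geom = build_fields(soma, radius_um=15.0, px_um=1.47)
        for i in range(2):
            total = (geom.soma[i].sum() + geom.annulus[i].sum()
                     + geom.global_mask(i).sum())
            assert total == 64 * 64

    def test_consumed_annulus_raises_naming_cell(self):
        # two concentric somata (disk + ring) share a centroid: the first
        # cell claims the whole annulus zone, leaving cell 1 nothing
        from neflow.preprocess import _disk
        inner = _disk((32, 32), (16, 16), 2.0)
        ring = _disk((32, 32), (16, 16), 5.0) & ~_disk((32, 32), (16, 16), 3.0)
        with pytest.raises(ValueError, match="cell 1"):
            build_fields(np.stack([inner, ring]), radius_um=6 * 1.47,
                         px_um=1.47)

    def test_label_image_accepted(self):
        labels = np.zeros((48, 48), np.uint16)
        labels[10:14, 10:14] = 1
        labels[30:34, 30:34] = 2
        geom = build_fields(soma_masks_from_labels(labels))
        assert geom.n_cells == 2


class TestBleedthrough:
    def test_independent_channels_nearly_unchanged(self, rng):
        g = rng.standard_normal((5000, 4, 4))
        r = rng.standard_normal((5000, 4, 4))
        m = _movie(np.stack([g, r], axis=-1))
        out = bleedthrough_correct(m)
        gc = g - g.mean(axis=0)
        # slope noise ~ 1/sqrt(T): residual deviates only marginally
        assert np.abs(out.data[..., 0] - gc).max() < 0.15 * gc.std()

    def test_planted_leak_removed_to_numerical_zero(self, rng):
        r = rng.standard_normal((500, 4, 4))
        sig = rng.standard_normal((500, 4, 4))
        g = 0.2 * r + sig
        out = bleedthrough_correct(_movie(np.stack([g, r], axis=-1)))
        for i in range(4):
            for j in range(4):
                c = np.corrcoef(out.data[:, i, j, 0], r[:, i, j])[0, 1]
                assert abs(c) < 1e-10

    def test_correction_never_increases_cross_correlation(self, rng):
        g = rng.standard_normal((300, 5, 5))
        r = 0.3 * g + rng.standard_normal((300, 5, 5))
        m = _movie(np.stack([g, r], axis=-1))
        out = bleedthrough_correct(m)
        for i in range(5):
            for j in range(5):
                before = abs(np.corrcoef(g[:, i, j], r[:, i, j])[0, 1])
                after = abs(np.corrcoef(out.data[:, i, j, 0],
                                        out.data[:, i, j, 1])[0, 1])
                assert after <= before + 1e-12


class TestStandardize:
    def test_unit_moments(self, rng):
        x = rng.standard_normal(1000).cumsum()
        z = standardize(x, frame_hz=15.0)
        assert abs(z.mean()) < 1e-9
        assert abs(z.std() - 1) < 1e-6

    def test_pure_ramp_raises_zero_variance(self):
        with pytest.raises(ValueError, match="zero variance"):
            standardize(np.linspace(0, 1, 500), frame_hz=15.0)

    def test_gaussian_kernel_gain_matches_closed_form(self):
        # two sinusoids; after smoothing, their amplitude RATIO must equal
        # the ratio of the discrete Gaussian kernel's transfer function at
        # those frequencies (z-scoring rescales both tones equally).
        # Amplitudes are read out by lock-in over an integer number of
        # cycles away from the filter edges; the oracle is the kernel's
        # DTFT evaluated exactly at each frequency.
        fs, T = 15.0, 9000
        t = np.arange(T) / fs
        f1, f2 = 0.05, 0.5
        x = np.sin(2 * np.pi * f1 * t) + np.sin(2 * np.pi * f2 * t)
        z = standardize(x, frame_hz=fs, kernel_s=1.0)
        sl = slice(600, 8400)  # 7800 samples: integer cycles of both tones

        def lockin(sig, f):
            s, tt = sig[sl], t[sl]
            return np.hypot(2 * np.mean(s * np.cos(2 * np.pi * f * tt)),
                            2 * np.mean(s * np.sin(2 * np.pi * f * tt)))

        measured = ((lockin(z, f2) / lockin(x, f2))
                    / (lockin(z, f1) / lockin(x, f1)))
        from scipy.ndimage import gaussian_filter1d

        impulse = np.zeros(257)
        impulse[128] = 1.0
        kern = gaussian_filter1d(impulse, sigma=1.0 * fs, mode="nearest")
        n = np.arange(257) - 128
        H = lambda f: abs(np.sum(kern * np.exp(-2j * np.pi * f * n / fs)))
        assert measured == pytest.approx(H(f2) / H(f1), rel=0.02)

    def test_idempotent_up_to_tolerance(self, rng):
        x = rng.standard_normal(2000).cumsum()
        z1 = standardize(x, 15.0)
        z2 = standardize(z1, 15.0)
        # second pass re-smooths; correlation stays essentially 1
        assert np.corrcoef(z1, z2)[0, 1] > 0.995


class TestExtractTraces:
    def test_uniform_frames_give_frame_value_traces(self):
        T, H, W = 120, 32, 32
        vals = np.sin(np.arange(T) / 5.0)
        data = np.zeros((T, H, W, 2))
        data += vals[:, None, None, None]
        from neflow.preprocess import _disk
        soma = np.stack([_disk((H, W), (10, 10), 3.0),
                         _disk((H, W), (22, 22), 3.0)])
        geom = build_fields(soma, radius_um=6.0, px_um=1.47)
        ts = extract_traces(_movie(data, frame_hz=15.0), geom)
        assert np.allclose(ts.raw_ca[0], vals)
        assert np.allclose(ts.raw_local_ne[0], vals)
        assert np.allclose(ts.raw_global_ne[0], vals, atol=1e-12)

    def test_traceset_invariants_on_generator_run(self, bursty_run):
        ts = bursty_run["traces"]
        for arr in (ts.ca, ts.local_ne, ts.global_ne, ts.pop_ca):
            assert np.abs(arr.mean(axis=1)).max() < 1e-9
            assert np.abs(arr.std(axis=1) - 1).max() < 1e-6
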