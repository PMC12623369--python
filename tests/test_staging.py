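import numpy as np
import pytest

from sleepconn.preprocess import flag_bad_channels
from sleepconn.staging import (REM, SWS, UNSCORED, WK, Hypnogram, SegmentSet,
                               StateMap, build_state_map, cluster_states,
                               extract_sws_segments, smooth_hanning,
                               spectral_ratios, sws_duration)

from conftest import make_recording


def _sine(freq, dur_s=30.0, fs=1000.0, amp=1.0):
    t = np.arange(int(dur_s * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestSpectralRatios:
    def test_pure_delta_sine_saturates_both_ratios(self):
        rec = make_recording(_sine(2.0))
        _, r1, r2, valid = spectral_ratios(rec)
        assert valid.all()
        assert np.all(r1 > 0.97) and np.all(r2 > 0.97)

    def test_gamma_sine_has_low_ratio1(self):
        rec = make_recording(_sine(40.0))
        _, r1, _, _ = spectral_ratios(rec)
        assert np.all(r1 < 0.05)

    def test_epoch_grid_spacing_one_second(self):
        rec = make_recording(_sine(5.0, dur_s=20))
        et, r1, _, _ = spectral_ratios(rec)
        assert np.allclose(np.diff(et), 1.0)
        assert r1.shape == (len(et), 1)

    def test_matches_direct_periodogram_integration(self, rng):
        # independent oracle: literal Hann periodogram + band sums per epoch
        fs = 1000.0
        x = rng.standard_normal(int(12 * fs))
        rec = make_recording(x, rate=fs)
        _, r1, _, _ = spectral_ratios(rec)
        for ep in range(3):
            win = x[ep * 1000:(ep * 1000) + 2000] * np.hanning(2000)
            spec = np.abs(np.fft.rfft(win)) ** 2
            f = np.fft.rfftfreq(2000, 1 / fs)
            num = spec[(f >= 0.5) & (f <= 20)].sum()
            den = spec[(f >= 0.5) & (f <= 55)].sum()
            assert r1[ep, 0] == pytest.approx(num / den, rel=1e-2)

    def test_ratios_bounded(self, rng):
        rec = make_recording(rng.standard_normal((2, 15000)))
        _, r1, r2, valid = spectral_ratios(rec)
        assert np.all((r1 > 0) & (r1 <= 1)) and np.all((r2 > 0) & (r2 <= 1))


class TestStateMap:
    def test_smoothing_is_mean_preserving(self, rng):
        x = rng.standard_normal(500)
        y = smooth_hanning(x, 20)
        assert abs(y.mean() - x.mean()) < 1e-6
        assert len(y) == len(x)

    def test_smoothing_preserves_constant(self):
        assert np.allclose(smooth_hanning(np.full(100, 3.7), 20), 3.7)

    def test_identical_channels_collapse_to_common_series(self, rng):
        base = rng.standard_normal(100)
        mat = np.tile(base[:, None], (1, 4))
        sm = build_state_map(np.arange(100) + 1.0, mat, mat)
        # PC1 of identical channels is the (centered, scaled) common series
        r = np.corrcoef(sm.x, smooth_hanning(base - base.mean(), 20))[0, 1]
        assert r > 0.999

    def test_orientation_follows_channel_mean(self, rng):
        # two anti-correlated groups: PC sign fixed by positive correlation
        # with the cross-channel mean
        base = rng.standard_normal(200)
        mat = np.column_stack([base, base, base, -0.5 * base])
        sm = build_state_map(np.arange(200) + 1.0, mat, mat, smooth_s=2)
        assert np.corrcoef(sm.x, mat.mean(axis=1))[0, 1] > 0

    def test_constant_ratios_constant_map(self):
        mat = np.full((50, 3), 0.5)
        sm = build_state_map(np.arange(50) + 1.0, mat, mat)
        assert np.allclose(sm.x, sm.x[0]) and np.allclose(sm.y, sm.y[0])


class TestClusterStates:
    def test_separated_blobs_recovered_exactly(self, rng):
        n = 200
        # construct blobs per the positional rule: SWS highest x;
        # REM = higher y among the rest; WK the remaining cluster
        sws = rng.normal([5, 2], 0.1, size=(n, 2))
        rem = rng.normal([0, 5], 0.1, size=(n, 2))
        wk = rng.normal([0, 0], 0.1, size=(n, 2))
        pts = np.vstack([sws, rem, wk])
        truth = np.array([SWS] * n + [REM] * n + [WK] * n, dtype=object)
        sm = StateMap(epoch_times=np.arange(3 * n, dtype=float),
                      x=pts[:, 0], y=pts[:, 1],
                      valid=np.ones(3 * n, dtype=bool))
        hyp = cluster_states(sm)
        assert np.mean(hyp.labels == truth) == 1.0

    def test_degenerate_map_all_unscored(self):
        sm = StateMap(epoch_times=np.arange(50, dtype=float),
                      x=np.zeros(50), y=np.zeros(50),
                      valid=np.ones(50, dtype=bool))
        hyp = cluster_states(sm)
        assert np.all(hyp.labels == UNSCORED)

    def test_deterministic_given_seed(self, rng):
        pts = rng.standard_normal((300, 2))
        sm = StateMap(epoch_times=np.arange(300, dtype=float),
                      x=pts[:, 0], y=pts[:, 1],
                      valid=np.ones(300, dtype=bool))
        h1 = cluster_states(sm, seed=3)
        h2 = cluster_states(sm, seed=3)
        assert np.array_equal(h1.labels, h2.labels)


def _hyp(labels):
    return Hypnogram(epoch_times=np.arange(len(labels)) + 1.0,
                     labels=np.array(labels, dtype=object))


class TestSegments:
    def test_600s_contiguous_sws_gives_five_windows(self, rng):
        labels = [SWS] * 600
        rec = make_recording(rng.standard_normal((2, 602_000)) * 10)
        segs = extract_sws_segments(_hyp(labels), rec)
        assert len(segs) == 5

    def test_230s_gives_one_window(self, rng):
        labels = [SWS] * 230 + [WK] * 100
        rec = make_recording(rng.standard_normal((2, 332_000)) * 10)
        segs = extract_sws_segments(_hyp(labels), rec)
        assert len(segs) == 1

    def test_artifact_burst_drops_its_window(self, rng):
        labels = [SWS] * 360
        data = rng.standard_normal((2, 362_000)) * 10
        data[:, 150_000:152_000] += 1e4  # excursion inside the second window
        rec = make_recording(data)
        segs = extract_sws_segments(_hyp(labels), rec)
        starts = [s for s, _ in segs.windows]
        assert len(segs) == 2
        assert not any(s <= 150.0 < s + 120.0 for s in starts)

    def test_flagged_channels_excluded(self, rng):
        labels = [SWS] * 130
        data = rng.standard_normal((2, 132_000)) * 10
        rec = make_recording(data)
        q = flag_bad_channels(rec)
        q.flags[rec.channels[0]] = "clipped"
        segs = extract_sws_segments(_hyp(labels), rec, q)
        assert segs.channels == [rec.channels[1]]

    def test_windows_lie_inside_sws_runs(self, rng):
        labels = [WK] * 50 + [SWS] * 250 + [REM] * 30 + [SWS] * 121
        rec = make_recording(rng.standard_normal((1, 452_000)) * 10)
        hyp = _hyp(labels)
        segs = extract_sws_segments(hyp, rec)
        for s, e in segs.windows:
            inside = (hyp.epoch_times > s) & (hyp.epoch_times < e)
            assert np.all(hyp.labels[inside] == SWS)


class TestSwsDuration:
    @pytest.mark.parametrize("labels,expected", [
        ([SWS] * 10, 1.0),
        ([WK] * 10, 0.0),
        ([SWS, WK] * 5, 0.5),
    ])
    def test_normalized_fraction(self, labels, expected):
        total, norm = sws_duration(_hyp(labels))
        assert norm == pytest.approx(expected)
        assert total == pytest.approx(expected * len(labels))
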