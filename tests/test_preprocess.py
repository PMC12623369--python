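import numpy as np
import pytest
from scipy import signal

from sleepconn.preprocess import (BipolarMontage, adjacent_pairs_montage,
                                  apply_bipolar, apply_linefilter,
                                  decimate_to_lfp, design_linefilter,
                                  flag_bad_channels)
from sleepconn.recording import Recording

from conftest import make_recording, two_region_recording


class TestBipolar:
    def test_self_pair_is_zero(self, rng):
        rec = make_recording(rng.standard_normal((1, 1000)))
        mont = BipolarMontage(((rec.channels[0], rec.channels[0]),))
        out = apply_bipolar(rec, mont)
        assert np.all(out.data == 0)

    def test_identity_under_zero_reference(self):
        t = np.arange(2000) / 1000.0
        sine = np.sin(2 * np.pi * 5 * t)
        rec = make_recording([sine, np.zeros_like(sine)])
        out = apply_bipolar(rec, BipolarMontage(((rec.channels[0],
                                                  rec.channels[1]),)))
        assert np.allclose(out.data[0], sine)
        assert out.region_of[out.channels[0]] == "S1"

    def test_common_mode_rejected(self, rng):
        drift = np.cumsum(rng.standard_normal(20000)) * 0.1
        a = drift + rng.standard_normal(20000)
        b = drift + rng.standard_normal(20000)
        rec = make_recording([a, b])
        out = apply_bipolar(rec, BipolarMontage(((rec.channels[0],
                                                  rec.channels[1]),)))
        corr = np.corrcoef(out.data[0], drift)[0, 1]
        assert abs(corr) < 0.05

    def test_cross_region_pair_rejected(self, rng):
        rec = two_region_recording(rng.standard_normal((1, 100)),
                                   rng.standard_normal((1, 100)))
        with pytest.raises(ValueError, match="regions"):
            apply_bipolar(rec, BipolarMontage((("S1_01", "RFA_01"),)))

    def test_unknown_channel_rejected(self, rng):
        rec = make_recording(rng.standard_normal((2, 100)))
        with pytest.raises(KeyError):
            apply_bipolar(rec, BipolarMontage((("nope", "S1_01"),)))

    def test_duplicate_anode_rejected(self):
        with pytest.raises(ValueError, match="anode"):
            BipolarMontage((("a", "b"), ("a", "c")))

    def test_default_montage_pairs_adjacent_within_region(self, rng):
        rec = two_region_recording(rng.standard_normal((4, 10)),
                                   rng.standard_normal((4, 10)))
        mont = adjacent_pairs_montage(rec)
        assert mont.pairs == (("S1_01", "S1_02"), ("S1_03", "S1_04"),
                              ("RFA_01", "RFA_02"), ("RFA_03", "RFA_04"))


class TestDecimate:
    def test_passband_sine_preserved(self):
        fs = 25000.0
        t = np.arange(int(2 * fs)) / fs
        rec = make_recording(np.sin(2 * np.pi * 10 * t), rate=fs)
        out = decimate_to_lfp(rec)
        assert out.rate == 1000.0
        # compare amplitude away from edges
        mid = out.data[0][500:-500]
        assert abs(mid.max() - 1.0) < 0.01

    def test_stopband_sine_removed(self):
        fs = 25000.0
        t = np.arange(int(2 * fs)) / fs
        x = np.sin(2 * np.pi * 400 * t)
        rec = make_recording(x, rate=fs)
        out = decimate_to_lfp(rec)
        assert np.sqrt(np.mean(out.data[0] ** 2)) < 0.01 * np.sqrt(np.mean(x ** 2))

    def test_passthrough_at_target_rate(self, rng):
        rec = make_recording(rng.standard_normal(5000), rate=1000.0)
        out = decimate_to_lfp(rec)
        assert out.rate == 1000.0
        assert out.n_samples == rec.n_samples

    def test_target_above_rate_rejected(self, rng):
        rec = make_recording(rng.standard_normal(100), rate=500.0)
        with pytest.raises(ValueError):
            decimate_to_lfp(rec, target_rate_hz=1000.0)

    def test_parseval_band_power_preserved(self, rng):
        # total 0-300 Hz power preserved within 5% through the chain
        fs = 5000.0
        x = rng.standard_normal(int(10 * fs))
        rec = make_recording(x, rate=fs)
        out = decimate_to_lfp(rec)
        f_in, p_in = signal.welch(x, fs=fs, nperseg=4096)
        f_out, p_out = signal.welch(out.data[0], fs=1000.0, nperseg=4096)
        pw_in = np.trapezoid(p_in[f_in <= 290], f_in[f_in <= 290])
        pw_out = np.trapezoid(p_out[f_out <= 290], f_out[f_out <= 290])
        assert abs(pw_out - pw_in) / pw_in < 0.05


class TestLineFilter:
    @pytest.fixture(scope="class")
    def filt(self):
        return design_linefilter(1000.0)

    def test_stopband_attenuation_at_mains_and_harmonics(self, filt):
        for f in (50.0, 150.0):
            assert filt.attenuation_db(f) >= 53.0

    def test_harmonics_cover_nyquist(self, filt):
        assert filt.stop_centers_hz == tuple(np.arange(50.0, 500.0, 50.0))

    def test_passband_flat(self, filt):
        assert abs(filt.response_db(10.0)[0]) < 1.0
        assert abs(filt.response_db(30.0)[0]) < 1.0

    def test_unattainable_budget_reports_attenuation(self):
        with pytest.raises(ValueError, match="dB"):
            design_linefilter(1000.0, numtaps=101)

    def test_white_noise_psd_notched_passband_intact(self, rng):
        # the 1 Hz notch needs fine spectral resolution and low leakage to
        # be measurable down to -53 dB
        filt = design_linefilter(1000.0)
        x = rng.standard_normal(600_000)
        rec = make_recording(x, rate=1000.0)
        out = apply_linefilter(rec, filt)
        f, p_in = signal.welch(x, fs=1000.0, nperseg=65536)
        _, p_out = signal.welch(out.data[0], fs=1000.0, nperseg=65536)
        notch = (f >= 49.7) & (f <= 50.3)
        drop_db = 10 * np.log10(p_in[notch] / np.maximum(p_out[notch], 1e-30))
        assert drop_db.min() >= 53.0
        band = (f >= 10) & (f <= 40)
        change_db = 10 * np.log10(p_out[band].mean() / p_in[band].mean())
        assert abs(change_db) < 1.0


class TestChannelQuality:
    def test_saturating_square_wave_is_clipped(self):
        x = np.sign(np.sin(2 * np.pi * 5 * np.arange(10000) / 1000.0)) * 300
        q = flag_bad_channels(make_recording(x))
        assert q.flags["S1_01"] == "clipped"
        assert q.clip_fraction["S1_01"] > 0.9

    def test_pure_sine_is_good(self):
        x = np.sin(2 * np.pi * 10 * np.arange(30000) / 1000.0)
        q = flag_bad_channels(make_recording(x))
        assert q.flags["S1_01"] == "good"

    def test_slow_ramp_is_drifting(self):
        t = np.arange(60000) / 1000.0
        x = np.sin(2 * np.pi * 10 * t) + 20 * np.sin(2 * np.pi * 0.05 * t)
        q = flag_bad_channels(make_recording(x))
        assert q.flags["S1_01"] == "drifting"
        assert q.drift_ratio["S1_01"] > 0.5

    def test_empty_recording_all_good(self):
        rec = make_recording(np.empty((2, 0)))
        q = flag_bad_channels(rec)
        assert set(q.flags.values()) == {"good"}
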