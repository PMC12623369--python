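import numpy as np
import pytest

from sleepconn.plv import make_bank, plv, wavelet_coeffs
from sleepconn.preprocess import flag_bad_channels
from sleepconn.staging import SWS, extract_sws_segments
from sleepconn.synth import (ArtifactSpec, PacCoupling, PlvCoupling,
                             SessionSpec, StateProfile, StudySpec,
                             generate_session, generate_sws_segment,
                             jitter_for_plv, make_study)


class TestDeterminism:
    def test_same_seed_identical_sessions(self):
        spec = SessionSpec(duration_s=60.0, n_channels_per_region=2, seed=4)
        r1, t1 = generate_session(spec)
        r2, t2 = generate_session(spec)
        assert np.array_equal(r1.data, r2.data)
        assert np.array_equal(t1.hypnogram.labels, t2.hypnogram.labels)

    def test_different_seeds_differ(self):
        r1, _ = generate_session(SessionSpec(duration_s=30.0, seed=1,
                                             n_channels_per_region=1))
        r2, _ = generate_session(SessionSpec(duration_s=30.0, seed=2,
                                             n_channels_per_region=1))
        assert not np.array_equal(r1.data, r2.data)


class TestSpectralStructure:
    def test_background_slope_matches_exponent(self, rng):
        from scipy import signal as sig

        spec = SessionSpec(
            duration_s=120.0, n_channels_per_region=1, line_noise_uv=0.0,
            profiles={s: StateProfile(0, 0, 0) for s in ("WK", "SWS", "REM")},
            seed=8)
        rec, _ = generate_session(spec, state_intervals=[(0, 120.0, SWS)])
        f, p = sig.welch(rec.data[0], fs=1000.0, nperseg=8192)
        band = (f >= 2) & (f <= 80)
        slope = np.polyfit(np.log10(f[band]), np.log10(p[band]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.2)

    def test_line_noise_present_at_50hz(self):
        rec = generate_sws_segment(duration_s=60.0, n_channels_per_region=1,
                                   line_noise_uv=10.0, seed=0)
        from scipy import signal as sig

        f, p = sig.welch(rec.data[0], fs=1000.0, nperseg=8192)
        i50 = np.argmin(np.abs(f - 50.0))
        neighborhood = (f > 40) & (f < 48)
        assert p[i50] > 20 * p[neighborhood].mean()

    def test_sws_delta_dominates_wk(self):
        from scipy import signal as sig

        spec = SessionSpec(duration_s=240.0, n_channels_per_region=1,
                           line_noise_uv=0.0, seed=3)
        rec, _ = generate_session(
            spec, state_intervals=[(0, 120.0, SWS), (120.0, 240.0, "WK")])
        f, p_sws = sig.welch(rec.data[0][:120_000], fs=1000.0, nperseg=4096)
        _, p_wk = sig.welch(rec.data[0][120_000:], fs=1000.0, nperseg=4096)
        delta = (f >= 1) & (f <= 4)
        assert p_sws[delta].sum() > 3 * p_wk[delta].sum()


class TestCouplingInjection:
    def test_perfect_coupling_clean_signal_unit_plv(self):
        # c = 1, zero jitter, no background: shared phase is deterministic
        spec = SessionSpec(
            duration_s=60.0, n_channels_per_region=1, line_noise_uv=0.0,
            background_rms=0.0,
            profiles={s: StateProfile(0, 0, 0) for s in ("WK", "SWS", "REM")},
            plv_couplings=[PlvCoupling("S1", "RFA", 3.0, 1.0)], seed=5)
        rec, _ = generate_session(spec, state_intervals=[(0, 60.0, SWS)])
        bank = make_bank()
        f = float(bank.center_freqs[np.argmin(np.abs(bank.center_freqs - 3.0))])
        coeffs, valid = wavelet_coeffs(rec.data, bank, rec.rate, freqs=[f])
        cs = coeffs[f][:, valid[f]]
        assert plv(cs[0], cs[1]) > 0.99

    def test_coupling_above_nyquist_rejected(self):
        spec = SessionSpec(duration_s=10.0,
                           plv_couplings=[PlvCoupling("S1", "RFA", 600.0, 0.5)])
        with pytest.raises(ValueError, match="Nyquist"):
            generate_session(spec)

    def test_jitter_mapping_monotone(self):
        sds = [jitter_for_plv(c) for c in (0.2, 0.5, 0.8)]
        assert sds[0] > sds[1] > sds[2] >= 0.0

    def test_pac_envelope_depth_normalization_keeps_peak(self):
        # envelope (1+m cos)/(1+m) has unit maximum for every depth
        for m in (0.0, 0.5, 1.0):
            phi = np.linspace(0, 2 * np.pi, 1001)
            env = (1 + m * np.cos(phi)) / (1 + m)
            assert env.max() == pytest.approx(1.0, abs=1e-6)
            assert env.min() == pytest.approx((1 - m) / (1 + m), abs=1e-6)


class TestArtifacts:
    def test_injected_bursts_are_dropped_by_staging(self):
        spec = SessionSpec(duration_s=600.0, n_channels_per_region=2,
                           line_noise_uv=0.0,
                           artifacts=ArtifactSpec(rate_per_min=0.5,
                                                  duration_s=2.0),
                           seed=9)
        rec, truth = generate_session(
            spec, state_intervals=[(0.0, 600.0, SWS)])
        assert truth.artifact_windows, "expected injected artifacts"
        quality = flag_bad_channels(rec)
        segs = extract_sws_segments(truth.hypnogram, rec, quality)
        # no surviving window may overlap an injected artifact
        for s, e in segs.windows:
            for a_s, a_e in truth.artifact_windows:
                assert not (a_s < e and a_e > s)


class TestStudy:
    def test_truth_table_structure_and_pairing(self):
        spec = StudySpec(segments_per_animal=1, segment_duration_s=20.0,
                         n_channels_per_region=1, seed=1)
        study = make_study(spec)
        t = study.truth
        assert len(t[t.condition == "NOLESION"]) == 5
        assert len(t[t.condition == "D7"]) == 4
        # lesion animals appear in both paired conditions
        assert set(t[t.condition == "D7"].animal) == \
            set(t[t.condition == "D14"].animal)

    def test_study_deterministic(self):
        spec = StudySpec(n_nolesion=2, n_lesion=2, segments_per_animal=1,
                         segment_duration_s=10.0, n_channels_per_region=1,
                         seed=7)
        s1 = make_study(spec)
        s2 = make_study(spec)
        k = next(iter(s1.segments))
        assert np.array_equal(s1.segments[k][0].data, s2.segments[k][0].data)
        assert s1.truth.equals(s2.truth)

    def test_condition_effect_shifts_truth(self):
        spec = StudySpec(n_nolesion=2, n_lesion=2, segments_per_animal=1,
                         segment_duration_s=10.0, n_channels_per_region=1,
                         pac_depth={"NOLESION": 0.2, "D7": 0.6, "D14": 0.2},
                         animal_re_sd=0.0, seed=2)
        t = make_study(spec).truth
        assert (t[t.condition == "D7"].pac_depth > 0.5).all()
        assert (t[t.condition == "D14"].pac_depth < 0.3).all()

    def test_study_files_written(self, tmp_path):
        spec = StudySpec(n_nolesion=2, n_lesion=2, segments_per_animal=1,
                         segment_duration_s=5.0, n_channels_per_region=1,
                         seed=3)
        make_study(spec, out_dir=tmp_path)
        assert (tmp_path / "truth.csv").exists()
        assert (tmp_path / "study.json").exists()
        assert list(tmp_path.glob("*.bin"))
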