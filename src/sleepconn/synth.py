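"""Ground-truthed synthetic LFP sessions.

Emulates the statistical structure the analysis pipeline assumes: two
multi-electrode regions (S1, RFA), a semi-Markov sleep–wake cycle with
state-dependent spectra (delta-dominated SWS, theta-dominated REM,
desynchronized WK over a 1/f background), 50 Hz line contamination with
harmonics, movement/clipping artifacts, and injectable inter-channel phase
coupling and low-frequency-phase -> high-frequency-amplitude coupling with
known parameters, so every stage of the pipeline can be validated by
parameter recovery rather than against withheld data.

Phase coupling at frequency f and strength c is injected as a shared
oscillator whose per-channel phase jitter is calibrated (Monte-Carlo lookup
table, shipped as package data; analytic fallback PLV ~ exp(-sigma^2)) so
the measured PLV approximates c.  Amplitude coupling multiplies an HF
carrier by the depth-normalized envelope (1 + m cos phi_LF) / (1 + m),
which keeps peak amplitude constant across modulation depths so coupling
tests are not confounded by power.
"""

from __future__ import annotations

import importlib.resources as _res
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import Recording, write_recording
from .staging import Hypnogram, WK, SWS, REM

__all__ = ["StateProfile", "PlvCoupling", "PacCoupling", "ArtifactSpec",
           "SessionSpec", "GroundTruth", "generate_session",
           "generate_sws_segment", "StudySpec", "Study", "make_study",
           "jitter_for_plv"]

log = logging.getLogger(__name__)

STATES = (WK, SWS, REM)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateProfile:
    """Per-state oscillator gains (uV RMS) over the 1/f background."""

    delta: float
    theta: float
    gamma: float
    background_exponent: float = 1.0


#: state-dependent spectra: SWS delta-dominant, REM theta-dominant with low
#: delta, WK flat/desynchronized — the structure the scoring ratios separate.
DEFAULT_PROFILES: dict[str, StateProfile] = {
    SWS: StateProfile(delta=60.0, theta=8.0, gamma=6.0),
    REM: StateProfile(delta=5.0, theta=45.0, gamma=10.0),
    WK: StateProfile(delta=8.0, theta=10.0, gamma=12.0),
}


@dataclass(frozen=True)
class PlvCoupling:
    """Shared-phase coupling: regions name the coupled channel sets
    (equal -> within-region)."""

    region_a: str
    region_b: str
    freq_hz: float
    strength: float  # target PLV in [0, 1]
    amplitude: float = 150.0  # oscillator RMS, uV; keeps in-band SNR high

    def __post_init__(self) -> None:
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("coupling strength must be in [0, 1]")


@dataclass(frozen=True)
class PacCoupling:
    """LF-phase (phase_region) -> HF-amplitude (amp_region) coupling."""

    phase_region: str
    amp_region: str
    lf_hz: float
    ratio: float
    depth: float  # modulation depth m in [0, 1]
    lf_amplitude: float = 30.0
    hf_amplitude: float = 12.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.depth <= 1.0:
            raise ValueError("modulation depth must be in [0, 1]")

    @property
    def hf_hz(self) -> float:
        return self.lf_hz * self.ratio


@dataclass(frozen=True)
class ArtifactSpec:
    """Clipping-burst artifacts: movement-like saturating excursions."""

    rate_per_min: float = 0.0
    duration_s: float = 2.0
    rail_uv: float = 1500.0  # amplifier range sits far above signal SD


@dataclass
class SessionSpec:
    """Full synthetic-session configuration (defaults mirror the intended
    study's recordings: 1 kHz LFP, 16 + 16 channels, 6-h sessions)."""

    duration_s: float = 21600.0
    rate: float = 1000.0
    n_channels_per_region: int = 16
    regions: tuple[str, str] = ("S1", "RFA")
    mean_dwell_s: dict = field(default_factory=lambda: {WK: 180.0, SWS: 300.0,
                                                        REM: 90.0})
    transition: dict = field(default_factory=lambda: {
        WK: {SWS: 1.0}, SWS: {WK: 0.7, REM: 0.3}, REM: {WK: 1.0}})
    profiles: dict = field(default_factory=lambda: dict(DEFAULT_PROFILES))
    background_rms: float = 20.0  # uV over the LFP band
    plv_couplings: list = field(default_factory=list)
    pac_couplings: list = field(default_factory=list)
    line_noise_uv: float = 5.0  # 50 Hz amplitude; harmonics decay 1/k
    n_harmonics: int = 3
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec)
    seed: int = 0

    def validate(self) -> None:
        nyq = self.rate / 2
        for c in self.plv_couplings:
            if c.freq_hz >= nyq:
                raise ValueError(f"PLV coupling at {c.freq_hz} Hz above Nyquist")
        for c in self.pac_couplings:
            if c.hf_hz >= nyq:
                raise ValueError(f"PAC coupling HF {c.hf_hz} Hz above Nyquist")
        for s, trans in self.transition.items():
            if abs(sum(trans.values()) - 1.0) > 1e-9:
                raise ValueError(f"transition probabilities from {s} must sum to 1")

    def to_json(self) -> str:
        def default(o):
            if hasattr(o, "__dataclass_fields__"):
                return asdict(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        return json.dumps(asdict(self), default=default, indent=1)


@dataclass
class GroundTruth:
    """Everything the generator injected, aligned to the samples."""

    hypnogram: Hypnogram
    state_intervals: list[tuple[float, float, str]]
    plv_couplings: list[PlvCoupling]
    pac_couplings: list[PacCoupling]
    artifact_windows: list[tuple[float, float]]
    region_of: dict[str, str]

    def state_at(self, t: float) -> str:
        for s, e, st in self.state_intervals:
            if s <= t < e:
                return st
        return self.state_intervals[-1][2]


# ---------------------------------------------------------------------------
# PLV jitter calibration
# ---------------------------------------------------------------------------

_CALIBRATION: pd.DataFrame | None = None


def _load_calibration() -> pd.DataFrame | None:
    global _CALIBRATION
    if _CALIBRATION is None:
        try:
            with _res.files("sleepconn").joinpath(
                    "data/plv_jitter_calibration.csv").open() as fh:
                _CALIBRATION = pd.read_csv(fh, comment="#")
        except FileNotFoundError:
            log.warning("PLV jitter calibration table not found; using the "
                        "analytic exp(-sigma^2) mapping")
            _CALIBRATION = pd.DataFrame()
    return _CALIBRATION if len(_CALIBRATION) else None


def jitter_for_plv(strength: float) -> float:
    """Phase-jitter SD (rad) whose expected measured PLV is ``strength``.

    Uses the shipped Monte-Carlo calibration table (jitter -> mean PLV under
    the generator's default conditions), inverted by interpolation; outside
    the tabulated range, or without the table, falls back to the analytic
    slow-jitter mapping PLV = exp(-sigma^2) (two independent von
    Mises-like jitters of SD sigma give a phase-difference circular
    variance of 2 sigma^2).
    """
    if strength >= 1.0:
        return 0.0
    tab = _load_calibration()
    if tab is not None:
        # table rows: jitter_sd ascending, plv descending
        plv = tab["plv"].to_numpy()
        sd = tab["jitter_sd"].to_numpy()
        if plv.min() <= strength <= plv.max():
            return float(np.interp(strength, plv[::-1], sd[::-1]))
    return float(np.sqrt(-np.log(max(strength, 1e-6))))


# ---------------------------------------------------------------------------
# signal primitives
# ---------------------------------------------------------------------------

def _one_over_f(n: int, fs: float, exponent: float,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f^exponent Gaussian noise."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = amp * (rng.standard_normal(len(freqs))
                  + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_noise(n: int, fs: float, lo: float, hi: float,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS narrow-band Gaussian noise with soft band edges."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    from scipy.special import expit

    width = max(0.15 * (hi - lo), 0.1)
    amp = expit((freqs - lo) / width) * expit(-(freqs - hi) / width)
    spec = amp * (rng.standard_normal(len(freqs))
                  + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _slow_noise(n: int, fs: float, cutoff_hz: float, sd: float,
                rng: np.random.Generator) -> np.ndarray:
    """Slowly varying Gaussian series with SD ``sd`` (for phase jitter and
    frequency drift)."""
    if sd == 0.0:
        return np.zeros(n)
    x = _band_noise(n, fs, 0.0, cutoff_hz, rng)
    return sd * x


def _oscillator_phase(n: int, fs: float, f_hz: float,
                      rng: np.random.Generator,
                      rel_bandwidth: float = 0.15) -> np.ndarray:
    """Phase of a narrow-band Gaussian process centered at ``f_hz``.

    Unlike a pure phase ramp, this phase diffuses on a ~1/(bw*f) timescale,
    as cortical rhythms do — which is what makes circular-split surrogates
    destroy injected coupling (a perfectly periodic modulator would survive
    rotation up to a constant offset).
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    sigma_f = max(rel_bandwidth * f_hz, 2.0 * fs / n)
    amp = np.exp(-0.5 * ((freqs - f_hz) / sigma_f) ** 2)
    spec = amp * (rng.standard_normal(len(freqs))
                  + 1j * rng.standard_normal(len(freqs)))
    spec[0] = 0.0
    # analytic signal: positive frequencies only
    full = np.zeros(n, dtype=complex)
    full[: len(freqs)] = spec
    z = np.fft.ifft(full * n)
    return np.unwrap(np.angle(z))


def _smooth_gate(indicator: np.ndarray, fs: float,
                 ramp_s: float = 1.0) -> np.ndarray:
    """Soft-edged 0/1 gate (moving average) to avoid switching clicks."""
    w = max(int(ramp_s * fs), 1)
    kern = np.ones(w) / w
    return np.convolve(indicator.astype(float), kern, mode="same")


# ---------------------------------------------------------------------------
# session generation
# ---------------------------------------------------------------------------

def _draw_states(spec: SessionSpec, rng: np.random.Generator,
                 ) -> list[tuple[float, float, str]]:
    """Semi-Markov state sequence with gamma-distributed dwell times."""
    intervals = []
    t = 0.0
    state = WK
    shape = 2.0
    while t < spec.duration_s:
        mean = spec.mean_dwell_s[state]
        dwell = float(rng.gamma(shape, mean / shape))
        dwell = max(dwell, 10.0)
        end = min(t + dwell, spec.duration_s)
        intervals.append((t, end, state))
        t = end
        nxt = spec.transition[state]
        state = rng.choice(list(nxt), p=list(nxt.values()))
    return intervals


def _truth_hypnogram(intervals, duration_s: float, win_s: float = 2.0,
                     step_s: float = 1.0) -> Hypnogram:
    """Ground-truth labels on the scoring epoch grid (state at window
    center; epochs straddling a transition carry the majority state)."""
    n_epochs = int((duration_s - win_s) / step_s) + 1
    centers = np.arange(n_epochs) * step_s + win_s / 2
    bounds = np.array([e for _, e, _ in intervals])
    states = [st for _, _, st in intervals]
    idx = np.searchsorted(bounds, centers, side="right")
    idx = np.clip(idx, 0, len(states) - 1)
    labels = np.array([states[i] for i in idx], dtype=object)
    return Hypnogram(epoch_times=centers, labels=labels)


def generate_session(spec: SessionSpec,
                     state_intervals: list[tuple[float, float, str]] | None = None,
                     ) -> tuple[Recording, GroundTruth]:
    """Generate one synthetic session with its ground truth.

    Per channel: 1/f background + state-gated band oscillators (delta,
    theta, gamma) + coupling terms + common line noise + clipping
    artifacts.  Fully reproducible from ``spec.seed``.  A fixed
    ``state_intervals`` sequence may be supplied instead of the semi-Markov
    draw (used for single-state segments).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.rate))
    fs = spec.rate
    t = np.arange(n) / fs

    channels: list[str] = []
    region_of: dict[str, str] = {}
    for region in spec.regions:
        for i in range(spec.n_channels_per_region):
            ch = f"{region}_{i + 1:02d}"
            channels.append(ch)
            region_of[ch] = region
    n_ch = len(channels)

    intervals = (_draw_states(spec, rng) if state_intervals is None
                 else list(state_intervals))
    gates = {}
    for st in STATES:
        ind = np.zeros(n)
        for s, e, state in intervals:
            if state == st:
                ind[int(s * fs):int(e * fs)] = 1.0
        gates[st] = _smooth_gate(ind, fs)

    data = np.empty((n_ch, n))
    bands = {"delta": (1.0, 4.0), "theta": (5.0, 8.0), "gamma": (30.0, 80.0)}
    for ci in range(n_ch):
        x = spec.background_rms * _one_over_f(
            n, fs, spec.profiles[SWS].background_exponent, rng)
        for st in STATES:
            prof = spec.profiles[st]
            if not np.any(gates[st]):
                continue
            for name, (lo, hi) in bands.items():
                gain = getattr(prof, name)
                if gain > 0:
                    x += gates[st] * gain * _band_noise(n, fs, lo, hi, rng)
        data[ci] = x

    # line noise: common across channels, harmonics decaying as 1/k
    if spec.line_noise_uv > 0:
        phase0 = rng.uniform(0, 2 * np.pi)
        for k in range(1, spec.n_harmonics + 1):
            f = 50.0 * k
            if f >= fs / 2:
                break
            data += (spec.line_noise_uv / k) * np.sin(
                2 * np.pi * f * t + phase0 * k)

    # shared-phase (PLV) couplings
    for c in spec.plv_couplings:
        phi = _oscillator_phase(n, fs, c.freq_hz, rng)
        sigma = jitter_for_plv(c.strength)
        for ci, ch in enumerate(channels):
            if region_of[ch] in (c.region_a, c.region_b):
                jit = _slow_noise(n, fs, 0.5, sigma, rng)
                data[ci] += c.amplitude * np.sqrt(2) * np.cos(phi + jit)

    # LF-phase -> HF-amplitude (PAC) couplings
    for c in spec.pac_couplings:
        phi_lf = _oscillator_phase(n, fs, c.lf_hz, rng)
        lf_wave = c.lf_amplitude * np.sqrt(2) * np.cos(phi_lf)
        env = (1.0 + c.depth * np.cos(phi_lf)) / (1.0 + c.depth)
        for ci, ch in enumerate(channels):
            if region_of[ch] == c.phase_region:
                data[ci] += lf_wave
            if region_of[ch] == c.amp_region:
                psi = rng.uniform(0, 2 * np.pi)
                data[ci] += c.hf_amplitude * np.sqrt(2) * env * np.cos(
                    2 * np.pi * c.hf_hz * t + psi)

    # clipping artifacts: saturating common-mode bursts
    artifact_windows: list[tuple[float, float]] = []
    if spec.artifacts.rate_per_min > 0:
        n_art = rng.poisson(spec.artifacts.rate_per_min * spec.duration_s / 60.0)
        for _ in range(n_art):
            s = float(rng.uniform(0, spec.duration_s - spec.artifacts.duration_s))
            e = s + spec.artifacts.duration_s
            sl = slice(int(s * fs), int(e * fs))
            burst = 3.0 * spec.artifacts.rail_uv * _band_noise(
                sl.stop - sl.start, fs, 0.5, 8.0, rng)
            data[:, sl] = np.clip(data[:, sl] + burst,
                                  -spec.artifacts.rail_uv,
                                  spec.artifacts.rail_uv)
            artifact_windows.append((s, e))

    rec = Recording(data=data, rate=fs, channels=channels, region_of=region_of)
    truth = GroundTruth(
        hypnogram=_truth_hypnogram(intervals, spec.duration_s),
        state_intervals=intervals,
        plv_couplings=list(spec.plv_couplings),
        pac_couplings=list(spec.pac_couplings),
        artifact_windows=artifact_windows,
        region_of=region_of,
    )
    return rec, truth


def generate_sws_segment(duration_s: float = 120.0, rate: float = 1000.0,
                         n_channels_per_region: int = 2,
                         plv_couplings: list | None = None,
                         pac_couplings: list | None = None,
                         background_rms: float = 20.0,
                         line_noise_uv: float = 0.0,
                         seed: int = 0) -> Recording:
    """Stationary SWS-state segment (no state switching, no artifacts).

    A shortcut for metric-level simulations: identical synthesis to the SWS
    branch of :func:`generate_session`.
    """
    spec = SessionSpec(
        duration_s=duration_s, rate=rate,
        n_channels_per_region=n_channels_per_region,
        plv_couplings=plv_couplings or [],
        pac_couplings=pac_couplings or [],
        background_rms=background_rms,
        line_noise_uv=line_noise_uv,
        artifacts=ArtifactSpec(rate_per_min=0.0),
        seed=seed,
    )
    rec, _ = generate_session(spec, state_intervals=[(0.0, duration_s, SWS)])
    return rec


# ---------------------------------------------------------------------------
# studies
# ---------------------------------------------------------------------------

@dataclass
class StudySpec:
    """Multi-animal study mirroring the experimental design: a control
    group recorded once (NOLESION) and a lesion group recorded at 7 and 14
    days (D7, D14) — paired across those two conditions.

    ``pac_depth`` / ``plv_strength`` give per-condition injected coupling
    parameters; per-animal random intercepts (SD ``animal_re_sd``) shift
    them, and ``sleep_fraction`` gets its own per-animal spread.
    """

    n_nolesion: int = 5
    n_lesion: int = 4
    segments_per_animal: int = 2
    segment_duration_s: float = 120.0
    n_channels_per_region: int = 2
    pac_lf_hz: float = 5.9
    pac_ratio: float = 7.0  # HF ~ 41 Hz
    pac_depth: dict = field(default_factory=lambda: {
        "NOLESION": 0.2, "D7": 0.2, "D14": 0.2})
    plv_freq_hz: float = 2.4
    plv_strength: dict = field(default_factory=lambda: {
        "NOLESION": 0.5, "D7": 0.5, "D14": 0.5})
    animal_re_sd: float = 0.03
    sleep_fraction: float = 0.45
    sleep_fraction_sd: float = 0.08
    seed: int = 0


@dataclass
class Study:
    """Generated study: per (animal, condition) a list of SWS segment
    recordings, plus the injected-parameter truth table."""

    segments: dict[tuple[str, str], list[Recording]]
    truth: pd.DataFrame
    spec: StudySpec

    @property
    def animals(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for (animal, cond) in self.segments:
            out.setdefault(cond, []).append(animal)
        return {c: sorted(set(a)) for c, a in out.items()}


def make_study(spec: StudySpec, out_dir: str | Path | None = None) -> Study:
    """Generate a study of SWS analysis segments with per-animal random
    effects and per-condition coupling parameters.

    Writes sessions and truth CSVs under ``out_dir`` when given (binary
    container + JSON sidecar per segment, ``truth.csv``, ``study.json``).
    """
    if spec.n_nolesion < 2 or spec.n_lesion < 2:
        raise ValueError("need at least 2 animals per group")
    root = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(root)

    plan: list[tuple[str, str]] = []
    for i in range(spec.n_nolesion):
        plan.append((f"ctl{i + 1:02d}", "NOLESION"))
    for i in range(spec.n_lesion):
        for cond in ("D7", "D14"):
            plan.append((f"les{i + 1:02d}", cond))

    # per-animal random effects are drawn once per animal
    animals = sorted({a for a, _ in plan})
    re_depth = {a: float(rng.normal(0, spec.animal_re_sd)) for a in animals}
    re_plv = {a: float(rng.normal(0, spec.animal_re_sd)) for a in animals}
    re_sleep = {a: float(rng.normal(0, spec.sleep_fraction_sd)) for a in animals}

    segments: dict[tuple[str, str], list[Recording]] = {}
    truth_rows = []
    for animal, cond in plan:
        depth = float(np.clip(spec.pac_depth[cond] + re_depth[animal], 0, 1))
        strength = float(np.clip(spec.plv_strength[cond] + re_plv[animal], 0, 1))
        sleep_frac = float(np.clip(spec.sleep_fraction + re_sleep[animal],
                                   0.05, 0.95))
        segs = []
        for si in range(spec.segments_per_animal):
            child_seed = int(rng.integers(2 ** 31))
            rec = generate_sws_segment(
                duration_s=spec.segment_duration_s,
                n_channels_per_region=spec.n_channels_per_region,
                plv_couplings=[PlvCoupling("S1", "RFA", spec.plv_freq_hz,
                                           strength)],
                pac_couplings=[PacCoupling("S1", "RFA", spec.pac_lf_hz,
                                           spec.pac_ratio, depth)],
                seed=child_seed,
            )
            segs.append(rec)
        segments[(animal, cond)] = segs
        truth_rows.append(dict(animal=animal, condition=cond,
                               pac_depth=depth, plv_strength=strength,
                               pac_lf_hz=spec.pac_lf_hz,
                               pac_hf_hz=spec.pac_lf_hz * spec.pac_ratio,
                               plv_freq_hz=spec.plv_freq_hz,
                               sleep_fraction=sleep_frac,
                               n_segments=spec.segments_per_animal))
    truth = pd.DataFrame(truth_rows)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for (animal, cond), segs in segments.items():
            for si, rec in enumerate(segs):
                write_recording(rec, out / f"{animal}_{cond}_seg{si:02d}")
        truth.to_csv(out / "truth.csv", index=False)
        (out / "study.json").write_text(json.dumps(asdict(spec), indent=1))
    return Study(segments=segments, truth=truth, spec=spec)
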