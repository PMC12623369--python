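"""Sleep–wake-cycle scoring from spectral-ratio state maps.

Vigilance states are separated by two band-power ratios computed on 2-s
windows stepped every second:

* ratio 1 = power(0.5–20 Hz) / power(0.5–55 Hz) — high during sleep, low in
  desynchronized wakefulness;
* ratio 2 = power(0.5–4.5 Hz) / power(0.5–9 Hz) — delta versus theta
  dominance, separating SWS from REM.

The first principal component of each ratio across channels, smoothed with a
20-s Hanning kernel, forms a 2-D state map whose clusters correspond to
wakefulness (WK), slow-wave sleep (SWS) and REM sleep.  Artifact-free 120-s
SWS windows are then extracted for every downstream metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as _sig

from .preprocess import ChannelQuality
from .recording import Recording

__all__ = [
    "StateMap",
    "Hypnogram",
    "SegmentSet",
    "spectral_ratios",
    "build_state_map",
    "cluster_states",
    "extract_sws_segments",
    "sws_duration",
    "WK",
    "SWS",
    "REM",
    "UNSCORED",
]

log = logging.getLogger(__name__)

WK, SWS, REM, UNSCORED = "WK", "SWS", "REM", "UNSCORED"

RATIO1_NUM = (0.5, 20.0)
RATIO1_DEN = (0.5, 55.0)
RATIO2_NUM = (0.5, 4.5)
RATIO2_DEN = (0.5, 9.0)


@dataclass
class StateMap:
    """2-D state-map coordinates per epoch (x: ratio-2 PC, y: ratio-1 PC)."""

    epoch_times: np.ndarray  # window centers, s
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray  # False where a ratio was undefined

    def __post_init__(self) -> None:
        n = len(self.epoch_times)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise ValueError("state-map arrays must share one length")


@dataclass
class Hypnogram:
    """Per-epoch WK/SWS/REM/UNSCORED labels aligned to a state map."""

    epoch_times: np.ndarray
    labels: np.ndarray  # dtype=object / str

    def __post_init__(self) -> None:
        if len(self.epoch_times) != len(self.labels):
            raise ValueError("labels and epoch_times must align")
        bad = set(np.unique(self.labels)) - {WK, SWS, REM, UNSCORED}
        if bad:
            raise ValueError(f"unknown hypnogram labels: {bad}")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"epoch_start_s": self.epoch_times, "label": self.labels})


@dataclass
class SegmentSet:
    """Non-overlapping artifact-free SWS analysis windows."""

    windows: list[tuple[float, float]]  # (start_s, end_s)
    channels: list[str]  # good channels feeding downstream metrics
    duration_s: float = 120.0

    def __post_init__(self) -> None:
        for s, e in self.windows:
            if abs((e - s) - self.duration_s) > 1e-9:
                raise ValueError(f"window ({s}, {e}) is not {self.duration_s} s long")
        starts = sorted(s for s, _ in self.windows)
        for a, b in zip(starts, starts[1:]):
            if b < a + self.duration_s - 1e-9:
                raise ValueError("segment windows overlap")

    def __len__(self) -> int:
        return len(self.windows)

    def slices(self, rate: float) -> list[slice]:
        return [slice(int(round(s * rate)), int(round(e * rate)))
                for s, e in self.windows]


# ---------------------------------------------------------------------------


def _band_power(psd: np.ndarray, freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    m = (freqs >= lo) & (freqs <= hi)
    return psd[..., m].sum(axis=-1)


def spectral_ratios(rec: Recording, win_s: float = 2.0, step_s: float = 1.0):
    """Per-channel, per-epoch spectral power ratios.

    Returns ``(epoch_times, ratio1, ratio2, valid)`` where the ratio arrays
    are (n_epochs, n_channels) and ``valid`` marks epochs whose window had
    any power on every channel.  Each 2-s window is Hann-tapered and its
    periodogram integrated over the ratio bands.
    """
    if rec.duration < win_s:
        raise ValueError("recording shorter than one scoring window")
    nwin = int(round(win_s * rec.rate))
    nstep = int(round(step_s * rec.rate))
    n_epochs = (rec.n_samples - nwin) // nstep + 1
    starts = np.arange(n_epochs) * nstep
    epoch_times = (starts + nwin / 2) / rec.rate

    taper = np.hanning(nwin)
    freqs = np.fft.rfftfreq(nwin, d=1.0 / rec.rate)
    r1 = np.empty((n_epochs, rec.n_channels))
    r2 = np.empty((n_epochs, rec.n_channels))
    valid = np.ones(n_epochs, dtype=bool)
    # windowed view: (n_epochs, nwin) per channel
    for ci in range(rec.n_channels):
        x = rec.data[ci]
        wins = np.lib.stride_tricks.sliding_window_view(x, nwin)[::nstep][:n_epochs]
        spec = np.abs(np.fft.rfft(wins * taper, axis=-1)) ** 2
        num1 = _band_power(spec, freqs, RATIO1_NUM)
        den1 = _band_power(spec, freqs, RATIO1_DEN)
        num2 = _band_power(spec, freqs, RATIO2_NUM)
        den2 = _band_power(spec, freqs, RATIO2_DEN)
        ok = (den1 > 0) & (den2 > 0)
        valid &= ok
        with np.errstate(invalid="ignore", divide="ignore"):
            r1[:, ci] = np.where(ok, num1 / np.where(den1 > 0, den1, 1.0), np.nan)
            r2[:, ci] = np.where(ok, num2 / np.where(den2 > 0, den2, 1.0), np.nan)
    return epoch_times, r1, r2, valid


def smooth_hanning(x: np.ndarray, width: int = 20) -> np.ndarray:
    """Mean-preserving same-length smoothing with a unit-sum Hanning kernel.

    Edge windows are renormalized to the kernel mass actually applied, and
    the series is re-centered so the global mean is preserved exactly.
    """
    if width < 2 or len(x) < 2:
        return np.asarray(x, dtype=float).copy()
    k = np.hanning(width + 2)[1:-1]  # strip zero endpoints
    k = k / k.sum()
    num = np.convolve(x, k, mode="same")
    den = np.convolve(np.ones_like(x, dtype=float), k, mode="same")
    y = num / den
    return y + (np.mean(x) - np.mean(y))


def _first_pc(mat: np.ndarray) -> np.ndarray:
    """First principal component scores of (epochs x channels), oriented to
    correlate positively with the cross-channel mean."""
    if mat.shape[1] < 2:
        log.warning("fewer than 2 channels; state map falls back to channel mean")
        return mat.mean(axis=1)
    from sklearn.decomposition import PCA

    pc = PCA(n_components=1).fit_transform(mat - mat.mean(axis=0))[:, 0]
    ref = mat.mean(axis=1)
    if np.std(pc) > 0 and np.std(ref) > 0 and np.corrcoef(pc, ref)[0, 1] < 0:
        pc = -pc
    return pc


def build_state_map(epoch_times: np.ndarray, ratio1: np.ndarray,
                    ratio2: np.ndarray, valid: np.ndarray | None = None,
                    smooth_s: int = 20) -> StateMap:
    """PCA across channels per ratio, then 20-s Hanning smoothing.

    ``x`` carries ratio 2 (delta dominance) and ``y`` ratio 1 (overall slow
    power); undefined epochs are interpolated before PCA and reported
    invalid in the result.
    """
    n = len(epoch_times)
    if n < smooth_s:
        raise ValueError(f"need at least {smooth_s} epochs, got {n}")
    if valid is None:
        valid = ~(np.isnan(ratio1).any(axis=1) | np.isnan(ratio2).any(axis=1))

    def clean(mat: np.ndarray) -> np.ndarray:
        mat = mat.copy()
        for c in range(mat.shape[1]):
            col = mat[:, c]
            bad = np.isnan(col)
            if bad.any():
                if bad.all():
                    mat[:, c] = 0.0
                else:
                    mat[:, c] = np.interp(np.arange(n), np.flatnonzero(~bad),
                                          col[~bad])
        return mat

    pc_r1 = _first_pc(clean(ratio1))
    pc_r2 = _first_pc(clean(ratio2))
    x = smooth_hanning(pc_r2, smooth_s)
    y = smooth_hanning(pc_r1, smooth_s)
    return StateMap(epoch_times=np.asarray(epoch_times), x=x, y=y,
                    valid=np.asarray(valid, dtype=bool))


def cluster_states(state_map: StateMap, k: int = 3, seed: int = 0,
                   n_init: int = 20) -> Hypnogram:
    """Cluster state-map points and label clusters by position.

    SWS is the cluster with the highest mean x (delta-dominant); of the
    remaining clusters, REM has the higher y (slow power with low delta) and
    WK is the rest.  A degenerate (zero-variance) map yields UNSCORED
    everywhere.
    """
    pts = np.c_[state_map.x, state_map.y]
    labels = np.full(len(pts), UNSCORED, dtype=object)
    use = state_map.valid & np.isfinite(pts).all(axis=1)
    if use.sum() < k or np.allclose(np.var(pts[use], axis=0), 0):
        log.warning("degenerate state map: all epochs unscored")
        return Hypnogram(state_map.epoch_times, labels)

    from sklearn.cluster import KMeans

    # standardize so neither axis dominates the distance metric
    p = pts[use]
    p = (p - p.mean(axis=0)) / np.where(p.std(axis=0) > 0, p.std(axis=0), 1.0)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(p)
    assign = km.labels_
    centers = km.cluster_centers_

    order = np.argsort(centers[:, 0])  # ascending mean x
    sws_c = order[-1]
    rest = order[:-1]
    rem_c = rest[np.argmax(centers[rest, 1])]
    name = {sws_c: SWS, rem_c: REM}
    for c in range(k):
        name.setdefault(c, WK)
    labels[use] = [name[c] for c in assign]
    return Hypnogram(state_map.epoch_times, labels)


def _sws_runs(hyp: Hypnogram) -> list[tuple[float, float]]:
    """Maximal (start_s, end_s) intervals of consecutive SWS epochs."""
    runs: list[tuple[float, float]] = []
    step = float(np.median(np.diff(hyp.epoch_times))) if len(hyp.epoch_times) > 1 else 1.0
    in_run = False
    start = 0.0
    for t, lab in zip(hyp.epoch_times, hyp.labels):
        if lab == SWS and not in_run:
            in_run, start = True, t - step / 2
        elif lab != SWS and in_run:
            in_run = False
            runs.append((start, t - step / 2))
    if in_run:
        runs.append((start, hyp.epoch_times[-1] + step / 2))
    return runs


def extract_sws_segments(hyp: Hypnogram, rec: Recording,
                         quality: ChannelQuality | None = None,
                         dur_s: float = 120.0,
                         artifact_z: float = 8.0) -> SegmentSet:
    """Tile SWS runs into clean, non-overlapping ``dur_s`` windows.

    Windows showing any amplitude excursion beyond ``artifact_z`` robust
    standard deviations (median/MAD) on a good channel are dropped; flagged
    channels are excluded from the returned channel list entirely.
    """
    if quality is not None:
        good = quality.good_channels(rec.channels)
    else:
        good = list(rec.channels)
    idx = [rec.channel_index(c) for c in good]

    med = np.median(rec.data[idx], axis=1, keepdims=True)
    mad = np.median(np.abs(rec.data[idx] - med), axis=1, keepdims=True)
    robust_sd = 1.4826 * np.where(mad > 0, mad, np.inf)

    windows: list[tuple[float, float]] = []
    for run_start, run_end in _sws_runs(hyp):
        n_fit = int(np.floor((run_end - run_start) / dur_s))
        for i in range(n_fit):
            s = run_start + i * dur_s
            e = s + dur_s
            sl = slice(int(round(s * rec.rate)), int(round(e * rec.rate)))
            if sl.stop > rec.n_samples:
                continue
            z = np.abs(rec.data[idx, sl] - med) / robust_sd
            if idx and np.max(z) > artifact_z:
                continue
            windows.append((s, e))
    if not windows:
        log.warning("no artifact-free SWS segment of %.0f s found", dur_s)
    return SegmentSet(windows=windows, channels=good, duration_s=dur_s)


def sws_duration(hyp: Hypnogram) -> tuple[float, float]:
    """Total SWS seconds (step-weighted epoch count) and the normalized
    duration = total / scored session length, in [0, 1]."""
    if len(hyp.epoch_times) == 0:
        return 0.0, 0.0
    step = float(np.median(np.diff(hyp.epoch_times))) if len(hyp.epoch_times) > 1 else 1.0
    total = step * float(np.sum(hyp.labels == SWS))
    scored = step * len(hyp.epoch_times)
    return total, total / scored
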