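"""Welch power spectral density per segment, channel and region.

Defaults follow the analysis configuration: 1 kHz LFP, Hann windows of
4096 samples (frequency resolution fs/nperseg ~ 0.244 Hz), 50% overlap,
density scaling in uV^2/Hz.  Region spectra are channel means; group spectra
carry a bootstrap confidence interval resampling animals with replacement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .recording import Recording
from .staging import SegmentSet

__all__ = ["PsdResult", "welch_psd", "segment_psds", "region_average",
           "bootstrap_ci"]

log = logging.getLogger(__name__)


@dataclass
class PsdResult:
    """PSD estimates on a common frequency grid.

    ``power`` is (n_segments, n_channels, n_freqs) in uV^2/Hz.
    """

    freqs: np.ndarray
    power: np.ndarray
    channels: list[str]

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("PSD power must be non-negative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")

    @property
    def resolution_hz(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def welch_psd(samples: np.ndarray, fs_hz: float = 1000.0, nperseg: int = 4096,
              overlap: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Hann-windowed averaged periodogram of one or more channels.

    ``samples`` is (..., n_samples); returns ``(freqs, psd)`` with density
    scaling.  Raises if the segment is shorter than one window.
    """
    n = np.asarray(samples).shape[-1]
    if n < nperseg:
        raise ValueError(
            f"segment of {n} samples is shorter than nperseg={nperseg}; "
            f"need at least {nperseg} samples"
        )
    freqs, psd = signal.welch(samples, fs=fs_hz, window="hann",
                              nperseg=nperseg, noverlap=int(nperseg * overlap),
                              detrend="constant", scaling="density", axis=-1)
    return freqs, psd


def segment_psds(rec: Recording, segments: SegmentSet, nperseg: int = 4096,
                 overlap: float = 0.5) -> PsdResult:
    """Welch PSD of every good channel in every analysis segment."""
    idx = [rec.channel_index(c) for c in segments.channels]
    power = []
    freqs = None
    for sl in segments.slices(rec.rate):
        freqs, psd = welch_psd(rec.data[idx, sl], fs_hz=rec.rate,
                               nperseg=nperseg, overlap=overlap)
        power.append(psd)
    if freqs is None:
        raise ValueError("empty segment set")
    return PsdResult(freqs=freqs, power=np.stack(power),
                     channels=list(segments.channels))


def region_average(psd: PsdResult, region_of) -> dict[str, np.ndarray]:
    """Mean spectrum per region: average over channels, then over segments.

    Regions left without a single good channel are omitted with a warning.
    """
    out: dict[str, np.ndarray] = {}
    regions: dict[str, list[int]] = {}
    for i, c in enumerate(psd.channels):
        regions.setdefault(region_of[c], []).append(i)
    for region, idx in regions.items():
        if not idx:
            log.warning("region %s has no good channels; omitted", region)
            continue
        out[region] = psd.power[:, idx, :].mean(axis=1).mean(axis=0)
    return out


def bootstrap_ci(per_animal: np.ndarray, n_boot: int = 1000, ci: float = 0.97,
                 seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Group mean with a percentile bootstrap CI resampling animals.

    ``per_animal`` is (n_animals, n_freqs); returns ``(mean, lo, hi)``.
    """
    per_animal = np.atleast_2d(per_animal)
    rng = np.random.default_rng(seed)
    n = per_animal.shape[0]
    means = per_animal[rng.integers(0, n, size=(n_boot, n))].mean(axis=1)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha], axis=0)
    return per_animal.mean(axis=0), lo, hi
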