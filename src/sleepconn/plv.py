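"""Morlet filter bank and phase-locking value connectivity.

The LFP is band-pass filtered with a bank of complex Morlet wavelets
(default: 43 log-spaced center frequencies, 1.2–200 Hz, width parameter
m = 7.5 cycles, i.e. sigma_t = m / (2 pi f)).  For two narrow-band
coefficient series x'(k), y'(k) the complex phase-locking value is

    cPLV = (1/K) sum_k  x'(k) y'*(k) / (|x'(k)| |y'(k)|)

and PLV = |cPLV| in [0, 1]: the length of the mean unit phasor of the phase
difference.  Channel-pair PLV matrices are averaged within S1, within RFA
and across the two regions, per segment and then over segments, alongside a
circular-split surrogate reference level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .recording import Recording
from .staging import SegmentSet
from .surrogates import SurrogateSpec, draw_split_points

__all__ = ["WaveletBank", "PLVResult", "make_bank", "morlet_kernel",
           "wavelet_coeffs", "cplv", "plv_pipeline", "PAIR_TYPES"]

log = logging.getLogger(__name__)

PAIR_TYPES = ("S1S1", "RFARFA", "S1RFA")


@dataclass(frozen=True)
class WaveletBank:
    """Log-spaced complex Morlet filter bank."""

    center_freqs: np.ndarray
    m: float = 7.5
    n_sigma: float = 4.0  # kernel support half-width, in sigma_t

    def __post_init__(self) -> None:
        f = np.asarray(self.center_freqs, dtype=float)
        if f.ndim != 1 or len(f) < 2 or np.any(np.diff(f) <= 0):
            raise ValueError("center frequencies must be strictly increasing")

    def sigma_t(self, f_hz: float) -> float:
        """Temporal width of the Gaussian envelope at ``f_hz``, seconds."""
        return self.m / (2.0 * np.pi * f_hz)

    def half_support(self, f_hz: float, fs_hz: float) -> int:
        """Half kernel length in samples at ``f_hz``."""
        return int(np.ceil(self.n_sigma * self.sigma_t(f_hz) * fs_hz))


def make_bank(n: int = 43, fmin: float = 1.2, fmax: float = 200.0,
              m: float = 7.5, spacing: str = "log") -> WaveletBank:
    """Build the default filter bank (43 wavelets, 1.2–200 Hz, m = 7.5)."""
    if not fmin < fmax or n < 2:
        raise ValueError("need fmin < fmax and n >= 2")
    if spacing == "log":
        freqs = np.geomspace(fmin, fmax, n)
    elif spacing == "linear":
        freqs = np.linspace(fmin, fmax, n)
    else:
        raise ValueError(f"unknown spacing {spacing!r}")
    return WaveletBank(center_freqs=freqs, m=m)


def morlet_kernel(f_hz: float, fs_hz: float, m: float = 7.5,
                  n_sigma: float = 4.0) -> np.ndarray:
    """Unit-energy complex Morlet kernel centered at ``f_hz``."""
    sigma_t = m / (2.0 * np.pi * f_hz)
    half = int(np.ceil(n_sigma * sigma_t * fs_hz))
    t = np.arange(-half, half + 1) / fs_hz
    kern = np.exp(-(t ** 2) / (2.0 * sigma_t ** 2)) * np.exp(2j * np.pi * f_hz * t)
    return kern / np.sqrt(np.sum(np.abs(kern) ** 2))


def wavelet_coeffs(samples: np.ndarray, bank: WaveletBank, fs_hz: float,
                   freqs: np.ndarray | None = None,
                   ) -> tuple[dict[float, np.ndarray], dict[float, slice]]:
    """Complex wavelet coefficients of (..., n_samples) at each bank frequency.

    Returns ``(coeffs, valid)``: per center frequency the same-length
    coefficient array and the slice of samples at least half a kernel
    support away from both edges (edge samples carry boundary bias and are
    excluded from K downstream).  Frequencies whose kernel does not fit the
    segment are omitted with a warning.
    """
    samples = np.asarray(samples, dtype=float)
    n = samples.shape[-1]
    coeffs: dict[float, np.ndarray] = {}
    valid: dict[float, slice] = {}
    for f in (bank.center_freqs if freqs is None else np.atleast_1d(freqs)):
        f = float(f)
        half = bank.half_support(f, fs_hz)
        if 2 * half + 1 > n:
            log.warning("segment of %d samples too short for %.2f Hz kernel; "
                        "frequency omitted", n, f)
            continue
        kern = morlet_kernel(f, fs_hz, bank.m, bank.n_sigma)
        coeffs[f] = fftconvolve(samples, kern[(np.newaxis,) * (samples.ndim - 1)],
                                mode="same", axes=-1)
        valid[f] = slice(half, n - half)
    return coeffs, valid


def cplv(x_coeffs: np.ndarray, y_coeffs: np.ndarray) -> complex:
    """Complex PLV of two equal-length coefficient series.

    Samples where either coefficient has zero magnitude are excluded from K.
    """
    x = np.asarray(x_coeffs)
    y = np.asarray(y_coeffs)
    if x.shape != y.shape:
        raise ValueError("coefficient series must have equal length")
    mag = np.abs(x) * np.abs(y)
    keep = mag > 0
    n_drop = int(np.size(keep) - np.count_nonzero(keep))
    if n_drop:
        log.info("cplv: excluded %d zero-magnitude samples", n_drop)
    if not np.any(keep):
        raise ValueError("no valid samples for cPLV (K = 0)")
    return complex(np.mean(x[keep] * np.conj(y[keep]) / mag[keep]))


def plv(x_coeffs: np.ndarray, y_coeffs: np.ndarray) -> float:
    """Phase-locking value |cPLV| in [0, 1]."""
    return abs(cplv(x_coeffs, y_coeffs))


@dataclass
class PLVResult:
    """Frequency-resolved PLV matrices and region-level mean spectra.

    ``matrices`` is (n_segments, n_freqs, n_ch, n_ch), symmetric with unit
    diagonal.  ``aggregates`` maps pair type (``S1S1``, ``RFARFA``,
    ``S1RFA``) to the mean spectrum over unordered pairs and segments;
    ``surrogate`` is the circular-split reference spectrum.
    """

    freqs: np.ndarray
    channels: list[str]
    matrices: np.ndarray
    aggregates: dict[str, np.ndarray]
    surrogate: np.ndarray | None = None

    def mean_matrix(self, band: tuple[float, float] | None = None) -> np.ndarray:
        """Segment-mean PLV matrix, optionally restricted to a band."""
        m = self.matrices.mean(axis=0)
        if band is None:
            return m.mean(axis=0)
        lo, hi = band
        sel = (self.freqs >= lo) & (self.freqs < hi)
        if not sel.any():
            raise ValueError(f"no bank frequency inside band {band}")
        return m[sel].mean(axis=0)


def _pair_type(region_a: str, region_b: str) -> str:
    if region_a == region_b:
        return "S1S1" if region_a == "S1" else "RFARFA"
    return "S1RFA"


def plv_pipeline(rec: Recording, segments: SegmentSet,
                 bank: WaveletBank | None = None,
                 surrogate_spec: SurrogateSpec | None = None,
                 seed: int = 0) -> PLVResult:
    """Per-segment channel-pair PLV at every bank frequency, aggregated
    within and between regions.

    The surrogate reference spectrum rotates one member of randomly chosen
    channel pairs (circular split of the coefficient series) and averages
    the resulting PLV per frequency.
    """
    if bank is None:
        bank = make_bank()
    channels = segments.channels
    if len(channels) < 2:
        raise ValueError("PLV needs at least 2 good channels")
    idx = [rec.channel_index(c) for c in channels]
    regions = [rec.region_of[c] for c in channels]
    n_ch = len(channels)
    if surrogate_spec is None:
        surrogate_spec = SurrogateSpec(n_surrogates=100, seed=seed)

    slices = segments.slices(rec.rate)
    freqs_used: list[float] | None = None
    all_mats: list[np.ndarray] = []
    rng = np.random.default_rng(surrogate_spec.seed)

    for seg_i, sl in enumerate(slices):
        seg = rec.data[idx, sl]
        coeffs, valid = wavelet_coeffs(seg, bank, rec.rate)
        if freqs_used is None:
            freqs_used = list(coeffs)
            surr_sum = np.zeros(len(freqs_used))
            surr_counts = np.zeros(len(freqs_used))
        mats = np.empty((len(freqs_used), n_ch, n_ch))
        for fi, f in enumerate(freqs_used):
            c = coeffs[f][:, valid[f]]
            mag = np.abs(c)
            phasor = np.where(mag > 0, c / np.where(mag > 0, mag, 1.0), 0.0)
            k_eff = phasor.shape[1]
            mat = np.abs(phasor @ phasor.conj().T) / k_eff
            np.fill_diagonal(mat, 1.0)
            mats[fi] = mat
            # surrogate reference: rotate one member of random pairs
            n_draw = max(1, surrogate_spec.n_surrogates // max(len(slices), 1))
            for _ in range(n_draw):
                a, b = rng.choice(n_ch, size=2, replace=False)
                k = int(rng.integers(surrogate_spec.min_margin,
                                     k_eff - surrogate_spec.min_margin))
                rolled = np.roll(phasor[a], k)
                surr_sum[fi] += np.abs(np.vdot(rolled, phasor[b])) / k_eff
                surr_counts[fi] += 1
        all_mats.append(mats)

    if freqs_used is None or not all_mats:
        raise ValueError("empty segment set")
    matrices = np.stack(all_mats)

    aggregates: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {t: np.zeros((n_ch, n_ch), dtype=bool)
                                    for t in PAIR_TYPES}
    for i in range(n_ch):
        for j in range(i + 1, n_ch):
            masks[_pair_type(regions[i], regions[j])][i, j] = True
    for t, mask in masks.items():
        if not mask.any():
            log.warning("no channel pairs of type %s; aggregate omitted", t)
            continue
        aggregates[t] = matrices[:, :, mask].mean(axis=(0, 2))

    surrogate = np.where(surr_counts > 0, surr_sum / np.maximum(surr_counts, 1),
                         np.nan)
    return PLVResult(freqs=np.array(freqs_used), channels=list(channels),
                     matrices=matrices, aggregates=aggregates,
                     surrogate=surrogate)
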