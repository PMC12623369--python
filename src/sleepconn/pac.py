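"""Surrogate-normalized phase–amplitude coupling (PAC) comodulograms.

PAC quantifies how the phase of a slow oscillation organizes the amplitude
of a faster one.  For a phase channel x and an amplitude channel y at a low
frequency LF and high frequency HF = LF * ratio:

* theta_x,LF      — phase of x's complex Morlet coefficients at LF;
* A_y,HF          — amplitude envelope of y filtered at HF;
* theta_env       — phase of that envelope filtered again at LF (the
  envelope's rhythm at the modulating frequency);
* PAC = |(1/K) sum_k exp(i (theta_x,LF(k) - theta_env(k)))|  in [0, 1].

Raw PAC is biased by autocorrelation, so it is normalized by the mean PAC of
circular-split surrogates: nPAC = PAC_obs / mean(PAC_surr), ~1 under the
null.  The (LF, ratio) grid is fixed: LF in {1.2 ... 68.1} Hz, 22 ratios,
and any cell whose HF = LF * ratio exceeds 200 Hz is discarded.

Note on the envelope term: the coupling statistic contrasts the LF phase of
x with the *phase of the LF-filtered amplitude envelope* of y.  Reading the
envelope term as an amplitude would leave the phasor expression undefined;
the envelope-phase reading is the one implemented (and the alternative
band-pass + analytic-signal envelope extraction sits behind
``envelope_method="hilbert"``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import fftconvolve, hilbert

from .plv import morlet_kernel
from .recording import Recording
from .staging import SegmentSet
from .surrogates import SurrogateSpec, draw_split_points

__all__ = ["PacGrid", "PacResult", "pac_value", "normalize_pac",
           "comodulogram", "project_to_hf", "DIRECTIONS"]

log = logging.getLogger(__name__)

LF_HZ = (1.2, 2.4, 3.7, 5.9, 8.6, 13.2, 19.5, 29.5, 47.3, 68.1)
RATIOS = (2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 14.06, 17.96, 22.96, 29.34, 37.49,
          47.91, 61.23, 78.25, 100, 110, 149.11, 202.13)
HF_MAX_HZ = 200.0

DIRECTIONS = ("S1S1", "RFARFA", "S1RFA", "RFAS1")


@dataclass(frozen=True)
class PacGrid:
    """The fixed LF x ratio grid with its HF <= 200 Hz validity mask."""

    lf_hz: tuple[float, ...] = LF_HZ
    ratios: tuple[float, ...] = RATIOS
    hf_max_hz: float = HF_MAX_HZ

    @property
    def hf_hz(self) -> np.ndarray:
        """HF = LF * ratio, shape (n_lf, n_ratio)."""
        return np.outer(self.lf_hz, self.ratios)

    @property
    def mask(self) -> np.ndarray:
        """True where the cell is kept (HF <= hf_max_hz)."""
        return self.hf_hz <= self.hf_max_hz

    def valid_cells(self) -> list[tuple[int, int, float, float]]:
        """(lf index, ratio index, lf_hz, hf_hz) for every kept cell."""
        hf = self.hf_hz
        m = self.mask
        return [(i, j, self.lf_hz[i], float(hf[i, j]))
                for i in range(len(self.lf_hz))
                for j in range(len(self.ratios)) if m[i, j]]


def _coeffs(x: np.ndarray, f_hz: float, fs_hz: float, m: float) -> np.ndarray:
    kern = morlet_kernel(f_hz, fs_hz, m)
    return fftconvolve(x, kern, mode="same")


# FFT-domain filtering for the comodulogram inner loops: the circular
# convolution differs from the linear one only within half a kernel support
# of the edges, which the validity margins trim anyway.  Kernel spectra are
# cached per (frequency, rate, width, length).
_KERNEL_FFT_CACHE: dict[tuple[float, float, float, int], np.ndarray] = {}


def _kernel_fft(f_hz: float, fs_hz: float, m: float, n: int) -> np.ndarray:
    key = (f_hz, fs_hz, m, n)
    if key not in _KERNEL_FFT_CACHE:
        kern = morlet_kernel(f_hz, fs_hz, m)
        if len(kern) > n:
            raise ValueError(f"segment too short for the {f_hz} Hz kernel")
        padded = np.zeros(n, dtype=complex)
        half = len(kern) // 2
        padded[: len(kern)] = kern
        padded = np.roll(padded, -half)  # center the kernel at lag zero
        if len(_KERNEL_FFT_CACHE) > 512:
            _KERNEL_FFT_CACHE.clear()
        _KERNEL_FFT_CACHE[key] = np.fft.fft(padded)
    return _KERNEL_FFT_CACHE[key]


def _coeffs_fft(x_fft: np.ndarray, f_hz: float, fs_hz: float,
                m: float) -> np.ndarray:
    """Wavelet coefficients from a precomputed full FFT of the signal."""
    n = len(x_fft)
    return np.fft.ifft(x_fft * _kernel_fft(f_hz, fs_hz, m, n))


def _margin(lf_hz: float, hf_hz: float, fs_hz: float, m: float,
            n_sigma: float = 4.0) -> int:
    """Edge samples contaminated by the HF then LF filtering chain."""
    s_lf = m / (2 * np.pi * lf_hz)
    s_hf = m / (2 * np.pi * hf_hz)
    return int(np.ceil(n_sigma * (s_lf + s_hf) * fs_hz))


def _phase_series(x: np.ndarray, y: np.ndarray, lf_hz: float, hf_hz: float,
                  fs_hz: float, m: float, envelope_method: str,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Unit phasors of theta_x,LF and theta_env on the valid interior."""
    zx = _coeffs(np.asarray(x, float), lf_hz, fs_hz, m)
    if envelope_method == "wavelet":
        amp = np.abs(_coeffs(np.asarray(y, float), hf_hz, fs_hz, m))
    elif envelope_method == "hilbert":
        # band-pass via wavelet real part, then analytic-signal envelope
        amp = np.abs(hilbert(np.real(_coeffs(np.asarray(y, float), hf_hz,
                                             fs_hz, m))))
    else:
        raise ValueError(f"unknown envelope_method {envelope_method!r}")
    zenv = _coeffs(amp - amp.mean(), lf_hz, fs_hz, m)
    margin = _margin(lf_hz, hf_hz, fs_hz, m)
    n = len(zx)
    if 2 * margin >= n:
        raise ValueError(
            f"segment of {n} samples too short for the {lf_hz} Hz kernel chain"
        )
    sl = slice(margin, n - margin)
    px = zx[sl]
    pe = zenv[sl]
    px = np.where(np.abs(px) > 0, px / np.where(np.abs(px) > 0, np.abs(px), 1), 0)
    pe = np.where(np.abs(pe) > 0, pe / np.where(np.abs(pe) > 0, np.abs(pe), 1), 0)
    return px, pe


def pac_value(x: np.ndarray, y: np.ndarray, lf_hz: float, hf_hz: float,
              fs_hz: float = 1000.0, m: float = 7.5,
              envelope_method: str = "wavelet") -> float:
    """Raw PAC between phase channel ``x`` and amplitude channel ``y``.

    Kernels are centered at the exact LF and HF values (not snapped to the
    PLV bank).  Raises for HF above the 200 Hz limit or a segment too short
    for the LF kernel chain.
    """
    if hf_hz > HF_MAX_HZ:
        raise ValueError(f"HF {hf_hz} Hz exceeds the {HF_MAX_HZ} Hz limit")
    if hf_hz <= lf_hz:
        raise ValueError("HF must exceed LF")
    px, pe = _phase_series(x, y, lf_hz, hf_hz, fs_hz, m, envelope_method)
    return float(np.abs(np.mean(px * np.conj(pe))))


def normalize_pac(raw: float, surrogate_raws: Sequence[float]) -> float:
    """nPAC = raw / mean(surrogates); ~1 under the no-coupling null."""
    surr = np.asarray(surrogate_raws, dtype=float)
    if surr.size < 1:
        raise ValueError("need at least one surrogate value")
    mean = float(surr.mean())
    if mean <= 0:
        raise ValueError("degenerate surrogate ensemble (zero mean)")
    return float(raw) / mean


def _pac_with_surrogates(px: np.ndarray, pe: np.ndarray,
                         ks: np.ndarray) -> tuple[float, np.ndarray]:
    """Observed PAC plus circular-split surrogate values (phase series of x
    rotated at each k)."""
    raw = float(np.abs(np.mean(px * np.conj(pe))))
    pc = np.conj(pe)
    surr = np.array([abs(np.mean(np.roll(px, int(k)) * pc)) for k in ks])
    return raw, surr


@dataclass
class PacResult:
    """Comodulograms per direction, with grid metadata.

    ``raw`` and ``npac`` map a direction label to an (n_lf, n_ratio) array,
    NaN at invalid (HF > 200 Hz) cells, averaged over directed channel
    pairs and segments.
    """

    grid: PacGrid
    raw: dict[str, np.ndarray]
    npac: dict[str, np.ndarray]
    n_pairs: dict[str, int]
    n_segments: int

    def hf_spectrum(self, direction: str, n_bins: int = 24,
                    hf_range: tuple[float, float] = (2.0, 200.0),
                    ) -> tuple[np.ndarray, np.ndarray]:
        """LF-mean nPAC per logarithmic HF bin (see :func:`project_to_hf`)."""
        return project_to_hf(self.npac[direction], self.grid, n_bins, hf_range)


def project_to_hf(cells: np.ndarray, grid: PacGrid, n_bins: int = 24,
                  hf_range: tuple[float, float] = (2.0, 200.0),
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Project an (LF, ratio) cell array onto a log-spaced HF axis.

    Each valid cell lands in the bin containing its HF = LF * ratio; the
    returned spectrum is the mean over all contributing LF rows per bin
    (NaN where no cell contributes).  Returns (bin centers, spectrum).
    """
    edges = np.geomspace(hf_range[0], hf_range[1], n_bins + 1)
    centers = np.sqrt(edges[:-1] * edges[1:])
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    hf = grid.hf_hz
    mask = grid.mask
    for i in range(cells.shape[0]):
        for j in range(cells.shape[1]):
            if not mask[i, j] or not np.isfinite(cells[i, j]):
                continue
            b = int(np.searchsorted(edges, hf[i, j], side="right") - 1)
            if 0 <= b < n_bins:
                sums[b] += cells[i, j]
                counts[b] += 1
    with np.errstate(invalid="ignore"):
        spec = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return centers, spec


_DIRECTION_MAP = {"S1S1": ("S1", "S1"), "RFARFA": ("RFA", "RFA"),
                  "S1RFA": ("S1", "RFA"), "RFAS1": ("RFA", "S1")}


def _direction_pairs(channels: Sequence[str], region_of,
                     direction: str) -> list[tuple[int, int]]:
    """Directed (phase channel, amplitude channel) index pairs."""
    if direction not in _DIRECTION_MAP:
        raise ValueError(f"unknown direction {direction!r}")
    src, dst = _DIRECTION_MAP[direction]
    regions = [region_of[c] for c in channels]
    pairs = [(i, j) for i in range(len(channels)) for j in range(len(channels))
             if i != j and regions[i] == src and regions[j] == dst]
    return pairs


def comodulogram(rec: Recording, segments: SegmentSet,
                 grid: PacGrid | None = None,
                 directions: Iterable[str] = DIRECTIONS,
                 n_surrogates: int = 50, seed: int = 0, m: float = 7.5,
                 envelope_method: str = "wavelet",
                 max_pairs_per_direction: int | None = None) -> PacResult:
    """Surrogate-normalized comodulogram per direction.

    Intra-areal directions (``S1S1``, ``RFARFA``) couple distinct
    electrodes within a region; inter-areal directions take the LF phase in
    one region and the HF amplitude in the other.  Cell values are averaged
    over directed channel pairs and over segments.
    ``max_pairs_per_direction`` subsamples pairs (seeded) to bound runtime.
    """
    if grid is None:
        grid = PacGrid()
    directions = list(directions)
    channels = segments.channels
    rng = np.random.default_rng(seed)

    dir_pairs: dict[str, list[tuple[int, int]]] = {}
    for d in directions:
        pairs = _direction_pairs(channels, rec.region_of, d)
        if not pairs:
            log.warning("no channel pairs for direction %s; omitted", d)
            continue
        if max_pairs_per_direction is not None and len(pairs) > max_pairs_per_direction:
            sel = rng.choice(len(pairs), size=max_pairs_per_direction,
                             replace=False)
            pairs = [pairs[s] for s in sel]
        dir_pairs[d] = pairs

    idx = [rec.channel_index(c) for c in channels]
    shape = (len(grid.lf_hz), len(grid.ratios))
    raw_acc = {d: np.zeros(shape) for d in dir_pairs}
    npac_acc = {d: np.zeros(shape) for d in dir_pairs}
    n_acc = {d: 0 for d in dir_pairs}

    slices = segments.slices(rec.rate)
    for sl in slices:
        seg = rec.data[idx, sl]
        n = seg.shape[1]
        # per-segment caches of the expensive filtering steps
        fft_cache: dict[int, np.ndarray] = {}
        zx_cache: dict[tuple[int, float], np.ndarray] = {}
        env_cache: dict[tuple[int, float, float], np.ndarray] = {}

        def sig_fft(ch: int) -> np.ndarray:
            if ch not in fft_cache:
                fft_cache[ch] = np.fft.fft(seg[ch])
            return fft_cache[ch]

        def phase_lf(ch: int, lf: float) -> np.ndarray:
            key = (ch, lf)
            if key not in zx_cache:
                zx_cache[key] = _coeffs_fft(sig_fft(ch), lf, rec.rate, m)
            return zx_cache[key]

        def env_phase(ch: int, lf: float, hf: float) -> np.ndarray:
            key = (ch, lf, hf)
            if key not in env_cache:
                zy = _coeffs_fft(sig_fft(ch), hf, rec.rate, m)
                if envelope_method == "wavelet":
                    amp = np.abs(zy)
                elif envelope_method == "hilbert":
                    amp = np.abs(hilbert(np.real(zy)))
                else:
                    raise ValueError(
                        f"unknown envelope_method {envelope_method!r}")
                env_cache[key] = _coeffs_fft(np.fft.fft(amp - amp.mean()),
                                             lf, rec.rate, m)
            return env_cache[key]

        for d, pairs in dir_pairs.items():
            raw_cells = np.full(shape, np.nan)
            npac_cells = np.full(shape, np.nan)
            for i, j, lf, hf in grid.valid_cells():
                margin = _margin(lf, hf, rec.rate, m)
                if 2 * margin >= n:
                    continue
                vs = slice(margin, n - margin)
                r_sum = n_sum = 0.0
                for (pi, aj) in pairs:
                    zx = phase_lf(pi, lf)[vs]
                    ze = env_phase(aj, lf, hf)[vs]
                    px = np.exp(1j * np.angle(zx))
                    pe = np.exp(1j * np.angle(ze))
                    spec = SurrogateSpec(
                        n_surrogates=n_surrogates,
                        seed=int(rng.integers(2 ** 31)),
                        min_margin=max(1, int(0.05 * len(px))),
                    )
                    ks = draw_split_points(len(px), spec)
                    r, surr = _pac_with_surrogates(px, pe, ks)
                    r_sum += r
                    n_sum += normalize_pac(r, surr)
                raw_cells[i, j] = r_sum / len(pairs)
                npac_cells[i, j] = n_sum / len(pairs)
            raw_acc[d] += np.nan_to_num(raw_cells)
            npac_acc[d] += np.nan_to_num(npac_cells)
            n_acc[d] += 1

    mask = grid.mask
    raw_out, npac_out = {}, {}
    for d in dir_pairs:
        n = max(n_acc[d], 1)
        raw_out[d] = np.where(mask, raw_acc[d] / n, np.nan)
        npac_out[d] = np.where(mask, npac_acc[d] / n, np.nan)
    return PacResult(grid=grid, raw=raw_out, npac=npac_out,
                     n_pairs={d: len(p) for d, p in dir_pairs.items()},
                     n_segments=len(slices))
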