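"""Circular-split surrogates for connectivity null levels.

A surrogate is built by choosing a random interior time point k and swapping
the two halves of one signal: ``x_surr = [x(k..T), x(1..k)]``.  This is a
circular rotation, so the sample multiset, the amplitude spectrum and hence
the full autocorrelation structure of the rotated channel are preserved
exactly, while its temporal alignment with the partner channel — and with it
any phase locking or phase–amplitude coupling — is destroyed.  Rotations are
applied to narrow-band (wavelet-coefficient) series, after filtering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = ["SurrogateSpec", "split_surrogate", "draw_split_points",
           "surrogate_ensemble"]


@dataclass(frozen=True)
class SurrogateSpec:
    """Surrogate-ensemble configuration.

    ``min_margin`` keeps the split point at least that many samples away
    from both ends, so a draw can never produce a near-identity rotation.
    """

    n_surrogates: int = 50
    seed: int = 0
    min_margin: int = 1

    def __post_init__(self) -> None:
        if self.n_surrogates < 1:
            raise ValueError("need at least one surrogate")
        if self.min_margin < 1:
            raise ValueError("min_margin must be >= 1")


def split_surrogate(x: np.ndarray, k: int) -> np.ndarray:
    """Rotate ``x`` circularly at interior index ``k`` (0 < k < len(x)).

    Returns ``[x[k:], x[:k]]``; the partner signal is left untouched.
    """
    x = np.asarray(x)
    n = x.shape[-1]
    if not 0 < k < n:
        raise ValueError(f"split point k={k} must satisfy 0 < k < {n}")
    return np.concatenate([x[..., k:], x[..., :k]], axis=-1)


def draw_split_points(n_samples: int, spec: SurrogateSpec) -> np.ndarray:
    """Seeded uniform draws of valid split points."""
    lo, hi = spec.min_margin, n_samples - spec.min_margin
    if hi <= lo:
        raise ValueError(
            f"signal of {n_samples} samples too short for margin {spec.min_margin}"
        )
    rng = np.random.default_rng(spec.seed)
    return rng.integers(lo, hi + 1, size=spec.n_surrogates)


def surrogate_ensemble(x: np.ndarray, y: np.ndarray, spec: SurrogateSpec,
                       metric_fn: Callable[[np.ndarray, np.ndarray], float],
                       ) -> tuple[np.ndarray, float]:
    """Evaluate ``metric_fn`` on ``spec.n_surrogates`` rotated copies of x.

    Returns ``(values, mean)``; reproducible given ``spec.seed``.  ``x`` and
    ``y`` are typically narrow-band coefficient series and ``metric_fn`` a
    PLV- or PAC-valued function.
    """
    ks = draw_split_points(np.asarray(x).shape[-1], spec)
    values = np.array([metric_fn(split_surrogate(x, int(k)), y) for k in ks])
    return values, float(values.mean())
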