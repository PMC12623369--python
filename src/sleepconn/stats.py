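"""Per-frequency group comparisons with multiple-testing control.

For spectra observed per animal (PSD, PLV or nPAC HF-spectra) this module
runs, frequency by frequency:

* unpaired contrast (control vs lesion D7): Mann–Whitney U on central
  tendency, Fligner–Killeen on spread;
* paired contrast (D7 vs D14, same animals): paired t-test, and a
  permutation test on the difference of log variances whose null swaps each
  animal's condition pair independently (exhaustive for n <= 12 animals,
  seeded sampling otherwise);
* descriptors: per-group coefficient of variation (SD/mean across animals),
  log variance ratio lnVR = ln(var_a / var_b), Cohen's d with pooled SD;
* Benjamini–Hochberg adjustment across frequencies at alpha = 0.05.

A Shapiro–Wilk normality report is produced alongside but never switches
the tests: the battery above runs regardless of its outcome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["SpectrumByAnimal", "ComparisonReport", "compare_unpaired",
           "compare_paired", "bh_adjust", "shapiro_gate", "cohens_d",
           "ln_variance_ratio", "coefficient_of_variation"]

log = logging.getLogger(__name__)


@dataclass
class SpectrumByAnimal:
    """One metric spectrum per animal: ``values`` is (n_animals, n_freqs)."""

    animals: list[str]
    condition: str
    freqs: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.animals), len(self.freqs)):
            raise ValueError("values must be (n_animals, n_freqs)")


@dataclass
class ComparisonReport:
    """Per-frequency test battery results (one row per frequency)."""

    frame: pd.DataFrame
    kind: str  # "unpaired" | "paired"
    alpha: float = 0.05

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def coefficient_of_variation(x: np.ndarray, axis: int = 0) -> np.ndarray:
    """CV = SD / mean (across animals); NaN where the mean vanishes."""
    x = np.asarray(x, dtype=float)
    mean = x.mean(axis=axis)
    sd = x.std(axis=axis, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(mean != 0, sd / mean, np.nan)


def ln_variance_ratio(a: np.ndarray, b: np.ndarray, axis: int = 0) -> np.ndarray:
    """lnVR = ln(var_a / var_b); antisymmetric under group swap."""
    va = np.var(a, axis=axis, ddof=1)
    vb = np.var(b, axis=axis, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.log(va / vb)


def cohens_d(a: np.ndarray, b: np.ndarray, axis: int = 0) -> np.ndarray:
    """Cohen's d with pooled SD; antisymmetric under group swap."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.shape[axis], b.shape[axis]
    va = np.var(a, axis=axis, ddof=1)
    vb = np.var(b, axis=axis, ddof=1)
    pooled = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(pooled > 0,
                        (a.mean(axis=axis) - b.mean(axis=axis)) / pooled, 0.0)


def effect_size_label(d: float) -> str:
    """Conventional small/medium/large descriptor (0.2/0.5/0.8 cutoffs)."""
    d = abs(d)
    if d < 0.2:
        return "negligible"
    if d < 0.5:
        return "small"
    if d < 0.8:
        return "medium"
    return "large"


def bh_adjust(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up adjusted q-values and rejection set.

    Returns ``(q, reject)``; empty input yields empty output.  NaN p-values
    propagate as NaN / non-rejected.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    q = np.full(p.shape, np.nan)
    reject = np.zeros(p.shape, dtype=bool)
    ok = np.isfinite(p)
    if ok.any():
        from statsmodels.stats.multitest import multipletests

        rej, qv, _, _ = multipletests(p[ok], alpha=alpha, method="fdr_bh")
        q[ok] = qv
        reject[ok] = rej
    return q, reject


def _battery_frame(freqs, rows) -> pd.DataFrame:
    frame = pd.DataFrame(rows)
    frame.insert(0, "freq_hz", np.asarray(freqs))
    frame["q_central"], frame["reject_central"] = bh_adjust(frame["p_central"])
    frame["q_var"], frame["reject_var"] = bh_adjust(frame["p_var"])
    return frame


def compare_unpaired(a: SpectrumByAnimal, b: SpectrumByAnimal,
                     alpha: float = 0.05) -> ComparisonReport:
    """Independent-groups battery: Mann–Whitney U + Fligner–Killeen.

    Groups smaller than 2 animals yield NaN tests with a "skipped" marker.
    """
    if not np.allclose(a.freqs, b.freqs):
        raise ValueError("groups must share one frequency grid")
    rows = []
    for fi in range(len(a.freqs)):
        xa, xb = a.values[:, fi], b.values[:, fi]
        row = dict(p_central=np.nan, p_var=np.nan, skipped=False)
        if len(xa) < 2 or len(xb) < 2:
            row["skipped"] = True
        else:
            try:
                row["p_central"] = float(
                    sps.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
            except ValueError:  # all-identical values
                row["p_central"] = 1.0
            try:
                row["p_var"] = float(sps.fligner(xa, xb).pvalue)
            except ValueError:
                row["p_var"] = 1.0
        row["cv_a"] = float(coefficient_of_variation(xa))
        row["cv_b"] = float(coefficient_of_variation(xb))
        row["lnvr"] = float(ln_variance_ratio(xa, xb))
        row["cohen_d"] = float(cohens_d(xa, xb))
        rows.append(row)
    return ComparisonReport(_battery_frame(a.freqs, rows), kind="unpaired",
                            alpha=alpha)


def _perm_log_var(da: np.ndarray, db: np.ndarray, n_perm: int,
                  seed: int) -> float:
    """Two-sided p for T = ln var(a) - ln var(b) under per-animal swaps.

    Exhaustive over all 2^n assignments when n <= 12, else ``n_perm``
    seeded draws; add-one smoothed for the sampled case.
    """
    n = len(da)

    def t_stat(a, b):
        return np.log(np.var(a, ddof=1)) - np.log(np.var(b, ddof=1))

    t_obs = t_stat(da, db)
    if not np.isfinite(t_obs):
        return np.nan

    def t_for_swaps(swaps: np.ndarray) -> np.ndarray:
        pa = np.where(swaps, db, da)
        pb = np.where(swaps, da, db)
        return (np.log(np.var(pa, axis=1, ddof=1))
                - np.log(np.var(pb, axis=1, ddof=1)))

    if n <= 12:
        masks = np.arange(2 ** n)[:, None]
        swaps = (masks >> np.arange(n)) & 1
        t = t_for_swaps(swaps.astype(bool))
        return float(np.mean(np.abs(t) >= abs(t_obs) - 1e-12))
    rng = np.random.default_rng(seed)
    swaps = rng.integers(0, 2, size=(n_perm, n)).astype(bool)
    t = t_for_swaps(swaps)
    return (int(np.sum(np.abs(t) >= abs(t_obs) - 1e-12)) + 1) / (n_perm + 1)


def compare_paired(a7: SpectrumByAnimal, a14: SpectrumByAnimal,
                   alpha: float = 0.05, n_perm: int = 10_000,
                   seed: int = 0) -> ComparisonReport:
    """Within-subject battery: paired t + permutation on log variance.

    Requires the same animals in the same order in both conditions.
    """
    if a7.animals != a14.animals:
        raise ValueError("paired comparison requires identical, aligned animals")
    if not np.allclose(a7.freqs, a14.freqs):
        raise ValueError("groups must share one frequency grid")
    rows = []
    for fi in range(len(a7.freqs)):
        xa, xb = a7.values[:, fi], a14.values[:, fi]
        row = dict(p_central=np.nan, p_var=np.nan, skipped=False)
        if len(xa) < 2:
            row["skipped"] = True
        else:
            if np.allclose(xa, xb):
                row["p_central"] = 1.0
                row["p_var"] = 1.0
            else:
                row["p_central"] = float(sps.ttest_rel(xa, xb).pvalue)
                row["p_var"] = _perm_log_var(xa, xb, n_perm, seed + fi)
        row["cv_a"] = float(coefficient_of_variation(xa))
        row["cv_b"] = float(coefficient_of_variation(xb))
        row["lnvr"] = float(ln_variance_ratio(xa, xb))
        row["cohen_d"] = float(cohens_d(xa, xb))
        rows.append(row)
    return ComparisonReport(_battery_frame(a7.freqs, rows), kind="paired",
                            alpha=alpha)


def shapiro_gate(values: np.ndarray, freqs: np.ndarray | None = None,
                 ) -> pd.DataFrame:
    """Shapiro–Wilk normality report per frequency (informational only).

    ``values`` is (n_animals, n_freqs).  Constant samples or n < 3 are
    marked skipped.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, n_freq = values.shape
    if freqs is None:
        freqs = np.arange(n_freq, dtype=float)
    rows = []
    for fi in range(n_freq):
        x = values[:, fi]
        if n < 3 or np.allclose(x, x[0]):
            rows.append(dict(freq_hz=freqs[fi], W=np.nan, p=np.nan,
                             skipped=True))
        else:
            w, p = sps.shapiro(x)
            rows.append(dict(freq_hz=freqs[fi], W=float(w), p=float(p),
                             skipped=False))
    return pd.DataFrame(rows)
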