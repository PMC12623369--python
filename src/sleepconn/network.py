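"""Graph metrics on PLV matrices and mixed-model sleep–centrality trends.

Eigenvector centrality (EVC) — the leading eigenvector of the band-averaged
PLV matrix with zeroed diagonal, non-negative and unit L2 norm — scores each
channel's importance in the slow-wave-sleep connectivity network.  Per
(region, band) the relation between normalized SWS duration and
square-root-transformed EVC is modelled with a linear mixed-effects model
(random intercept per animal), duration x condition fixed effects, per-
condition slopes, pairwise slope contrasts and Benjamini–Hochberg-adjusted
p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BANDS", "evc", "band_average", "CentralityTable",
           "fit_sleep_centrality", "SlopeReport"]

log = logging.getLogger(__name__)

#: canonical frequency bands (Hz)
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 100.0),
}

CONDITIONS = ("NOLESION", "D7", "D14")


def band_average(matrices: np.ndarray, freqs: np.ndarray,
                 band: tuple[float, float]) -> np.ndarray:
    """Average (n_freqs, n, n) PLV matrices over bank frequencies whose
    centers fall inside ``band`` (lower edge inclusive)."""
    lo, hi = band
    sel = (freqs >= lo) & (freqs < hi)
    if not sel.any():
        raise ValueError(f"no frequency inside band {band}")
    return np.asarray(matrices)[sel].mean(axis=0)


def evc(plv_matrix: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Eigenvector centrality of a symmetric non-negative PLV matrix.

    The diagonal is zeroed, the leading eigenvector taken (dense
    eigendecomposition), signs fixed non-negative and the vector scaled to
    unit L2 norm.  A disconnected matrix is scored per connected component
    (each component's sub-vector unit-normalized within the global vector
    of its size) with a warning.
    """
    a = np.asarray(plv_matrix, dtype=float).copy()
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("PLV matrix must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("PLV matrix must be symmetric")
    if np.any(a < -tol):
        raise ValueError("PLV matrix must be non-negative")
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]

    import networkx as nx

    g = nx.from_numpy_array(a > 0)
    comps = list(nx.connected_components(g))
    out = np.zeros(n)
    if len(comps) > 1:
        log.warning("PLV graph has %d components; EVC computed per component",
                    len(comps))
    for comp in comps:
        idx = sorted(comp)
        if len(idx) == 1:
            out[idx[0]] = 1.0
            continue
        sub = a[np.ix_(idx, idx)]
        w, v = np.linalg.eigh(sub)
        lead = v[:, np.argmax(w)]
        if lead.sum() < 0:
            lead = -lead
        lead = np.abs(lead)  # Perron vector of a non-negative matrix
        out[idx] = lead / np.linalg.norm(lead)
    if len(comps) == 1:
        out = out / np.linalg.norm(out)
    return out


@dataclass
class CentralityTable:
    """Long-form per-channel centrality observations.

    Columns: animal, condition (NOLESION/D7/D14), region, band, channel,
    evc, sqrt_evc, norm_sws_duration.
    """

    frame: pd.DataFrame

    REQUIRED = ("animal", "condition", "region", "band", "channel", "evc",
                "norm_sws_duration")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"centrality table missing columns: {missing}")
        if (self.frame["evc"] < 0).any():
            raise ValueError("evc must be non-negative")
        if "sqrt_evc" not in self.frame.columns:
            self.frame = self.frame.assign(sqrt_evc=np.sqrt(self.frame["evc"]))


@dataclass
class SlopeReport:
    """Per-(region, band, condition) duration slopes and their contrasts.

    ``slopes`` columns: region, band, condition, estimate, se, t, df, p,
    p_adj.  ``contrasts`` columns: region, band, cond_a, cond_b, estimate,
    se, t, p, p_adj (estimate antisymmetric under swapping a and b).
    """

    slopes: pd.DataFrame
    contrasts: pd.DataFrame
    backend: str = "mixedlm"


def _fit_one(sub: pd.DataFrame):
    """Fit sqrt_evc ~ duration * condition with animal random intercepts.

    Returns (slope rows, contrast rows, backend) for one (region, band).
    Falls back to per-condition OLS when the mixed fit is singular.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    conds = [c for c in CONDITIONS if c in set(sub["condition"])]
    sub = sub.copy()
    sub["condition"] = pd.Categorical(sub["condition"], categories=conds)

    backend = "mixedlm"
    try:
        md = smf.mixedlm("sqrt_evc ~ norm_sws_duration * condition", sub,
                         groups=sub["animal"])
        fit = md.fit(reml=True, method="lbfgs")
        if not np.isfinite(fit.bse_fe).all():
            raise np.linalg.LinAlgError("non-finite standard errors")
        params, cov = fit.fe_params, fit.cov_params().loc[
            fit.fe_params.index, fit.fe_params.index]
        df_resid = fit.df_resid
    except Exception as exc:  # singular / non-converged mixed fit
        log.warning("mixed model failed (%s); falling back to OLS", exc)
        backend = "ols"
        fit = smf.ols("sqrt_evc ~ norm_sws_duration * condition", sub).fit()
        params, cov = fit.params, fit.cov_params()
        df_resid = fit.df_resid

    def slope_vec(cond: str) -> np.ndarray:
        v = pd.Series(0.0, index=params.index)
        v["norm_sws_duration"] = 1.0
        inter = f"norm_sws_duration:condition[T.{cond}]"
        if inter in v.index:
            v[inter] = 1.0
        return v.to_numpy()

    from scipy import stats as sps

    slope_rows, contrast_rows = [], []
    vecs = {c: slope_vec(c) for c in conds}
    for c in conds:
        v = vecs[c]
        est = float(v @ params.to_numpy())
        se = float(np.sqrt(v @ cov.to_numpy() @ v))
        t = est / se if se > 0 else np.nan
        p = 2 * sps.t.sf(abs(t), df_resid) if np.isfinite(t) else np.nan
        slope_rows.append(dict(condition=c, estimate=est, se=se, t=t,
                               df=df_resid, p=p))
    for ia, ca in enumerate(conds):
        for cb in conds[ia + 1:]:
            v = vecs[ca] - vecs[cb]
            est = float(v @ params.to_numpy())
            se = float(np.sqrt(v @ cov.to_numpy() @ v))
            t = est / se if se > 0 else np.nan
            p = 2 * sps.t.sf(abs(t), df_resid) if np.isfinite(t) else np.nan
            contrast_rows.append(dict(cond_a=ca, cond_b=cb, estimate=est,
                                      se=se, t=t, p=p))
    return slope_rows, contrast_rows, backend


def fit_sleep_centrality(table: CentralityTable) -> SlopeReport:
    """Duration-vs-centrality slopes per (region, band) with BH correction.

    BH adjustment is applied within each region across all its band x
    condition slope tests (and separately across its contrasts).
    """
    df = table.frame
    if df["animal"].nunique() < 2:
        raise ValueError("need at least 2 animals")
    if df["norm_sws_duration"].nunique() < 2:
        raise ValueError("need at least 2 distinct duration values")

    from statsmodels.stats.multitest import multipletests

    slope_rows, contrast_rows = [], []
    backend = "mixedlm"
    for (region, band), sub in df.groupby(["region", "band"], observed=True):
        s_rows, c_rows, be = _fit_one(sub)
        if be == "ols":
            backend = "ols"
        for r in s_rows:
            slope_rows.append(dict(region=region, band=band, **r))
        for r in c_rows:
            contrast_rows.append(dict(region=region, band=band, **r))

    slopes = pd.DataFrame(slope_rows)
    contrasts = pd.DataFrame(contrast_rows)
    for frame in (slopes, contrasts):
        frame["p_adj"] = np.nan
        if frame.empty:
            continue
        for region, sub in frame.groupby("region"):
            ok = sub["p"].notna()
            if ok.any():
                _, q, _, _ = multipletests(sub.loc[ok, "p"], method="fdr_bh")
                frame.loc[sub.index[ok], "p_adj"] = q
    return SlopeReport(slopes=slopes, contrasts=contrasts, backend=backend)
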