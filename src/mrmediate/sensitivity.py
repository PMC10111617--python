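"""Heterogeneity and pleiotropy diagnostics for MR instrument sets.

Excess heterogeneity among per-instrument causal estimates, or a non-zero
average pleiotropy intercept, signals violations of the exclusion
restriction.  Three complementary diagnostics are provided:

* :func:`cochran_q` — Cochran's Q against the IVW fit (ratio scale,
  n-1 df) or Ruecker's Q' against the Egger fit (regression scale, n-2 df);
* :func:`egger_intercept_test` — the MR-Egger intercept with a two-sided
  t test;
* :func:`mr_presso` — the simulation-based residual-sum-of-squares global
  test with per-SNP outlier detection (Bonferroni-adjusted) and a
  distortion test comparing the IVW slope before and after outlier removal.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import egger, ivw, _orient, _wls_line
from .summary_data import HarmonizedSet


class QResult(NamedTuple):
    statistic: float
    df: int
    pval: float


class InterceptResult(NamedTuple):
    estimate: float
    se: float
    pval: float


@dataclasses.dataclass
class PressoResult:
    """MR-PRESSO global, outlier and distortion test results."""

    global_rss: float
    global_p: float
    outlier_p: dict[str, float]  # Bonferroni-adjusted per-SNP p
    outliers: list[str]
    distortion_p: float | None
    n_simulations: int
    seed: int


@dataclasses.dataclass
class SensitivityReport:
    """Bundle of heterogeneity and pleiotropy diagnostics for one analysis."""

    q_ivw: QResult | None = None
    q_egger: QResult | None = None
    egger_intercept: InterceptResult | None = None
    presso: PressoResult | None = None

    def to_dict(self) -> dict:
        d: dict = {}
        if self.q_ivw is not None:
            d["q_ivw"] = dict(self.q_ivw._asdict())
        if self.q_egger is not None:
            d["q_egger"] = dict(self.q_egger._asdict())
        if self.egger_intercept is not None:
            d["egger_intercept"] = dict(self.egger_intercept._asdict())
        if self.presso is not None:
            p = self.presso
            d["mr_presso"] = {
                "global_rss": p.global_rss,
                "global_p": p.global_p,
                "outlier_p": p.outlier_p,
                "outliers": p.outliers,
                "distortion_p": p.distortion_p,
                "n_simulations": p.n_simulations,
                "seed": p.seed,
            }
        return d


def cochran_q(h: HarmonizedSet, fit: str = "ivw") -> QResult:
    """Cochran's Q heterogeneity statistic.

    ``fit="ivw"``: Q = sum w_j (ratio_j - beta_ivw)^2 on the Wald-ratio
    scale with weights 1/se(ratio)^2 and n-1 df.  ``fit="egger"``:
    Ruecker's Q', the weighted residual sum of squares of the Egger line on
    the regression scale (weights 1/se_out^2) with n-2 df.
    """
    if fit == "ivw":
        if h.nsnp < 2:
            raise ValueError("Cochran's Q (IVW) needs at least 2 SNPs")
        ratios = h.beta_out / h.beta_exp
        w = h.beta_exp**2 / h.se_out**2
        beta = float(np.sum(w * ratios) / np.sum(w))
        q = float(np.sum(w * (ratios - beta) ** 2))
        df = h.nsnp - 1
    elif fit == "egger":
        if h.nsnp < 3:
            raise ValueError("Ruecker's Q' (Egger) needs at least 3 SNPs")
        x, y = _orient(h)
        w = 1.0 / h.se_out**2
        _, _, _, rss, df = _wls_line(x, y, w)
        q = rss
    else:
        raise ValueError(f"unknown fit {fit!r}")
    return QResult(q, df, float(stats.chi2.sf(q, df)))


def egger_intercept_test(h: HarmonizedSet) -> InterceptResult:
    """MR-Egger pleiotropy intercept with its two-sided t test.

    A two-SNP input yields the exact line through both points; the
    intercept is reported with a df=0 warning and no inference.
    """
    if h.nsnp == 2:
        warnings.warn(
            "2-point Egger fit is exact (df=0); intercept reported without "
            "inference",
            stacklevel=2,
        )
        x, y = _orient(h)
        slope = (y[1] - y[0]) / (x[1] - x[0])
        intercept = y[0] - slope * x[0]
        return InterceptResult(float(intercept), math.nan, math.nan)
    e = egger(h)
    assert e.egger_intercept is not None
    return InterceptResult(e.egger_intercept, e.egger_intercept_se, e.egger_intercept_p)


def _loo_slopes(x, y, w):
    """Leave-one-out zero-intercept WLS slopes, vectorized over rows.

    x, y may be (n,) or (n_sim, n); w is (n,).
    """
    sxy = np.sum(w * x * y, axis=-1, keepdims=True)
    sxx = np.sum(w * x * x, axis=-1, keepdims=True)
    return (sxy - w * x * y) / (sxx - w * x * x)


def mr_presso(
    h: HarmonizedSet,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
) -> PressoResult:
    """MR-PRESSO: global RSS test, per-SNP outlier test, distortion test.

    The observed statistic is the weighted residual sum of squares of each
    SNP against the IVW slope fitted *without* that SNP.  The null
    distribution comes from ``n_sim`` parametric simulations drawing per-SNP
    effects from Gaussians centred on the leave-one-out fitted values.  The
    per-SNP outlier p-values are Bonferroni-adjusted over SNPs; if any SNP
    is flagged, the distortion test permutes outlier labels to assess
    whether removing the flagged SNPs changes the IVW slope more than
    removing a random subset of the same size.  Reproducible bit-for-bit
    given (seed, n_sim).
    """
    n = h.nsnp
    if n < 4:
        raise ValueError("MR-PRESSO is undefined for fewer than 4 SNPs")
    if n_sim < 100:
        raise ValueError("MR-PRESSO needs n_sim >= 100")
    x = h.beta_exp
    y = h.beta_out
    w = 1.0 / h.se_out**2

    loo = np.atleast_1d(np.squeeze(_loo_slopes(x, y, w)))
    resid_obs = w * (y - x * loo) ** 2
    rss_obs = float(np.sum(resid_obs))

    rng = np.random.default_rng(seed)
    xs = x + h.se_exp * rng.standard_normal((n_sim, n))
    ys = x * loo + h.se_out * rng.standard_normal((n_sim, n))
    loo_s = _loo_slopes(xs, ys, w)
    resid_s = w * (ys - xs * loo_s) ** 2
    rss_s = resid_s.sum(axis=1)

    global_p = float(np.mean(rss_s >= rss_obs))
    p_raw = np.mean(resid_s >= resid_obs[None, :], axis=0)
    p_adj = np.minimum(1.0, p_raw * n)
    outlier_p = {s: float(p) for s, p in zip(h.snp_ids, p_adj)}
    flagged = [s for s, p in outlier_p.items() if p < outlier_alpha]

    distortion_p: float | None = None
    if flagged and len(flagged) < n:
        is_out = np.array([s in flagged for s in h.snp_ids])
        slope_all = float(np.sum(w * x * y) / np.sum(w * x * x))

        def slope_without(mask: np.ndarray) -> float:
            keep = ~mask
            return float(
                np.sum(w[keep] * x[keep] * y[keep])
                / np.sum(w[keep] * x[keep] * x[keep])
            )

        d_obs = slope_all - slope_without(is_out)
        k = int(is_out.sum())
        d_sim = np.empty(n_sim)
        for i in range(n_sim):
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=k, replace=False)] = True
            d_sim[i] = slope_all - slope_without(mask)
        distortion_p = float(np.mean(np.abs(d_sim) >= abs(d_obs)))

    return PressoResult(
        global_rss=rss_obs,
        global_p=global_p,
        outlier_p=outlier_p,
        outliers=flagged,
        distortion_p=distortion_p,
        n_simulations=n_sim,
        seed=seed,
    )


def sensitivity_report(
    h: HarmonizedSet,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
    run_presso: bool = True,
) -> SensitivityReport:
    """All diagnostics applicable at the available instrument count."""
    rep = SensitivityReport()
    if h.nsnp >= 2:
        rep.q_ivw = cochran_q(h, "ivw")
    if h.nsnp >= 3:
        rep.q_egger = cochran_q(h, "egger")
        rep.egger_intercept = egger_intercept_test(h)
    if run_presso and h.nsnp >= 4:
        rep.presso = mr_presso(h, n_sim=n_sim, outlier_alpha=outlier_alpha, seed=seed)
    return rep


def funnel_data(h: HarmonizedSet) -> pd.DataFrame:
    """Per-SNP Wald ratio vs precision, the funnel-plot coordinates."""
    ratios = h.beta_out / h.beta_exp
    se_ratio = h.se_out / np.abs(h.beta_exp)
    return pd.DataFrame(
        {"snp_id": h.snp_ids, "ratio": ratios, "precision": 1.0 / se_ratio}
    )
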