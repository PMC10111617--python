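"""Causal-effect estimators for two-sample Mendelian randomization.

All estimators consume a :class:`~mrmediate.summary_data.HarmonizedSet` of
per-SNP exposure and outcome effects and return an :class:`MrEstimate`
carrying the causal log-OR, its standard error, the OR with a 95% CI, and
the instrument count.

* :func:`wald_ratio` — single instrument, ``beta_out / beta_exp`` with a
  first-order delta-method standard error.
* :func:`ivw` — inverse-variance-weighted pooling of per-SNP Wald ratios
  with weights ``beta_exp^2 / se_out^2``; identical to the slope of the
  zero-intercept weighted regression of outcome on exposure effects.  The
  default model inflates the SE multiplicatively by ``sqrt(max(1, Q/df))``.
* :func:`egger` — weighted regression *with* an intercept; the intercept
  estimates average directional pleiotropy and the slope is a
  pleiotropy-adjusted causal effect (inference on n-2 df t).
* :func:`weighted_median` — the per-SNP ratio at which the cumulative
  normalized weight crosses 1/2, consistent when valid instruments carry
  more than half the weight; SE by parametric bootstrap.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings

import numpy as np
from scipy import stats

from .summary_data import HarmonizedSet

logger = logging.getLogger(__name__)

#: two-sided 95% Gaussian multiplier
Z95 = 1.959964

METHODS = ("wald_ratio", "ivw", "egger", "weighted_median")


@dataclasses.dataclass
class MrEstimate:
    """A causal effect estimate on the log-OR scale with its OR and 95% CI."""

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def ci_low(self) -> float:
        return math.exp(self.beta - Z95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.beta + Z95 * self.se)

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "n_snp": self.n_snp,
            "beta": self.beta,
            "se": self.se,
            "pval": self.pval,
            "or": self.or_,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }
        if self.egger_intercept is not None:
            d["egger_intercept"] = self.egger_intercept
            d["egger_intercept_se"] = self.egger_intercept_se
            d["egger_intercept_p"] = self.egger_intercept_p
        return d


def _gauss_p(beta: float, se: float) -> float:
    if se == 0:
        return 0.0 if beta != 0 else 1.0
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def wald_ratio(h: HarmonizedSet) -> MrEstimate:
    """Single-instrument causal estimate ``beta_out / beta_exp``.

    The standard error is the first-order delta-method approximation
    ``se_out / |beta_exp|``, which ignores exposure-side noise; adequate for
    strong instruments (|beta_exp/se_exp| >~ 10).
    """
    if h.nsnp != 1:
        raise ValueError("wald_ratio requires exactly one SNP")
    be = float(h.beta_exp[0])
    if be == 0:
        raise ZeroDivisionError("Wald ratio undefined for beta_exp = 0")
    beta = float(h.beta_out[0]) / be
    se = float(h.se_out[0]) / abs(be)
    return MrEstimate("wald_ratio", beta, se, _gauss_p(beta, se), 1)


def _drop_null_exposure(h: HarmonizedSet) -> HarmonizedSet:
    zero = h.beta_exp == 0
    if zero.any():
        warnings.warn(
            f"excluding {int(zero.sum())} SNP(s) with beta_exp = 0 "
            "(undefined Wald ratio)",
            stacklevel=3,
        )
        h = h.subset(~zero)
    return h


def ivw(h: HarmonizedSet, model: str = "multiplicative_random") -> MrEstimate:
    """Inverse-variance-weighted estimate over multiple instruments.

    ``model="fixed"`` uses ``se = 1/sqrt(sum w)``;
    ``model="multiplicative_random"`` (default) inflates it by
    ``sqrt(max(1, Q/(n-1)))`` where Q is Cochran's heterogeneity statistic.
    A single-SNP input delegates to :func:`wald_ratio`.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    h = _drop_null_exposure(h)
    if h.nsnp == 1:
        return wald_ratio(h)
    ratios = h.beta_out / h.beta_exp
    w = h.beta_exp**2 / h.se_out**2
    beta = float(np.sum(w * ratios) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    if model == "multiplicative_random":
        q = float(np.sum(w * (ratios - beta) ** 2))
        se *= math.sqrt(max(1.0, q / (h.nsnp - 1)))
    return MrEstimate("ivw", beta, se, _gauss_p(beta, se), h.nsnp)


def _orient(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    """Joint sign flip so every exposure effect is non-negative."""
    sign = np.where(h.beta_exp < 0, -1.0, 1.0)
    return h.beta_exp * sign, h.beta_out * sign


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted straight-line fit; returns (intercept, slope, cov, rss_w, df)."""
    sw = np.sqrt(w)
    design = np.column_stack([np.ones_like(x), x]) * sw[:, None]
    yw = y * sw
    xtx = design.T @ design
    coef = np.linalg.solve(xtx, design.T @ yw)
    resid = yw - design @ coef
    rss = float(resid @ resid)
    df = len(x) - 2
    cov_unscaled = np.linalg.inv(xtx)
    return coef[0], coef[1], cov_unscaled, rss, df


def egger(h: HarmonizedSet) -> MrEstimate:
    """MR-Egger regression: weighted line with a free pleiotropy intercept.

    Exposure effects are oriented non-negative (flipping outcome effects
    jointly) before fitting, weights are ``1/se_out^2``, and standard errors
    carry the multiplicative random-effects scaling ``sqrt(max(1, Q'/(n-2)))``
    with inference on a t distribution with n-2 degrees of freedom.
    """
    h = _drop_null_exposure(h)
    if h.nsnp < 3:
        raise ValueError("MR-Egger requires at least 3 SNPs")
    x, y = _orient(h)
    w = 1.0 / h.se_out**2
    intercept, slope, cov_unscaled, rss, df = _wls_line(x, y, w)
    scale = max(1.0, rss / df)
    se_int = math.sqrt(scale * cov_unscaled[0, 0])
    se_slope = math.sqrt(scale * cov_unscaled[1, 1])
    p_slope = float(2.0 * stats.t.sf(abs(slope) / se_slope, df))
    p_int = float(2.0 * stats.t.sf(abs(intercept) / se_int, df))
    return MrEstimate(
        "egger",
        float(slope),
        se_slope,
        p_slope,
        h.nsnp,
        egger_intercept=float(intercept),
        egger_intercept_se=se_int,
        egger_intercept_p=p_int,
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Cumulative-weight-midpoint weighted median with linear interpolation."""
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, v))


def _weighted_median_rows(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise weighted medians for (n_boot, n_snp) matrices."""
    order = np.argsort(values, axis=1)
    v = np.take_along_axis(values, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    s = (np.cumsum(w, axis=1) - 0.5 * w) / np.sum(w, axis=1, keepdims=True)
    out = np.empty(values.shape[0])
    for i in range(values.shape[0]):
        out[i] = np.interp(0.5, s[i], v[i])
    return out


def weighted_median(
    h: HarmonizedSet, n_boot: int = 1000, seed: int = 0
) -> MrEstimate:
    """Weighted-median causal estimate with a parametric-bootstrap SE.

    Per-SNP Wald ratios are ordered and the estimate is the ratio at which
    the cumulative normalized weight (``beta_exp^2/se_out^2``, midpoint
    convention) crosses 1/2, with linear interpolation between the
    bracketing SNPs.  The SE resamples per-SNP exposure and outcome effects
    from their Gaussians ``n_boot`` times (seeded).
    """
    h = _drop_null_exposure(h)
    if h.nsnp < 3:
        raise ValueError("weighted_median requires at least 3 SNPs")
    ratios = h.beta_out / h.beta_exp
    w = h.beta_exp**2 / h.se_out**2
    beta = _weighted_median(ratios, w)

    rng = np.random.default_rng(seed)
    be = h.beta_exp + h.se_exp * rng.standard_normal((n_boot, h.nsnp))
    bo = h.beta_out + h.se_out * rng.standard_normal((n_boot, h.nsnp))
    be = np.where(be == 0, np.finfo(float).tiny, be)
    boot = _weighted_median_rows(bo / be, be**2 / h.se_out**2)
    se = float(np.std(boot, ddof=1))
    return MrEstimate("weighted_median", beta, se, _gauss_p(beta, se), h.nsnp)


def estimate_all(
    h: HarmonizedSet,
    ivw_model: str = "multiplicative_random",
    n_boot: int = 1000,
    seed: int = 0,
) -> dict[str, MrEstimate]:
    """Every estimator applicable at the available instrument count."""
    if h.nsnp == 1:
        return {"wald_ratio": wald_ratio(h)}
    out = {"ivw": ivw(h, model=ivw_model)}
    if h.nsnp >= 3:
        out["egger"] = egger(h)
        out["weighted_median"] = weighted_median(h, n_boot=n_boot, seed=seed)
    return out
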