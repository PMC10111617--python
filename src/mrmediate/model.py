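"""Model/Results interface over the MR estimators and the mediation step.

:class:`MRModel` is constructed from harmonized per-SNP effects (or
directly from arrays / a DataFrame); ``fit()`` returns an
:class:`MRResults` carrying the causal estimate, its uncertainty and a
``summary()`` table.  :class:`MediationModel` combines three fitted
results into the mediation decomposition.

>>> model = MRModel.from_arrays(beta_exp, se_exp, beta_out, se_out)
>>> res = model.fit(method="ivw")
>>> print(res.summary())
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .estimators import MrEstimate, estimate_all, egger, ivw, wald_ratio, weighted_median
from .mediation import MediationResult, decompose, with_uncertainty
from .sensitivity import SensitivityReport, sensitivity_report
from .summary_data import HarmonizedSet


class MRModel:
    """Two-sample MR model over one harmonized exposure/outcome SNP set."""

    def __init__(self, data: HarmonizedSet):
        self.data = data

    @classmethod
    def from_arrays(
        cls,
        beta_exp: Sequence[float],
        se_exp: Sequence[float],
        beta_out: Sequence[float],
        se_out: Sequence[float],
        snp_ids: Sequence[str] | None = None,
    ) -> "MRModel":
        n = len(beta_exp)
        ids = list(snp_ids) if snp_ids is not None else [f"snp{i+1}" for i in range(n)]
        return cls(
            HarmonizedSet(
                snp_ids=ids,
                beta_exp=np.asarray(beta_exp, dtype=float),
                se_exp=np.asarray(se_exp, dtype=float),
                beta_out=np.asarray(beta_out, dtype=float),
                se_out=np.asarray(se_out, dtype=float),
            )
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        beta_exp: str = "beta_exp",
        se_exp: str = "se_exp",
        beta_out: str = "beta_out",
        se_out: str = "se_out",
        snp_id: str | None = "snp_id",
    ) -> "MRModel":
        ids = df[snp_id].astype(str).tolist() if snp_id in df.columns else None
        return cls.from_arrays(
            df[beta_exp], df[se_exp], df[beta_out], df[se_out], snp_ids=ids
        )

    @property
    def nsnp(self) -> int:
        return self.data.nsnp

    def fit(self, method: str = "ivw", **kwargs) -> "MRResults":
        """Fit one estimator: ivw, egger, weighted_median or wald_ratio."""
        fitters = {
            "ivw": ivw,
            "egger": egger,
            "weighted_median": weighted_median,
            "wald_ratio": wald_ratio,
        }
        if method not in fitters:
            raise ValueError(f"unknown method {method!r}; choose from {sorted(fitters)}")
        return MRResults(self, fitters[method](self.data, **kwargs))

    def fit_all(self, **kwargs) -> dict[str, "MRResults"]:
        """Every estimator applicable at the available instrument count."""
        return {
            name: MRResults(self, est)
            for name, est in estimate_all(self.data, **kwargs).items()
        }

    def sensitivity(self, n_sim: int = 1000, seed: int = 0, **kw) -> SensitivityReport:
        """Heterogeneity and pleiotropy diagnostics for this instrument set."""
        return sensitivity_report(self.data, n_sim=n_sim, seed=seed, **kw)


class MRResults:
    """A fitted causal estimate with OR/CI accessors and a summary table."""

    def __init__(self, model: MRModel, estimate: MrEstimate):
        self.model = model
        self.estimate = estimate

    # statsmodels-flavoured accessors
    @property
    def beta(self) -> float:
        return self.estimate.beta

    @property
    def bse(self) -> float:
        return self.estimate.se

    @property
    def pvalue(self) -> float:
        return self.estimate.pval

    @property
    def odds_ratio(self) -> float:
        return self.estimate.or_

    def conf_int(self) -> tuple[float, float]:
        return (self.estimate.ci_low, self.estimate.ci_high)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.estimate.to_dict()])

    def summary(self) -> str:
        e = self.estimate
        lines = [
            "Two-sample Mendelian randomization",
            "==================================",
            f"method:        {e.method}",
            f"instruments:   {e.n_snp}",
            f"beta (log-OR): {e.beta:+.4f} (se {e.se:.4f})",
            f"OR [95% CI]:   {e.or_:.3f} [{e.ci_low:.3f}, {e.ci_high:.3f}]",
            f"p-value:       {e.pval:.3g}",
        ]
        if e.egger_intercept is not None:
            lines.append(
                f"intercept:     {e.egger_intercept:+.4g} "
                f"(se {e.egger_intercept_se:.3g}, p {e.egger_intercept_p:.3g})"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        e = self.estimate
        return f"<MRResults {e.method}: OR={e.or_:.3f}, p={e.pval:.3g}, nsnp={e.n_snp}>"


class MediationModel:
    """Two-step mediation decomposition over three fitted MR estimates."""

    def __init__(self, total, step1, step2):
        self.total = getattr(total, "estimate", total)
        self.step1 = getattr(step1, "estimate", step1)
        self.step2 = getattr(step2, "estimate", step2)

    def fit(
        self, se_method: str = "delta", n_boot: int = 5000, seed: int = 0
    ) -> "MediationResults":
        result = decompose(self.total, self.step1, self.step2)
        if se_method != "none":
            result = with_uncertainty(
                result, self.step1, self.step2,
                method=se_method, n_boot=n_boot, seed=seed,
            )
        return MediationResults(self, result)


class MediationResults:
    def __init__(self, model: MediationModel, result: MediationResult):
        self.model = model
        self.result = result

    @property
    def proportion_mediated(self) -> float | None:
        return self.result.proportion_mediated

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.result.to_dict()])

    def summary(self) -> str:
        r = self.result
        prop = (
            "undefined"
            if r.proportion_mediated is None
            else f"{100 * r.proportion_mediated:.2f}%"
        )
        lines = [
            "Two-step MR mediation decomposition (log-OR scale)",
            "==================================================",
            f"total effect (c):        {r.total_effect:+.4f}",
            f"exposure->mediator (a):  {r.step1_effect:+.4f}",
            f"mediator->outcome (b):   {r.step2_effect:+.4f}",
            f"mediated effect (a*b):   {r.mediated_effect:+.4f}",
            f"direct effect (c - a*b): {r.direct_effect:+.4f}",
            f"proportion mediated:     {prop}",
        ]
        if r.se_mediated is not None:
            lines.append(
                f"mediated se ({r.method_se}):     {r.se_mediated:.4f}"
            )
        return "\n".join(lines)
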