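"""Two-step MR mediation decomposition (product of coefficients).

Given three MR estimates on the log-OR scale — the total effect ``c`` of
the exposure on the outcome, the effect ``a`` of the exposure on the
mediator (step 1), and the effect ``b`` of the mediator on the outcome
(step 2) — the mediated (indirect) effect is ``a*b``, the direct effect is
``c - a*b``, and the proportion mediated is ``a*b / c``.  All arithmetic is
carried at full precision; rounding happens only at reporting.

Candidate mediators are screened before decomposition: only mediators with
a significant mediator-to-outcome effect proceed (:func:`screen_mediators`,
strict ``p < alpha``).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Iterable, Mapping

import numpy as np

from .estimators import Z95, MrEstimate


def _beta(effect) -> float:
    """Accept an MrEstimate (its ``beta``) or a bare log-scale float."""
    return float(getattr(effect, "beta", effect))


def _se(effect) -> float:
    return float(getattr(effect, "se", 0.0))


@dataclasses.dataclass
class MediationResult:
    """Total/mediated/direct effects and the proportion mediated.

    Invariants ``mediated + direct == total`` and
    ``proportion * total == mediated`` hold to machine precision by
    construction (direct and proportion are derived, never re-estimated).
    """

    total_effect: float
    step1_effect: float
    step2_effect: float
    mediated_effect: float
    direct_effect: float
    proportion_mediated: float | None
    se_mediated: float | None = None
    ci_mediated: tuple[float, float] | None = None
    method_se: str = "none"

    def to_dict(self) -> dict:
        return {
            "total_effect": self.total_effect,
            "step1_effect": self.step1_effect,
            "step2_effect": self.step2_effect,
            "mediated_effect": self.mediated_effect,
            "direct_effect": self.direct_effect,
            "proportion_mediated": self.proportion_mediated,
            "proportion_mediated_pct": (
                None
                if self.proportion_mediated is None
                else 100.0 * self.proportion_mediated
            ),
            "se_mediated": self.se_mediated,
            "ci_mediated": list(self.ci_mediated) if self.ci_mediated else None,
            "method_se": self.method_se,
        }


def decompose(total, step1, step2) -> MediationResult:
    """Product-of-coefficients decomposition on the log-OR scale.

    ``total``, ``step1`` and ``step2`` may be :class:`MrEstimate` objects or
    bare log-scale effects.  When the total effect is exactly zero the
    proportion mediated is reported missing (with a warning); mediated and
    direct effects are still computed.
    """
    c = _beta(total)
    a = _beta(step1)
    b = _beta(step2)
    mediated = a * b
    direct = c - mediated
    if c == 0.0:
        warnings.warn(
            "total effect is zero; proportion mediated undefined", stacklevel=2
        )
        proportion = None
    else:
        proportion = mediated / c
    return MediationResult(
        total_effect=c,
        step1_effect=a,
        step2_effect=b,
        mediated_effect=mediated,
        direct_effect=direct,
        proportion_mediated=proportion,
    )


def mediated_se(
    step1,
    step2,
    method: str = "delta",
    n_boot: int = 5000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Standard error and 95% CI for the mediated effect ``a*b``.

    ``delta``: Sobel-type ``sqrt(b^2 se_a^2 + a^2 se_b^2)`` with a Gaussian
    CI.  ``bootstrap``: resample (a, b) from independent Gaussians; SE from
    the sample of products, CI from its 2.5/97.5 percentiles.
    """
    a, b = _beta(step1), _beta(step2)
    se_a, se_b = _se(step1), _se(step2)
    if se_a < 0 or se_b < 0:
        raise ValueError("standard errors must be non-negative")
    if method == "delta":
        se = math.sqrt(b**2 * se_a**2 + a**2 * se_b**2)
        return se, (a * b - Z95 * se, a * b + Z95 * se)
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        prod = (a + se_a * rng.standard_normal(n_boot)) * (
            b + se_b * rng.standard_normal(n_boot)
        )
        se = float(np.std(prod, ddof=1))
        lo, hi = np.percentile(prod, [2.5, 97.5])
        return se, (float(lo), float(hi))
    raise ValueError(f"unknown method {method!r}")


def with_uncertainty(
    result: MediationResult,
    step1,
    step2,
    method: str = "delta",
    n_boot: int = 5000,
    seed: int = 0,
) -> MediationResult:
    """Return a copy of ``result`` carrying the mediated-effect SE and CI."""
    se, ci = mediated_se(step1, step2, method=method, n_boot=n_boot, seed=seed)
    return dataclasses.replace(
        result, se_mediated=se, ci_mediated=ci, method_se=method
    )


def screen_mediators(
    candidates: Iterable[tuple[str, MrEstimate]] | Mapping[str, MrEstimate],
    alpha: float = 0.05,
) -> list[str]:
    """Mediators whose mediator-to-outcome effect has ``p`` strictly < alpha.

    Candidates failing the screen do not proceed to decomposition; the
    strict inequality excludes boundary cases with p exactly equal to
    alpha.
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    items = candidates.items() if isinstance(candidates, Mapping) else candidates
    return [name for name, est in items if est.pval < alpha or alpha == 1.0]
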