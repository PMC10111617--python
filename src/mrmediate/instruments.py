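"""Instrument-variable selection and quality control.

A valid genetic instrument must be (i) robustly associated with the
exposure, (ii) independent of the other retained instruments, (iii) strong
enough that weak-instrument bias is negligible, and (iv) upstream of the
outcome rather than downstream.  These translate into four mechanical
filters applied in sequence:

* genome-wide significance thresholding (:func:`select_by_pvalue`, default
  p < 5e-8, relaxed to 1e-5 for traits with few hits),
* greedy LD clumping at r^2 < 0.001 (:func:`clump`),
* per-instrument F statistics with the conventional F > 10 floor
  (:func:`f_statistic`),
* Steiger direction filtering, removing SNPs that explain more variance in
  the outcome than in the exposure (:func:`steiger_filter`).
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .summary_data import HarmonizedSet, SnpRecord

logger = logging.getLogger(__name__)

RELAXED_THRESHOLD = 1e-5


@dataclasses.dataclass
class LdMatrix:
    """Pairwise LD *correlations* (r, not r^2) for a set of SNPs."""

    snp_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.snp_ids)
        if self.r.shape != (k, k):
            raise ValueError("LD matrix must be square and match snp_ids")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("LD matrix must have a unit diagonal")
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise ValueError("LD correlations must lie in [-1, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def r2(self, a: str, b: str) -> float:
        """r^2 between two SNPs; SNPs absent from the matrix are independent."""
        ia = self._index.get(a)
        ib = self._index.get(b)
        if ia is None or ib is None:
            return 0.0
        return float(self.r[ia, ib] ** 2)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LdMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(snp_ids=[str(s) for s in df.index], r=df.to_numpy(dtype=float))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.r, index=self.snp_ids, columns=self.snp_ids).to_csv(
            path, sep="\t", float_format="%.6g"
        )


@dataclasses.dataclass
class InstrumentSet:
    """Retained instruments with their strength statistics and provenance."""

    records: list[SnpRecord]
    f_stats: np.ndarray
    provenance: dict
    r2_exposure: np.ndarray | None = None
    r2_outcome: np.ndarray | None = None

    @property
    def f_range(self) -> tuple[float, float]:
        return (float(np.min(self.f_stats)), float(np.max(self.f_stats)))

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]


def select_by_pvalue(
    records: Sequence[SnpRecord], threshold: float
) -> list[SnpRecord]:
    """Keep exactly the records with ``pval`` strictly below ``threshold``."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    kept = [r for r in records if r.pval < threshold or threshold == 1.0]
    if not kept:
        raise ValueError(
            f"no SNP passes p < {threshold:g}; consider the relaxed threshold "
            f"{RELAXED_THRESHOLD:g} used for traits with few instruments"
        )
    return kept


def clump(
    records: Sequence[SnpRecord],
    ld: LdMatrix | None,
    r2_threshold: float = 0.001,
    window_kb: int = 10_000,
) -> list[SnpRecord]:
    """Greedy LD clumping.

    SNPs are visited in order of ascending p-value (ties broken by lexical
    ``snp_id``, which makes the output invariant to input row order).  A SNP
    is accepted unless it lies within ``window_kb`` of an already accepted
    SNP on the same chromosome with r^2 at or above ``r2_threshold``.  SNPs
    absent from ``ld`` (or all SNPs when ``ld`` is None) are treated as
    independent.
    """
    if ld is not None:
        missing = [r.snp_id for r in records if r.snp_id not in ld]
        if missing:
            logger.info(
                "clump: %d SNP(s) absent from the LD matrix treated as independent",
                len(missing),
            )
    window_bp = int(window_kb) * 1000
    ordered = sorted(records, key=lambda r: (r.pval, r.snp_id))
    accepted: list[SnpRecord] = []
    for rec in ordered:
        pruned = False
        for acc in accepted:
            if rec.chrom != acc.chrom or abs(rec.pos - acc.pos) > window_bp:
                continue
            r2 = ld.r2(rec.snp_id, acc.snp_id) if ld is not None else 0.0
            if r2 >= r2_threshold:
                pruned = True
                break
        if not pruned:
            accepted.append(rec)
    return accepted


def f_statistic(record: SnpRecord) -> float:
    """Per-instrument approximate first-stage F, ``(beta/se)^2``.

    Algebraically identical to ``(n-2) R^2 / (1-R^2)`` with
    ``R^2 = t^2 / (t^2 + n - 2)``, the single-regressor identity.
    """
    return float((record.beta / record.se) ** 2)


def f_statistic_from_r2(record: SnpRecord) -> float:
    """Exact R^2-based F, available when ``eaf`` and ``n`` are present.

    Uses the standardized-trait variance explained ``R^2 = 2 p (1-p) beta^2``
    and ``F = R^2 (n-2) / (1-R^2)``.  Requires ``beta`` in trait-SD units.
    """
    if record.eaf is None or record.n is None:
        raise ValueError(f"{record.snp_id}: eaf and n required for the R^2-based F")
    r2 = 2.0 * record.eaf * (1.0 - record.eaf) * record.beta**2
    if not (0 <= r2 < 1):
        raise ValueError(f"{record.snp_id}: implied R^2 {r2:.3g} outside [0, 1)")
    return float((record.n - 2) * r2 / (1.0 - r2))


def variance_explained(t: np.ndarray, n: float) -> np.ndarray:
    """Variance in a trait explained by one SNP, ``r^2 = t^2 / (t^2 + n - 2)``."""
    t2 = np.asarray(t, dtype=float) ** 2
    return t2 / (t2 + n - 2.0)


def steiger_table(h: HarmonizedSet, n_exp: float, n_out: float) -> pd.DataFrame:
    """Per-SNP Steiger directionality statistics.

    Variance explained in each trait is computed from the z score and the
    sample size; the direction test compares the two (Fisher-transformed)
    correlations with a two-sided z test.
    """
    if n_exp <= 3 or n_out <= 3:
        raise ValueError("sample sizes must exceed 3 for the Steiger test")
    r2_exp = variance_explained(h.beta_exp / h.se_exp, n_exp)
    r2_out = variance_explained(h.beta_out / h.se_out, n_out)
    z = (np.arctanh(np.sqrt(r2_exp)) - np.arctanh(np.sqrt(r2_out))) / np.sqrt(
        1.0 / (n_exp - 3.0) + 1.0 / (n_out - 3.0)
    )
    pval = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "snp_id": h.snp_ids,
            "r2_exposure": r2_exp,
            "r2_outcome": r2_out,
            "steiger_z": z,
            "steiger_p": pval,
        }
    )


def steiger_filter(
    h: HarmonizedSet, n_exp: float, n_out: float, alpha: float = 0.05
) -> HarmonizedSet:
    """Remove SNPs whose association points from outcome to exposure.

    A SNP is retained when it explains more variance in the exposure than in
    the outcome and the direction is either unambiguous (zero outcome
    signal) or significant at ``alpha`` under the Fisher z test.
    """
    table = steiger_table(h, n_exp, n_out)
    correct = table["r2_exposure"].to_numpy() > table["r2_outcome"].to_numpy()
    decided = (table["steiger_p"].to_numpy() < alpha) | (
        table["r2_outcome"].to_numpy() == 0.0
    )
    keep = correct & decided
    removed = [s for s, k in zip(h.snp_ids, keep) if not k]
    if removed:
        logger.info("steiger_filter: removed %d SNP(s): %s", len(removed), removed)
    if not keep.any():
        raise ValueError("Steiger filtering removed every SNP; no valid instruments")
    return h.subset(keep)


def build_instrument_set(
    records: Sequence[SnpRecord], provenance: dict | None = None
) -> InstrumentSet:
    f = np.array([f_statistic(r) for r in records])
    return InstrumentSet(
        records=list(records), f_stats=f, provenance=dict(provenance or {})
    )
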