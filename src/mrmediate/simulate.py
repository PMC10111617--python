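"""Synthetic GWAS summary statistics with a mediation causal structure.

The generator emulates the three-cohort, two-sample design this package
analyzes: a large continuous-exposure GWAS (vitamin-D-status scale,
~497k participants), a continuous-mediator GWAS (total-testosterone scale,
~194k), and a binary-outcome case-control GWAS (osteoporosis scale, ~6.3k
cases / ~326k controls), all over a shared SNP panel.

The causal diagram is ``G -> X -> M -> Y`` with a direct ``X -> Y`` path:

* exposure-instrument SNPs carry true effects ``gamma_j`` on X, drawn
  Normal with ``E[2 p (1-p) gamma^2] = per_snp_h2``; they reach M as
  ``a * gamma_j`` and Y as ``(a*b + c') * gamma_j``;
* mediator-instrument SNPs carry their own primary effects on M and reach
  Y as ``b * delta_j`` — these are what the mediator-to-outcome MR step
  instruments on;
* optional horizontal pleiotropy (balanced or directional), outlier SNPs
  with inflated outcome effects, reverse-causal SNPs (primary outcome
  effect with an induced exposure association), palindromic allele pairs,
  and LD blocks.

Summary statistics are generated directly on the summary level: observed
betas are the true means plus Gaussian noise with analytic standard errors
``1/sqrt(2 p (1-p) n)`` (continuous traits) and
``1/sqrt(2 p (1-p) n phi (1-phi))`` on the log-OR scale for the
case-control outcome with case fraction ``phi``.  All randomness flows
from a single mandatory seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .instruments import LdMatrix
from .summary_data import SnpRecord, read_summary_stats, write_summary_stats, _MIN_P

_NONPALINDROMIC_PAIRS = (
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
)
_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))


@dataclasses.dataclass
class PleiotropySpec:
    """Horizontal pleiotropy acting on the outcome.

    ``none``: no pleiotropy.  ``balanced``: per-SNP effects Normal(0, sd^2).
    ``directional``: ``offset`` (plus Normal(0, sd^2) jitter) applied in the
    orientation of the exposure-increasing allele, so the injected mean
    survives the sign orientation performed by MR-Egger.
    """

    mode: str = "none"
    sd: float = 0.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy mode {self.mode!r}")
        if self.sd < 0:
            raise ValueError("pleiotropy sd must be non-negative")


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions for one synthetic three-cohort dataset.

    Defaults mirror the analyzed design: 45 exposure instruments and 50
    mediator instruments at roughly 0.1% variance explained each, cohort
    sizes of 496,946 (exposure), 194,453 (mediator) and 332,020 (outcome;
    6,303 cases / 325,717 controls), a true exposure-to-mediator effect of
    0.06 SD/SD, a mediator-to-outcome log-OR of ln(1.25), and a direct
    exposure-to-outcome log-OR of 0.22 — a proportion mediated near 6%.
    """

    n_snp_causal: int = 45
    n_snp_causal_mediator: int = 50
    n_snp_null: int = 255
    n_exp: int = 496_946
    n_med: int = 194_453
    n_out: int = 332_020
    n_case: int = 6_303
    n_control: int = 325_717
    beta_xm: float = 0.06
    beta_my: float = math.log(1.25)
    beta_xy_direct: float = 0.22
    maf_range: tuple[float, float] = (0.05, 0.5)
    per_snp_h2: float = 0.001
    pleiotropy: PleiotropySpec = dataclasses.field(default_factory=PleiotropySpec)
    n_outlier_snps: int = 0
    outlier_scale: float = 0.0
    frac_palindromic: float = 0.0
    ld_blocks: tuple[tuple[int, float], ...] = ()
    reverse_causal_snps: int = 0
    reverse_r2_ratio: float = 5.0
    seed: int = dataclasses.field(kw_only=True)

    def __post_init__(self) -> None:
        if isinstance(self.pleiotropy, dict):
            self.pleiotropy = PleiotropySpec(**self.pleiotropy)
        self.ld_blocks = tuple(tuple(b) for b in self.ld_blocks)
        for name in ("n_exp", "n_med", "n_out"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be at least 2")
        if self.n_case + self.n_control != self.n_out:
            raise ValueError("n_case + n_control must equal n_out")
        if not (0 < self.per_snp_h2 < 1):
            raise ValueError("per_snp_h2 must lie in (0, 1)")
        if not (0 <= self.frac_palindromic <= 1):
            raise ValueError("frac_palindromic must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for size, r2 in self.ld_blocks:
            if size < 2 or not (0 < r2 <= 1):
                raise ValueError("ld_blocks entries must be (size>=2, r2 in (0,1])")
        if len(self.ld_blocks) > self.n_snp_causal:
            raise ValueError("more LD blocks than exposure-causal tag SNPs")
        if min(self.n_snp_causal, self.n_snp_causal_mediator, self.n_snp_null,
               self.n_outlier_snps, self.reverse_causal_snps) < 0:
            raise ValueError("SNP counts must be non-negative")
        if self.n_outlier_snps > self.n_snp_causal:
            raise ValueError("n_outlier_snps exceeds n_snp_causal")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclasses.dataclass
class Truth:
    """Ground truth of one simulated study."""

    a: float
    b: float
    c_direct: float
    c_total: float
    proportion_mediated: float
    outlier_ids: list[str]
    reverse_causal_ids: list[str]
    palindromic_ids: list[str]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class SyntheticStudy:
    exposure_stats: list[SnpRecord]
    mediator_stats: list[SnpRecord]
    outcome_stats: list[SnpRecord]
    ld: LdMatrix
    truth: Truth
    config: SimulationConfig


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return np.maximum(2.0 * stats.norm.sf(np.abs(beta) / se), _MIN_P)


def simulate(config: SimulationConfig) -> SyntheticStudy:
    """Draw one synthetic study under ``config`` (deterministic per seed)."""
    rng = np.random.default_rng(config.seed)
    a = config.beta_xm
    b = config.beta_my
    c_direct = config.beta_xy_direct
    c_total = a * b + c_direct
    phi = config.n_case / config.n_out

    # --- SNP roles ----------------------------------------------------------
    n_exp_causal = config.n_snp_causal
    n_med_causal = config.n_snp_causal_mediator
    n_rev = config.reverse_causal_snps
    n_null = config.n_snp_null
    n_extra = sum(size - 1 for size, _ in config.ld_blocks)
    n_total = n_exp_causal + n_med_causal + n_rev + n_null + n_extra

    maf = rng.uniform(*config.maf_range, size=n_total)
    v = 2.0 * maf * (1.0 - maf)

    gamma = np.zeros(n_total)        # true effect on X
    delta_m = np.zeros(n_total)      # primary effect on M
    delta_y = np.zeros(n_total)      # primary effect on Y (reverse-causal)

    i_exp = np.arange(0, n_exp_causal)
    i_med = np.arange(n_exp_causal, n_exp_causal + n_med_causal)
    i_rev = np.arange(n_exp_causal + n_med_causal, n_exp_causal + n_med_causal + n_rev)
    gamma[i_exp] = rng.normal(0.0, np.sqrt(config.per_snp_h2 / v[i_exp]))
    delta_m[i_med] = rng.normal(0.0, np.sqrt(config.per_snp_h2 / v[i_med]))
    if n_rev:
        # primary outcome effect sized so the Steiger outcome r^2 is
        # reverse_r2_ratio times an instrument's exposure r^2; the induced
        # exposure association mimics a genuine instrument so the SNP
        # passes selection and only direction filtering can remove it
        sign = rng.choice([-1.0, 1.0], size=n_rev)
        delta_y[i_rev] = sign * np.sqrt(
            config.reverse_r2_ratio * config.per_snp_h2 / (v[i_rev] * phi * (1 - phi))
        )
        gamma[i_rev] = sign * np.sqrt(config.per_snp_h2 / v[i_rev])

    # --- pleiotropy and outliers -------------------------------------------
    pleio_y = np.zeros(n_total)
    spec = config.pleiotropy
    if spec.mode == "balanced":
        pleio_y[i_exp] = rng.normal(0.0, spec.sd, size=n_exp_causal)
    elif spec.mode == "directional":
        orient = np.where(gamma[i_exp] < 0, -1.0, 1.0)
        pleio_y[i_exp] = orient * (
            spec.offset + rng.normal(0.0, spec.sd, size=n_exp_causal)
        )

    se_y_all = 1.0 / np.sqrt(v * config.n_out * phi * (1 - phi))
    outlier_idx = np.array([], dtype=int)
    if config.n_outlier_snps:
        outlier_idx = rng.choice(i_exp, size=config.n_outlier_snps, replace=False)
        pleio_y[outlier_idx] += (
            rng.choice([-1.0, 1.0], size=config.n_outlier_snps)
            * config.outlier_scale
            * se_y_all[outlier_idx]
        )

    # --- true summary-level means ------------------------------------------
    mean_x = gamma.copy()
    mean_m = a * gamma + delta_m
    mean_y = c_total * gamma + b * delta_m + delta_y + pleio_y
    # reverse-causal SNPs: the induced X association is downstream of Y, so
    # it does not propagate through the X -> M -> Y paths
    if n_rev:
        mean_m[i_rev] = 0.0
        mean_y[i_rev] = delta_y[i_rev]

    # --- LD blocks: correlated duplicates of exposure-causal tags ----------
    block_members: list[tuple[int, int, float]] = []  # (member_idx, tag_idx, loading)
    next_idx = n_exp_causal + n_med_causal + n_rev + n_null
    for tag_idx, (size, within_r2) in enumerate(config.ld_blocks):
        loading = math.sqrt(within_r2)
        for _ in range(size - 1):
            m = next_idx
            next_idx += 1
            maf[m] = maf[tag_idx]
            v[m] = v[tag_idx]
            mean_x[m] = loading * mean_x[tag_idx]
            mean_m[m] = loading * mean_m[tag_idx]
            mean_y[m] = loading * mean_y[tag_idx]
            block_members.append((m, tag_idx, loading))

    # --- observed effects: mean + correlated sampling noise -----------------
    se_x = 1.0 / np.sqrt(v * config.n_exp)
    se_m = 1.0 / np.sqrt(v * config.n_med)
    se_y = 1.0 / np.sqrt(v * config.n_out * phi * (1 - phi))

    z = rng.standard_normal((3, n_total))
    for m, t, loading in block_members:
        eps = rng.standard_normal(3)
        z[:, m] = loading * z[:, t] + math.sqrt(1.0 - loading**2) * eps
    beta_x = mean_x + se_x * z[0]
    beta_m = mean_m + se_m * z[1]
    beta_y = mean_y + se_y * z[2]

    # --- alleles, coordinates, identifiers ----------------------------------
    palindromic = rng.random(n_total) < config.frac_palindromic
    alleles = np.empty((n_total, 2), dtype=object)
    for i in range(n_total):
        pool = _PALINDROMIC_PAIRS if palindromic[i] else _NONPALINDROMIC_PAIRS
        alleles[i] = pool[rng.integers(len(pool))]

    snp_ids = [f"rs{i + 1}" for i in range(n_total)]
    chroms = [str((i % 22) + 1) for i in range(n_total)]
    positions = [10_000_000 + (i // 22) * 500_000 for i in range(n_total)]
    for m, t, _ in block_members:
        chroms[m] = chroms[t]
        positions[m] = positions[t] + (m - t) % 1000 + 1  # adjacent to the tag

    def records(beta, se, n) -> list[SnpRecord]:
        p = _pvals(beta, se)
        return [
            SnpRecord(
                snp_id=snp_ids[i],
                chrom=chroms[i],
                pos=positions[i],
                effect_allele=alleles[i][0],
                other_allele=alleles[i][1],
                eaf=float(maf[i]),
                beta=float(beta[i]),
                se=float(se[i]),
                pval=float(p[i]),
                n=int(n),
            )
            for i in range(n_total)
        ]

    r = np.eye(n_total)
    for m, t, loading in block_members:
        r[m, t] = r[t, m] = loading
    for m1, t1, l1 in block_members:
        for m2, t2, l2 in block_members:
            if m1 != m2 and t1 == t2:
                r[m1, m2] = l1 * l2

    truth = Truth(
        a=a,
        b=b,
        c_direct=c_direct,
        c_total=c_total,
        proportion_mediated=(a * b / c_total) if c_total != 0 else math.nan,
        outlier_ids=[snp_ids[i] for i in sorted(outlier_idx)],
        reverse_causal_ids=[snp_ids[i] for i in i_rev],
        palindromic_ids=[snp_ids[i] for i in np.flatnonzero(palindromic)],
    )
    return SyntheticStudy(
        exposure_stats=records(beta_x, se_x, config.n_exp),
        mediator_stats=records(beta_m, se_m, config.n_med),
        outcome_stats=records(beta_y, se_y, config.n_out),
        ld=LdMatrix(snp_ids=snp_ids, r=r),
        truth=truth,
        config=config,
    )


def write_study(study: SyntheticStudy, directory: str | Path) -> None:
    """Write the three stat TSVs, the LD matrix and the truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_summary_stats(study.exposure_stats, directory / "exposure.tsv")
    write_summary_stats(study.mediator_stats, directory / "mediator.tsv")
    write_summary_stats(study.outcome_stats, directory / "outcome.tsv")
    study.ld.to_tsv(directory / "ld.tsv")
    truth = study.truth.to_dict()
    truth["config"] = _config_dict(study.config)
    with open(directory / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _config_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["ld_blocks"] = [list(b) for b in config.ld_blocks]
    return d


def read_study(directory: str | Path) -> dict[str, list[SnpRecord]]:
    """Re-read the three stat tables written by :func:`write_study`."""
    directory = Path(directory)
    return {
        name: read_summary_stats(directory / f"{name}.tsv")
        for name in ("exposure", "mediator", "outcome")
    }
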