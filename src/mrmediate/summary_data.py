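"""GWAS summary statistics: per-SNP records, TSV I/O and allele harmonization.

Two-sample Mendelian randomization works entirely from published per-SNP
association results.  Each trait contributes one table with, per SNP, the
effect allele, the other allele, the additive effect estimate ``beta`` (a
log odds ratio for binary traits), its standard error, a p-value and,
optionally, the effect-allele frequency and the GWAS sample size.

Before any causal estimate can be formed, the exposure and outcome tables
must be expressed for a *common* effect allele per SNP.  :func:`harmonize`
aligns the two tables, flipping outcome effect signs where the allele
labels are swapped, resolving strand flips by complementing, and deleting
palindromic (A/T and C/G) SNPs whose strand cannot be resolved from the
allele labels alone.
"""

from __future__ import annotations

import dataclasses
import gzip
import logging
import math
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical field name -> column header of the canonical TSV dialect
CANONICAL_HEADER: dict[str, str] = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pval": "P",
    "n": "N",
}

MANDATORY_FIELDS = ("snp_id", "effect_allele", "other_allele", "beta", "se", "pval")

# smallest p-value we carry; avoids 0.0 from extreme z underflow
_MIN_P = 1e-320


def gaussian_pvalue(beta: float, se: float) -> float:
    """Two-sided Gaussian tail probability of ``beta/se``, floored away from 0."""
    return float(max(2.0 * stats.norm.sf(abs(beta) / se), _MIN_P))


def is_palindromic(a1: str, a2: str) -> bool:
    """A/T and C/G allele pairs are strand-ambiguous."""
    return COMPLEMENT.get(a1) == a2


@dataclasses.dataclass
class SnpRecord:
    """One SNP's summary association for one trait.

    ``beta`` is on the trait scale (log-OR for binary traits); ``se`` must be
    strictly positive; ``pval`` lies in (0, 1].  ``eaf`` and ``n`` may be
    missing (``None``).  Coordinates are 1-based; ``chrom`` is a string so
    that "X" is admissible.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: str = "0"
    pos: int = 0
    eaf: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        self.effect_allele = self.effect_allele.upper()
        self.other_allele = self.other_allele.upper()
        for allele in (self.effect_allele, self.other_allele):
            if allele not in VALID_ALLELES:
                raise ValueError(f"{self.snp_id}: invalid allele {allele!r} (SNPs only)")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if not self.se > 0:
            raise ValueError(f"{self.snp_id}: se must be positive, got {self.se}")
        if not (0 < self.pval <= 1):
            raise ValueError(f"{self.snp_id}: pval must be in (0, 1], got {self.pval}")
        if self.pos < 0:
            raise ValueError(f"{self.snp_id}: position must be non-negative")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValueError(f"{self.snp_id}: eaf must be in [0, 1]")
        if self.n is not None and self.n <= 0:
            raise ValueError(f"{self.snp_id}: n must be positive")
        self._check_p_consistency()

    def _check_p_consistency(self) -> None:
        # warn (never reject) if the p-value is far from the Gaussian tail of beta/se
        z_obs = abs(self.beta) / self.se
        # near the smallest representable p the Gaussian tail saturates
        if self.pval >= 1.0 or self.pval <= 1e-300 or z_obs == 0.0:
            return
        z_imp = stats.norm.isf(self.pval / 2.0)
        if not math.isfinite(z_imp):
            return
        if abs(z_imp - z_obs) > 0.5 + 0.1 * z_obs:
            logger.warning(
                "%s: p-value %.3g inconsistent with |beta/se|=%.3g under the "
                "Gaussian approximation", self.snp_id, self.pval, z_obs,
            )

    @property
    def palindromic(self) -> bool:
        return is_palindromic(self.effect_allele, self.other_allele)


@dataclasses.dataclass
class HarmonizedSet:
    """Exposure/outcome effect pairs aligned to one effect allele per SNP."""

    snp_ids: list[str]
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    n_dropped_palindromic: int = 0
    n_flipped: int = 0

    def __post_init__(self) -> None:
        for field in ("beta_exp", "se_exp", "beta_out", "se_out"):
            setattr(self, field, np.asarray(getattr(self, field), dtype=float))
        lengths = {len(self.snp_ids)} | {
            arr.shape[0]
            for arr in (self.beta_exp, self.se_exp, self.beta_out, self.se_out)
        }
        if len(lengths) != 1:
            raise ValueError("harmonized vectors must share one length")
        if self.nsnp < 1:
            raise ValueError("a harmonized set needs at least one SNP")
        if not (np.all(self.se_exp > 0) and np.all(self.se_out > 0)):
            raise ValueError("standard errors must be strictly positive")

    @property
    def nsnp(self) -> int:
        return len(self.snp_ids)

    def subset(self, mask: np.ndarray | Sequence[bool]) -> "HarmonizedSet":
        mask = np.asarray(mask, dtype=bool)
        return HarmonizedSet(
            snp_ids=[s for s, keep in zip(self.snp_ids, mask) if keep],
            beta_exp=self.beta_exp[mask],
            se_exp=self.se_exp[mask],
            beta_out=self.beta_out[mask],
            se_out=self.se_out[mask],
            n_dropped_palindromic=self.n_dropped_palindromic,
            n_flipped=self.n_flipped,
        )


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "r")


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[SnpRecord]:
    """Read a tab- or comma-separated summary-statistics table.

    ``column_map`` maps canonical field names (``snp_id``, ``effect_allele``,
    ``other_allele``, ``beta``, ``se``, ``pval``, and optionally ``chrom``,
    ``pos``, ``eaf``, ``n``) to the headers used in the file, so UKB- or
    FinnGen-style exports can be ingested without code changes.  Gzip input
    is accepted transparently.

    Rows with unparsable ``beta``/``se``, non-positive ``se``, or non-SNP
    alleles (indels, multi-allelic codes) are rejected; the rejection count
    is logged.  A missing ``pval`` *value* is reconstituted as the two-sided
    Gaussian tail of ``beta/se``; a missing mandatory *column* is a hard
    error.
    """
    path = Path(path)
    mapping = dict(column_map) if column_map is not None else dict(CANONICAL_HEADER)

    with _open_text(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    df = pd.read_csv(
        path, sep=sep, dtype=str, na_values=["NA", "NaN", ""], keep_default_na=True
    )

    for field in MANDATORY_FIELDS:
        header = mapping.get(field)
        if header is None or header not in df.columns:
            raise ValueError(
                f"mandatory column {field!r} (header {header!r}) missing from {path}"
            )

    def col(field: str):
        header = mapping.get(field)
        return df[header] if header is not None and header in df.columns else None

    records: list[SnpRecord] = []
    n_rejected = 0
    n_reconstituted = 0
    columns = {f: col(f) for f in CANONICAL_HEADER}
    for i in range(len(df)):
        row = {f: (c.iloc[i] if c is not None else None) for f, c in columns.items()}
        try:
            beta = float(row["beta"])
            se = float(row["se"])
            if math.isnan(beta) or math.isnan(se):
                raise ValueError("missing beta/se")
            pval_raw = row["pval"]
            if pval_raw is None or (isinstance(pval_raw, float) and math.isnan(pval_raw)):
                pval = gaussian_pvalue(beta, se)
                n_reconstituted += 1
            else:
                pval = max(float(pval_raw), _MIN_P)
            eaf_raw = row["eaf"]
            eaf = None if _missing(eaf_raw) else float(eaf_raw)
            n_raw = row["n"]
            n = None if _missing(n_raw) else int(float(n_raw))
            pos_raw = row["pos"]
            pos = 0 if _missing(pos_raw) else int(float(pos_raw))
            chrom_raw = row["chrom"]
            chrom = "0" if _missing(chrom_raw) else str(chrom_raw)
            records.append(
                SnpRecord(
                    snp_id=str(row["snp_id"]),
                    effect_allele=str(row["effect_allele"]),
                    other_allele=str(row["other_allele"]),
                    beta=beta,
                    se=se,
                    pval=pval,
                    chrom=chrom,
                    pos=pos,
                    eaf=eaf,
                    n=n,
                )
            )
        except (ValueError, TypeError):
            n_rejected += 1
    if n_rejected:
        logger.info("%s: rejected %d unparsable row(s)", path.name, n_rejected)
    if n_reconstituted:
        logger.info(
            "%s: reconstituted %d missing p-value(s) from beta/se",
            path.name,
            n_reconstituted,
        )
    read_summary_stats.last_n_rejected = n_rejected  # type: ignore[attr-defined]
    return records


def _missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return False


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    value = float(value)
    if math.isnan(value):
        return "NA"
    return repr(value)


def write_summary_stats(records: Sequence[SnpRecord], path: str | Path) -> None:
    """Write records as the canonical TSV (SNP CHR POS EA OA EAF BETA SE P N).

    Missing ``eaf``/``n`` serialize as ``NA``.  Floats use shortest
    round-trip representation, so write -> read -> write is byte-identical.
    """
    if not records:
        raise ValueError("refusing to write an empty summary-statistics table")
    path = Path(path)
    lines = ["\t".join(CANONICAL_HEADER.values())]
    for r in records:
        lines.append(
            "\t".join(
                [
                    r.snp_id,
                    r.chrom,
                    str(r.pos),
                    r.effect_allele,
                    r.other_allele,
                    _fmt(r.eaf),
                    _fmt(r.beta),
                    _fmt(r.se),
                    _fmt(r.pval),
                    _fmt(r.n),
                ]
            )
        )
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("\n".join(lines) + "\n")


def harmonize(
    exposure: Sequence[SnpRecord],
    outcome: Sequence[SnpRecord],
    palindrome_policy: str = "drop",
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect alleles, SNP by SNP.

    Only SNPs present in both tables are considered (keyed by ``snp_id``,
    exposure order preserved).  For each shared SNP:

    * alleles identical -> kept as-is;
    * alleles swapped -> outcome beta sign flipped (counted in ``n_flipped``);
    * alleles on the opposite strand -> complemented, then the same logic;
    * palindromic (A/T, C/G) on either side -> dropped unconditionally;
    * irreconcilable after complementing -> dropped with a warning.
    """
    if palindrome_policy != "drop":
        raise ValueError(f"unsupported palindrome_policy {palindrome_policy!r}")
    out_by_id = {r.snp_id: r for r in outcome}
    shared = [r for r in exposure if r.snp_id in out_by_id]
    if not shared:
        raise ValueError("exposure and outcome share no SNPs; cannot harmonize")

    snp_ids: list[str] = []
    be, se_e, bo, se_o = [], [], [], []
    n_palindromic = 0
    n_flipped = 0
    for exp in shared:
        out = out_by_id[exp.snp_id]
        if exp.palindromic or out.palindromic:
            n_palindromic += 1
            continue
        pair = (out.effect_allele, out.other_allele)
        direct = (exp.effect_allele, exp.other_allele)
        swapped = (exp.other_allele, exp.effect_allele)
        comp = (COMPLEMENT[pair[0]], COMPLEMENT[pair[1]])
        if pair == direct or comp == direct:
            sign = 1.0
        elif pair == swapped or comp == swapped:
            sign = -1.0
            n_flipped += 1
        else:
            warnings.warn(
                f"{exp.snp_id}: outcome alleles {pair} irreconcilable with "
                f"exposure alleles {direct}; SNP dropped",
                stacklevel=2,
            )
            continue
        snp_ids.append(exp.snp_id)
        be.append(exp.beta)
        se_e.append(exp.se)
        bo.append(sign * out.beta)
        se_o.append(out.se)

    if not snp_ids:
        raise ValueError("no SNPs retained after harmonization")
    return HarmonizedSet(
        snp_ids=snp_ids,
        beta_exp=np.array(be),
        se_exp=np.array(se_e),
        beta_out=np.array(bo),
        se_out=np.array(se_o),
        n_dropped_palindromic=n_palindromic,
        n_flipped=n_flipped,
    )
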