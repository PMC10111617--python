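"""End-to-end orchestration of the three-step mediation MR design.

Step 1 estimates the total effect of the exposure on the outcome and the
effect of each candidate mediator on the outcome; step 2 estimates the
exposure-to-mediator effect for mediators that survive screening; step 3
combines the three estimates into the mediation decomposition.  Every
exposure-outcome analysis runs the full instrument QC chain
(p-threshold -> LD clumping -> harmonization -> F filter -> Steiger
filter), all applicable estimators, and the sensitivity diagnostics.

:func:`run_pipeline` is the file-based entry point (TSV in, JSON/TSV out);
:func:`analyze_pair` and :func:`analyze_study` are the in-memory building
blocks.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .estimators import MrEstimate, estimate_all, ivw
from .instruments import (
    LdMatrix,
    clump,
    f_statistic,
    select_by_pvalue,
    steiger_filter,
)
from .mediation import decompose, screen_mediators, with_uncertainty
from .sensitivity import funnel_data, sensitivity_report
from .simulate import SyntheticStudy
from .summary_data import HarmonizedSet, SnpRecord, harmonize, read_summary_stats

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Tunable thresholds of the analysis chain.

    ``p_threshold`` is the genome-wide instrument threshold (5e-8);
    ``p_threshold_by_trait`` overrides it per trait (e.g. 1e-5 for traits
    with few instruments).  ``clump_r2``/``clump_window_kb`` control LD
    pruning, ``f_threshold`` the weak-instrument floor, ``steiger_alpha``
    the direction test, ``screen_alpha`` the mediator screen, and the
    remaining fields the estimator/sensitivity defaults.
    """

    p_threshold: float = 5e-8
    p_threshold_by_trait: dict = dataclasses.field(default_factory=dict)
    clump_r2: float = 0.001
    clump_window_kb: int = 10_000
    f_threshold: float = 10.0
    steiger_alpha: float = 0.05
    ivw_model: str = "multiplicative_random"
    n_boot: int = 1000
    presso_n_sim: int = 1000
    presso_outlier_alpha: float = 0.05
    screen_alpha: float = 0.05
    mediated_se_method: str = "delta"

    def threshold_for(self, trait: str) -> float:
        return float(self.p_threshold_by_trait.get(trait, self.p_threshold))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclasses.dataclass
class PairAnalysis:
    """One exposure-against-outcome MR analysis with full provenance."""

    trait: str
    counts: dict
    f_range: tuple[float, float]
    harmonized: HarmonizedSet
    estimates: dict[str, MrEstimate]
    sensitivity: object  # SensitivityReport | None

    @property
    def primary(self) -> MrEstimate:
        """IVW when available, otherwise the single-SNP Wald ratio."""
        return self.estimates.get("ivw", self.estimates.get("wald_ratio"))


def _median_n(records: Sequence[SnpRecord], fallback: float | None) -> float:
    ns = [r.n for r in records if r.n is not None]
    if ns:
        return float(np.median(ns))
    if fallback is not None:
        return float(fallback)
    raise ValueError("sample size unavailable: no N column and no fallback given")


def analyze_pair(
    exposure: Sequence[SnpRecord],
    outcome: Sequence[SnpRecord],
    ld: LdMatrix | None,
    config: PipelineConfig,
    trait: str,
    seed: int = 0,
    n_exp: float | None = None,
    n_out: float | None = None,
    run_sensitivity: bool = True,
    methods: str = "all",
) -> PairAnalysis:
    """Instrument QC plus estimation for one exposure/outcome pair.

    ``methods="ivw"`` restricts estimation to IVW (used by large simulation
    sweeps); ``methods="all"`` fits every applicable estimator.
    """
    counts = {"input": len(exposure)}
    selected = select_by_pvalue(exposure, config.threshold_for(trait))
    counts["significant"] = len(selected)
    clumped = clump(selected, ld, config.clump_r2, config.clump_window_kb)
    counts["clumped"] = len(clumped)

    h = harmonize(clumped, outcome)
    counts["harmonized"] = h.nsnp
    counts["dropped_palindromic"] = h.n_dropped_palindromic
    counts["flipped"] = h.n_flipped

    f = (h.beta_exp / h.se_exp) ** 2
    strong = f > config.f_threshold
    if not strong.any():
        raise ValueError(f"{trait}: every instrument is weak (F <= {config.f_threshold})")
    h = h.subset(strong)
    f = f[strong]
    counts["strong"] = h.nsnp

    ne = _median_n([r for r in clumped], n_exp)
    no = _median_n(list(outcome), n_out)
    h = steiger_filter(h, ne, no, alpha=config.steiger_alpha)
    f = (h.beta_exp / h.se_exp) ** 2
    counts["steiger"] = h.nsnp

    if methods == "ivw":
        est = {"ivw": ivw(h, model=config.ivw_model)} if h.nsnp > 1 else estimate_all(h)
    else:
        est = estimate_all(h, ivw_model=config.ivw_model, n_boot=config.n_boot, seed=seed)
    sens = (
        sensitivity_report(
            h,
            n_sim=config.presso_n_sim,
            outlier_alpha=config.presso_outlier_alpha,
            seed=seed + 1,
        )
        if run_sensitivity
        else None
    )
    return PairAnalysis(
        trait=trait,
        counts=counts,
        f_range=(float(f.min()), float(f.max())),
        harmonized=h,
        estimates=est,
        sensitivity=sens,
    )


def _pair_dict(pa: PairAnalysis) -> dict:
    d = {
        "trait": pa.trait,
        "counts": pa.counts,
        "f_range": list(pa.f_range),
        "estimates": {k: v.to_dict() for k, v in pa.estimates.items()},
    }
    if pa.sensitivity is not None:
        d["sensitivity"] = pa.sensitivity.to_dict()
    return d


def _significance_label(pval: float, alpha: float = 0.05) -> str:
    return "potential association" if pval < alpha else "no association"


def analyze_study(
    study: SyntheticStudy,
    config: PipelineConfig | None = None,
    seed: int = 0,
    run_sensitivity: bool = True,
    methods: str = "all",
    mediator_name: str = "mediator",
    exposure_name: str = "exposure",
) -> dict:
    """Run the full three-step analysis on an in-memory synthetic study."""
    config = config or PipelineConfig()
    return _run(
        exposure=(exposure_name, study.exposure_stats),
        mediators={mediator_name: study.mediator_stats},
        outcome=study.outcome_stats,
        ld=study.ld,
        config=config,
        seed=seed,
        run_sensitivity=run_sensitivity,
        methods=methods,
    )


def _run(
    exposure: tuple[str, Sequence[SnpRecord]],
    mediators: Mapping[str, Sequence[SnpRecord]],
    outcome: Sequence[SnpRecord],
    ld: LdMatrix | None,
    config: PipelineConfig,
    seed: int,
    run_sensitivity: bool = True,
    methods: str = "all",
) -> dict:
    exp_name, exp_records = exposure
    logger.info("stage exposure-outcome: %s", exp_name)
    total_pa = analyze_pair(
        exp_records, outcome, ld, config, exp_name, seed=seed,
        run_sensitivity=run_sensitivity, methods=methods,
    )
    total_est = total_pa.primary

    med_section: dict[str, dict] = {}
    screen_inputs: dict[str, MrEstimate] = {}
    med_pairs: dict[str, PairAnalysis] = {}
    for i, (name, records) in enumerate(sorted(mediators.items())):
        logger.info("stage mediator-outcome: %s", name)
        pa = analyze_pair(
            records, outcome, ld, config, name, seed=seed + 100 + i,
            run_sensitivity=run_sensitivity, methods=methods,
        )
        med_pairs[name] = pa
        screen_inputs[name] = pa.primary

    retained = screen_mediators(screen_inputs, alpha=config.screen_alpha)
    for i, (name, pa) in enumerate(med_pairs.items()):
        step2 = screen_inputs[name]
        entry: dict = {
            "outcome_analysis": _pair_dict(pa),
            "screen": {
                "pval": step2.pval,
                "alpha": config.screen_alpha,
                "retained": name in retained,
                "label": _significance_label(step2.pval, config.screen_alpha),
            },
        }
        if name in retained:
            logger.info("stage exposure-mediator: %s", name)
            step1_pa = analyze_pair(
                exp_records,
                mediators[name],
                ld,
                config,
                exp_name,
                seed=seed + 200 + i,
                run_sensitivity=run_sensitivity,
                methods=methods,
            )
            step1 = step1_pa.primary
            med = decompose(total_est, step1, step2)
            med = with_uncertainty(
                med, step1, step2, method=config.mediated_se_method,
                n_boot=config.n_boot, seed=seed + 300 + i,
            )
            entry["step1_analysis"] = _pair_dict(step1_pa)
            entry["mediation"] = med.to_dict()
        med_section[name] = entry

    report = {
        "software": {"name": "mrmediate", "version": __version__},
        "seed": seed,
        "config": dataclasses.asdict(config),
        "exposure": _pair_dict(total_pa),
        "exposure_label": _significance_label(total_est.pval),
        "mediators": med_section,
        "retained_mediators": retained,
    }
    return report


def run_pipeline(
    exposure_path: str | Path,
    mediator_paths: Mapping[str, str | Path],
    outcome_path: str | Path,
    out_dir: str | Path,
    ld_path: str | Path | None = None,
    config: PipelineConfig | None = None,
    seed: int = 0,
    column_map: Mapping[str, str] | None = None,
    exposure_name: str = "exposure",
) -> dict:
    """File-based pipeline: read TSVs, run the three steps, write the report.

    Outputs under ``out_dir``: ``report.json`` (machine-readable, validated
    against the shipped schema), ``estimates.tsv`` (one row per
    trait/method, forest-plot shaped), ``instruments.tsv``, ``funnel.tsv``
    (per-SNP ratio vs precision for the exposure) and ``mediation.tsv``.
    A failing stage aborts with the stage name; outputs written so far are
    preserved.
    """
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    exp_records = read_summary_stats(exposure_path, column_map)
    med_records = {
        str(name): read_summary_stats(path, column_map)
        for name, path in mediator_paths.items()
    }
    out_records = read_summary_stats(outcome_path, column_map)
    ld = LdMatrix.from_tsv(ld_path) if ld_path is not None else None

    report = _run(
        exposure=(exposure_name, exp_records),
        mediators=med_records,
        outcome=out_records,
        ld=ld,
        config=config,
        seed=seed,
    )
    validate_report(report)

    with open(out_dir / "report.json", "w") as fh:
        fh.write(json.dumps(report, indent=2, sort_keys=True) + "\n")

    rows = []
    sections = [(exposure_name, report["exposure"])] + [
        (name, entry["outcome_analysis"]) for name, entry in report["mediators"].items()
    ]
    for trait, section in sections:
        for method, est in section["estimates"].items():
            rows.append({"trait": trait, **est})
    pd.DataFrame(rows).to_csv(out_dir / "estimates.tsv", sep="\t", index=False)

    inst_rows = []
    for trait, section in sections:
        inst_rows.append(
            {
                "trait": trait,
                **{f"n_{k}": v for k, v in section["counts"].items()},
                "f_min": section["f_range"][0],
                "f_max": section["f_range"][1],
            }
        )
    pd.DataFrame(inst_rows).to_csv(out_dir / "instruments.tsv", sep="\t", index=False)

    # funnel data for the exposure-outcome analysis (re-derived, cheap)
    pa = analyze_pair(
        exp_records, out_records, ld, config, exposure_name, seed=seed,
        run_sensitivity=False, methods="ivw",
    )
    funnel_data(pa.harmonized).to_csv(out_dir / "funnel.tsv", sep="\t", index=False)

    med_rows = [
        {"mediator": name, **entry["mediation"]}
        for name, entry in report["mediators"].items()
        if "mediation" in entry
    ]
    if med_rows:
        for row in med_rows:
            row.pop("ci_mediated", None)
        pd.DataFrame(med_rows).to_csv(out_dir / "mediation.tsv", sep="\t", index=False)

    sens = report["exposure"].get("sensitivity")
    if sens is not None:
        with open(out_dir / "sensitivity.json", "w") as fh:
            fh.write(json.dumps(sens, indent=2, sort_keys=True) + "\n")
    return report


# --- minimal schema validation ---------------------------------------------


def _load_schema() -> dict:
    with resources.files("mrmediate").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "number": (int, float),
    "integer": int,
    "boolean": bool,
}


def _check(node: dict, value, path: str) -> list[str]:
    errors = []
    expected = node.get("type")
    if expected is not None:
        py = _TYPES[expected]
        if value is None and node.get("nullable", False):
            return errors
        if not isinstance(value, py) or (expected == "number" and isinstance(value, bool)):
            errors.append(f"{path}: expected {expected}, got {type(value).__name__}")
            return errors
    for key in node.get("required", []):
        if not isinstance(value, dict) or key not in value:
            errors.append(f"{path}: missing required key {key!r}")
    for key, sub in node.get("properties", {}).items():
        if isinstance(value, dict) and key in value:
            errors.extend(_check(sub, value[key], f"{path}.{key}"))
    if "items" in node and isinstance(value, list):
        for i, item in enumerate(value):
            errors.extend(_check(node["items"], item, f"{path}[{i}]"))
    return errors


def validate_report(report: dict) -> None:
    """Check the report against the shipped structural schema."""
    errors = _check(_load_schema(), report, "report")
    if errors:
        raise ValueError("report schema violation: " + "; ".join(errors))
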