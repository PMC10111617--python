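import numpy as np
import pytest

from mrmediate import (
    HarmonizedSet,
    SimulationConfig,
    SnpRecord,
    harmonize,
    select_by_pvalue,
    simulate,
)


def toy_harmonized(n=20, seed=0, slope=0.1, intercept=0.0, noise=1.0):
    """Deterministic synthetic per-SNP effect pairs around a known line."""
    rng = np.random.default_rng(seed)
    be = rng.uniform(0.02, 0.10, n)
    se_exp = np.full(n, 0.002)
    se_out = rng.uniform(0.005, 0.02, n)
    bo = intercept + slope * be + noise * se_out * rng.standard_normal(n)
    return HarmonizedSet(
        snp_ids=[f"rs{i + 1}" for i in range(n)],
        beta_exp=be,
        se_exp=se_exp,
        beta_out=bo,
        se_out=se_out,
    )


def simulated_instruments(seed, threshold=5e-8, **config_overrides):
    """Exposure instruments harmonized against the outcome, one seed."""
    overrides = {"n_snp_causal_mediator": 0, "n_snp_null": 0, **config_overrides}
    study = simulate(SimulationConfig(seed=seed, **overrides))
    selected = select_by_pvalue(study.exposure_stats, threshold)
    return harmonize(selected, study.outcome_stats), study


def make_record(snp_id="rs1", ea="A", oa="G", beta=0.1, se=0.01, pval=None, **kw):
    if pval is None:
        from mrmediate.summary_data import gaussian_pvalue

        pval = gaussian_pvalue(beta, se) if se > 0 else 0.5
    return SnpRecord(
        snp_id=snp_id, effect_allele=ea, other_allele=oa,
        beta=beta, se=se, pval=pval, **kw,
    )


@pytest.fixture
def twenty_snp_set():
    return toy_harmonized(n=20, seed=42)
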