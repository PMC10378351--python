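import numpy as np
import pytest

import survimage as sv


def make_tpm_cohort(
    n_patients=6, n_genes=16, seed=0, effect_size=2.0, **kwargs
) -> sv.Cohort:
    """Small filtered TPM cohort for imaging/training tests."""
    cfg = sv.SimConfig(
        n_patients=n_patients, n_genes=n_genes, seed=seed,
        effect_size=effect_size, **kwargs,
    )
    raw, _ = sv.simulate_cohort(cfg)
    cohort, _ = sv.filter_cohort(raw, require_death_date=True)
    return sv.Cohort(
        records=cohort.records, expression=sv.fpkm_to_tpm(cohort.expression)
    )


def make_manual_cohort(survivals, ages=None, n_genes=9, seed=0) -> sv.Cohort:
    """Cohort with hand-picked survival days (ids P00, P01, ... in order)."""
    rng = np.random.default_rng(seed)
    n = len(survivals)
    ids = [f"P{i:02d}" for i in range(n)]
    ages = list(ages) if ages is not None else [50 + i for i in range(n)]
    records = [
        sv.ClinicalRecord(ids[i], ages[i], int(survivals[i]), True)
        for i in range(n)
    ]
    fpkm = rng.lognormal(2.0, 1.0, size=(n_genes, n))
    expr = sv.ExpressionMatrix(
        gene_ids=[f"G{i:03d}" for i in range(n_genes)],
        sample_ids=ids,
        values=fpkm,
        unit="FPKM",
    )
    return sv.Cohort(records=records, expression=sv.fpkm_to_tpm(expr))


@pytest.fixture
def tpm_cohort():
    return make_tpm_cohort()
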