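import numpy as np
import pytest

from cytomdr import reference_genotype_counts, resample_from_marginals
from cytomdr.simulate import CohortSpec, simulate_cohort, xor_penetrance


@pytest.fixture(scope="session")
def ref_tables():
    return reference_genotype_counts()


@pytest.fixture(scope="session")
def ref_dataset(ref_tables):
    """Subject-level dataset with the reference study's exact marginals."""
    return resample_from_marginals(ref_tables, rng=np.random.default_rng(20240926))


def make_xor_cohort(seed, n_cases=400, n_controls=400, p_high=0.6, p_low=0.1,
                    n_null=3, null_maf=0.3):
    """Pure-epistasis cohort: two causal loci at MAF 0.5 plus null SNPs."""
    mafs = {"snpA": 0.5, "snpB": 0.5}
    for i in range(n_null):
        mafs[f"noise{i + 1}"] = null_maf
    spec = CohortSpec(n_cases=n_cases, n_controls=n_controls, mafs=mafs, seed=seed)
    model = xor_penetrance("snpA", "snpB", p_high, p_low)
    return simulate_cohort(spec, model=model)


@pytest.fixture()
def xor_cohort():
    return make_xor_cohort(seed=11)
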