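import pytest

from panpop.syndata import CohortSpec, simulate_genotypes


@pytest.fixture(scope="session")
def cohort():
    """Small five-subpopulation cohort reused across structure/diversity tests."""
    spec = CohortSpec(
        n_per_subpop={"XI-1A": 30, "XI-2": 20, "GJ-tmp": 30, "cA": 15, "cB": 10},
        n_snps=600,
        seed=11,
    )
    return simulate_genotypes(spec)
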