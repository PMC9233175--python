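import pytest

from haploci import DiallelSimParams, Genotype, McmcSettings, simulate_diallel


@pytest.fixture(scope="session")
def fast_settings():
    """Short chains for unit tests; convergence is checked where it matters."""
    return McmcSettings(chains=2, iterations=1500, warmup=500, seed=7)


@pytest.fixture(scope="session")
def ideal_diallel_records():
    """Large single-genotype diallel in the ideal limit (no mortality, no
    day effects): theta=0.8, phi=0.25, so the corrected indexes should
    approach (0.8, 0.2, 0.6)."""
    params = DiallelSimParams(
        genotypes=[Genotype("A")],
        theta=0.8,
        phi=0.25,
        fert=0.9,
        base_mort=0.0,
        day_sd=0.0,
        replicates_per_cross=60,
        eggs_mean=400.0,
        seed=3,
    )
    return simulate_diallel(params)
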