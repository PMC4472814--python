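import pytest

import meniscea as m
from meniscea.engine import RunOptions


@pytest.fixture(scope="session")
def ps():
    return m.default_parameters()


@pytest.fixture(scope="session")
def life_table(ps):
    return m.load_life_table(ps.life_table_path)


@pytest.fixture(scope="session")
def base_results(ps):
    """Cohort-mode point-estimate results for all three strategies, with
    occupancy-conservation tracking on."""
    return m.run_base_case(ps, RunOptions(validate=True))


@pytest.fixture(scope="session")
def psa_10k(ps):
    """The 10,000-draw probabilistic sensitivity analysis (timed)."""
    import time

    t0 = time.time()
    res = m.run_psa(ps, 10_000, seed=2013)
    res.elapsed_seconds = time.time() - t0
    return res


@pytest.fixture(scope="session")
def big_trial(ps):
    """Synthetic trial with 100,000 subjects per arm and its re-estimates."""
    records = m.generate_trial(ps, 100_000, seed=42)
    estimates = m.estimate_from_trial(records)
    return records, estimates
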