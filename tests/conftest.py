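import pytest

from flashtod import (
    KineticParams,
    OERParams,
    cooper_design,
    full_factorial,
    run_grid,
)


@pytest.fixture(scope="session")
def kinetic():
    return KineticParams()


@pytest.fixture(scope="session")
def oer_params():
    return OERParams()


@pytest.fixture(scope="session")
def design():
    return cooper_design()


@pytest.fixture(scope="session")
def cooper_tod(design, kinetic, oer_params):
    return run_grid(design, kinetic, oer_params)


@pytest.fixture(scope="session")
def factorial_tod(kinetic, oer_params):
    return run_grid(full_factorial(), kinetic, oer_params)


@pytest.fixture(scope="session")
def end_pO2_cache(cooper_tod):
    return {
        (r.oxygen_percent, r.dose_gy, r.dose_rate_gy_s): r.end_pO2_mmHg
        for r in cooper_tod.frame.itertuples()
    }
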