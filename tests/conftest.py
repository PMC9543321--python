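import pytest

from streampcb.scenario_engine import run_projection
from streampcb.synthetic_data import SynthConfig, gen_site_fixture

#: package-wide fixture seed (chosen once; all derived runs are deterministic)
FIXTURE_SEED = 20240101


@pytest.fixture(scope="session")
def synth_cfg():
    return SynthConfig(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def site(synth_cfg):
    return gen_site_fixture(synth_cfg)


@pytest.fixture(scope="session")
def projections(site):
    """Memoized 10-year projections shared across tests (they are costly)."""
    cache = {}

    def get(alternative=3, calibration="base", years=10.0):
        key = (alternative, str(calibration), years)
        if key not in cache:
            cache[key] = run_projection(site, alternative=alternative,
                                        calibration=calibration, years=years)
        return cache[key]

    return get
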