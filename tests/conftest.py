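import pytest
from hypothesis import settings

import telestroke_cea as tcea

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def base_cfg():
    """Packaged base-case configuration with the seed-0 synthetic fixture."""
    return tcea.default_config(0)


@pytest.fixture(scope="session")
def inert_cfg(base_cfg):
    """Base config with all hazards switched off (no deaths, no recurrences)."""
    d = base_cfg.to_dict()
    d["transition"]["p_recur_year1"] = 0.0
    d["transition"]["p_recur_later"] = 0.0
    d["life_table"] = {age: 0.0 for age in d["life_table"]}
    return tcea.ModelConfig.from_dict(d)
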