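import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from gutwbm import EffectConfig, run_flux_study  # noqa: E402


@pytest.fixture(scope="session")
def small_config() -> EffectConfig:
    return EffectConfig(n_samples=80, seed=7)


@pytest.fixture(scope="session")
def small_study(small_config):
    """One 80-sample end-to-end flux study shared across tests."""
    return run_flux_study(small_config)
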