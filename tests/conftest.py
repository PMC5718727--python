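import warnings

import pytest

from dxcea.core import Subgroup, SubgroupPrevalence
from dxcea.perftable import load_packaged_tables
from dxcea.strategies import EnumerationConfig, enumerate_strategies
from dxcea.synthetic import SyntheticConfig, generate_parameter_set


@pytest.fixture(scope="session")
def packaged():
    """Packaged point-estimate tables (rounding-repair warnings silenced)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return load_packaged_tables()


@pytest.fixture(scope="session")
def prevalence():
    """Synthetic referral-population prevalence used throughout the tests."""
    return SubgroupPrevalence(
        {
            Subgroup.NO_CANCER: 0.42,
            Subgroup.LOW_RISK: 0.18,
            Subgroup.INTERMEDIATE_RISK: 0.25,
            Subgroup.HIGH_RISK: 0.15,
        }
    )


@pytest.fixture(scope="session")
def all_strategies():
    return enumerate_strategies(EnumerationConfig(warn_on_count_mismatch=False))


@pytest.fixture(scope="session")
def bundle():
    """Synthetic bundle with the packaged tables kept exact."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_parameter_set(SyntheticConfig(seed=7, perf_ess=None))
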