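import numpy as np
import pytest
from hypothesis import settings

import armshuffle as ash

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_bundle():
    """One null-regime bundle at the generator's default sizes."""
    return ash.simulate_bundle(ash.SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def small_bundle():
    """One null-regime bundle at the reduced calibration sizes."""
    return ash.simulate_bundle(ash.SyntheticConfig.small(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(123)


def make_ol(oid, arm, start, end, is_lam=False, definition="OLC", genes=("gX",)):
    return ash.OLRegion(oid, arm, start, end, definition, tuple(genes), is_lam=is_lam)


def make_gene(gid, arm="2L", start=0, end=10, left_bp=0, right_bp=0,
              left_ch=False, right_ch=False, tag="untagged", nested_in=None,
              definition="OLC"):
    return ash.GeneRecord(
        gid, arm, start, end,
        left_breakpoints={definition: left_bp},
        right_breakpoints={definition: right_bp},
        left_changed={definition: left_ch},
        right_changed={definition: right_ch},
        nested_in=nested_in,
        tag=tag,
    )
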