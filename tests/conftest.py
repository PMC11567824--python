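from pathlib import Path

import pytest

from cogrisk import EffectSpec, generate_cohort, prepare

FIXTURE_DIR = Path(__file__).parent / "data" / "fixtures"


@pytest.fixture(scope="session")
def fixture_dir() -> Path:
    return FIXTURE_DIR


@pytest.fixture(scope="session")
def default_prep():
    """A mid-size default-spec cohort, prepared for the association stage."""
    return prepare(generate_cohort(EffectSpec(n=1500, seed=11)))


@pytest.fixture(scope="session")
def full_prep():
    """A full-size (n=3327) default-spec prepared cohort."""
    return prepare(generate_cohort(EffectSpec(n=3327, seed=3)))
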