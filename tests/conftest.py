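import random

import pytest

from plasmidplan.config import CostCurve, CostTier, DesignConfig, money
from plasmidplan.fixtures import generate_fixture, random_fixture_spec
from plasmidplan.pipeline import DesignRequest, make_sequence


@pytest.fixture
def config():
    return DesignConfig()


@pytest.fixture
def small_curve():
    """A two-tier curve: fixed $89 to 500 bp, $0.10/bp to 1500 bp."""
    return CostCurve((CostTier(500, money(89), False),
                      CostTier(1500, money("0.10"), True)))


def design_fixture(seed, allow_gaps=True, **spec_overrides):
    """Generate a seeded fixture and run the full design pipeline on it
    with the in-process search backend."""
    spec = random_fixture_spec(seed, allow_gaps=allow_gaps)
    for key, value in spec_overrides.items():
        setattr(spec, key, value)
    fx = generate_fixture(spec)
    request = DesignRequest(
        mode="sequence", sequence=fx.target,
        repos=list(fx.repositories.values()), backend="kmer")
    return fx, make_sequence(request)


def random_dna(seed, length):
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(length))
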