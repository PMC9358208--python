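import numpy as np
import pytest

from sichpipe import synth
from sichpipe.cohort import derive_fields, packaged_cohort


@pytest.fixture(scope="session")
def cohort():
    """The packaged 13-patient pilot cohort."""
    return packaged_cohort()


@pytest.fixture(scope="session")
def cohort_derived(cohort):
    return derive_fields(cohort)


@pytest.fixture(scope="session")
def phantom():
    """Default head phantom with mild (3 HU) noise plus its ground truth."""
    return synth.generate_ct_phantom(synth.PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def smear_fields():
    """Six smear fields with a 20% NET-like fraction and truth table."""
    return synth.generate_smear(synth.SmearSpec(seed=7, n_fields=6))


@pytest.fixture(scope="session")
def flow_events():
    """50k stained events with a planted 10% Q2 fraction + isotype tube."""
    return synth.generate_flow_events(synth.FlowSpec(seed=5))
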