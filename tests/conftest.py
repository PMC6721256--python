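import warnings

import pytest

from adaptindex import ParamStates, SubjectProfile, load_fixture
from adaptindex.errors import LowStabilityWarning


@pytest.fixture(scope="session")
def rats():
    """Bundled swimming-rat study (Case III, stability weighting, no recovery)."""
    return load_fixture("example1_rats")


@pytest.fixture(scope="session")
def horses():
    """Bundled race-horse study (Case III, unweighted, recovery included)."""
    return load_fixture("example2_horses")


@pytest.fixture(autouse=True)
def _quiet_low_stability():
    # the horse fixture legitimately carries lactate S < 0.5; the dedicated
    # warning tests re-enable it
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", LowStabilityWarning)
        yield


def make_profile(sid="s1", gid="g1", sig=None, **params):
    """Build a profile from name=(pre, load[, rec]) keyword tuples."""
    values = {name: ParamStates(*states) for name, states in params.items()}
    return SubjectProfile(subject_id=sid, group_id=gid, values=values, significant=sig)
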