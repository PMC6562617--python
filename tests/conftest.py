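import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from pedscout.core import Role, SampleRole


@pytest.fixture
def quartet_roles():
    """Two affected sibs, two obligate-carrier parents, one unaffected sib."""
    return [
        SampleRole("CASE1", Role.CASE, "Giant_Schnauzer"),
        SampleRole("CASE2", Role.CASE, "Giant_Schnauzer"),
        SampleRole("SIRE", Role.OBLIGATE_CARRIER, "Giant_Schnauzer"),
        SampleRole("DAM", Role.OBLIGATE_CARRIER, "Giant_Schnauzer"),
        SampleRole("SIB1", Role.UNAFFECTED, "Giant_Schnauzer"),
    ]
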