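import logging

import pytest
from hypothesis import HealthCheck, settings

import neovdist as nv

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# the fixture table deliberately contains drugs whose parameters trigger
# documented fallback warnings; keep test output quiet
logging.getLogger("neovdist").setLevel(logging.ERROR)
logging.getLogger("neovdist.kp_vss").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def drugs():
    return nv.packaged_drug_table()


@pytest.fixture(scope="session")
def drugs_by_name(drugs):
    return {d.name: d for d in drugs}


@pytest.fixture(scope="session")
def physiology():
    return nv.default_physiology()


@pytest.fixture(scope="session")
def adult_subject(physiology):
    return nv.build_reference_subject(physiology.default_spec("adult"), physiology)


@pytest.fixture(scope="session")
def term_subject(physiology):
    return nv.build_reference_subject(
        physiology.default_spec("term"), physiology, pna_days=7.0
    )


@pytest.fixture(scope="session")
def preterm_subject(physiology):
    return nv.build_reference_subject(
        physiology.default_spec("preterm"), physiology, ga_weeks=30.0, pna_days=0.0
    )


@pytest.fixture(scope="session")
def adult_vss_pt(drugs, physiology):
    return nv.adult_reference_vss(drugs, "PT_plus", physiology)
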