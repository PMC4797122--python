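import pytest
from hypothesis import HealthCheck, settings

import smilesim as sm

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

# The two sample SMILES strings used throughout the worked examples
# (typeset source contains spurious spaces, stripped by normalization).
SMI1 = "OC(O)=O"
SMI2 = "CCCCC(O)=C4"


@pytest.fixture
def smi1() -> str:
    return SMI1


@pytest.fixture
def smi2() -> str:
    return SMI2


@pytest.fixture
def sample_records() -> tuple[sm.CompoundRecord, sm.CompoundRecord]:
    return sm.make_record("SMI1", "OC(O) =O"), sm.make_record("SMI2", "CCCCC(O) =C4")


@pytest.fixture(scope="session")
def synth_bundle():
    """Small planted-cluster study shared by pipeline tests."""
    spec = sm.SyntheticSpec(n_drugs=30, n_targets=15, n_clusters=3, seed=7)
    return spec, *sm.generate_bundle(spec)
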