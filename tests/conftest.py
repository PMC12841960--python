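import pytest
from hypothesis import settings

from pfhb import HILIndices, SampleRecord, ThresholdConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def cfg() -> ThresholdConfig:
    return ThresholdConfig()


@pytest.fixture
def benign_record():
    """Factory for records where no rule fires unless overridden."""

    def make(**overrides) -> SampleRecord:
        hil = overrides.pop(
            "hil", HILIndices(h_index=0.0, i_index=0.0, l_index=0.0)
        )
        base = dict(
            sample_id="S1",
            hil=hil,
            fhb=40.0,
            tbil=10.0,
            dbil=5.0,
            venipuncture_verified=True,
        )
        base.update(overrides)
        return SampleRecord(**base)

    return make
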