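import numpy as np
import pytest

from mfcsholl import PipelineConfig, SyntheticSpec, generate_chamber


@pytest.fixture()
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_spec():
    """A reduced chamber: fast to render, same conventions as the default."""
    return SyntheticSpec(compartment_width_um=650.0, chamber_height_um=500.0,
                         axons_per_side=15, soma_count=60, rotation_deg=3.0,
                         seed=11)


@pytest.fixture(scope="session")
def small_chamber(small_spec):
    return generate_chamber(small_spec)


@pytest.fixture(scope="session")
def default_chamber():
    """One full-size chamber at a non-trivial angle."""
    return generate_chamber(SyntheticSpec(seed=3, rotation_deg=5.2))
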