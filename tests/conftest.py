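import numpy as np
import pytest

from dualact import PipelineConfig, PostureScript, Segment


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def four_posture_script():
    """Noiseless epoch-aligned script with 60/30/6/4 ground-truth fractions."""
    return PostureScript(
        segments=[
            Segment("lying", 300.0),
            Segment("sitting", 150.0),
            Segment("standing", 30.0),
            Segment("moving", 20.0, movement_enmo_target=25.0),
        ],
        jitter_sd=0.0,
        machine_noise_sd=0.0,
        seed=3,
    )


@pytest.fixture
def jittered_script():
    """Non-epoch-aligned script with 5 deg orientation jitter and machine noise."""
    return PostureScript(
        segments=[
            Segment("lying", 123.0),
            Segment("sitting", 77.0),
            Segment("standing", 41.0),
            Segment("moving", 34.0),
            Segment("lying", 60.0),
            Segment("sitting", 45.0),
        ],
        jitter_sd=5.0,
        machine_noise_sd=2.0,
        seed=11,
    )
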