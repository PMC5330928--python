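import warnings

import pytest

from shellprint import pipeline, synthetic
from shellprint.enhancement import MFGKParams

# the coarse-level ROF solves legitimately hit the iteration cap; the
# warning flag is carried in the stack and asserted where relevant
warnings.filterwarnings("ignore", message="ROF solver")


def phantom_config() -> pipeline.PipelineConfig:
    """Pipeline settings matched to the phantom line width (~3 px)."""
    return pipeline.PipelineConfig(
        mfgk=MFGKParams(a=8.0, sigma_kernel=0.25, polarity="bright")
    )


@pytest.fixture(scope="session")
def config() -> pipeline.PipelineConfig:
    return phantom_config()


@pytest.fixture(scope="session")
def clean_phantom() -> synthetic.Phantom:
    """Noise-free, jitter-free default phantom (48 ray-ring crossings)."""
    return synthetic.generate_phantom(synthetic.ShellPhantomSpec(jitter_seed=0))


@pytest.fixture(scope="session")
def jittered_phantom() -> synthetic.Phantom:
    return synthetic.generate_phantom(
        synthetic.ShellPhantomSpec(jitter_seed=7, jitter_sigma=2.0)
    )


@pytest.fixture(scope="session")
def phantom_artifacts(jittered_phantom, config):
    """Finest-scale pipeline artifacts of the jittered phantom."""
    return pipeline.extract_artifacts(
        jittered_phantom.image, config, scale_index=5
    )
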