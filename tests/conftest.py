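import numpy as np
import pytest

from landcarbon import synthetic

YEARS = np.arange(2002, 2018)


@pytest.fixture(scope="session")
def years():
    return YEARS.copy()


@pytest.fixture(scope="session")
def archetype_scene():
    """Noise-free 8-archetype scene, 25 pixels each."""
    layout = {name: 25 for name in synthetic.ARCHETYPES}
    return synthetic.generate_scene(layout, noise_sd=0.0, seed=42)
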