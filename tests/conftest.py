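import numpy as np
import pytest

from ploidyscape.genome import synthetic_genome
from ploidyscape.signatures import (load_ffpe_profile, load_id_signatures,
                                    load_sbs_signatures)
from ploidyscape.synth import SceneConfig, render_scene, sample_scene


@pytest.fixture(scope="session")
def genome():
    return synthetic_genome()


@pytest.fixture(scope="session")
def sbs_signatures():
    return load_sbs_signatures()


@pytest.fixture(scope="session")
def id_signatures():
    return load_id_signatures()


@pytest.fixture(scope="session")
def ffpe_profile():
    return load_ffpe_profile()


@pytest.fixture(scope="session")
def default_scene():
    """A mid-sized default-noise scene shared by read-only tests."""
    cfg = SceneConfig(n_cells=150, binuclear_fraction=0.2,
                      ploidy_class_probs=(0.6, 0.25, 0.1, 0.05), seed=101)
    scene = sample_scene(cfg)
    return scene, render_scene(scene)


@pytest.fixture(scope="session")
def noise_free_config():
    return SceneConfig(
        n_cells=120, binuclear_fraction=0.25,
        ploidy_class_probs=(0.55, 0.3, 0.1, 0.05),
        biological_cv=0.0, shot_noise=False, read_noise_sd=0.0,
        background=0.0, illumination_amplitude=0.0, mitotic_fraction=0.0,
        seed=77)
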