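import numpy as np
import pytest

from rgcpipe.protocol import StimulusProtocol
from rgcpipe.synthetic import SceneConfig, make_dataset, make_scene, simulate_spikes


@pytest.fixture(scope="session")
def protocol():
    return StimulusProtocol()


@pytest.fixture(scope="session")
def short_protocol():
    """Protocol with 60-s spontaneous epochs and a single chirp/bar trial,
    for tests that only need structure, not statistics."""
    return StimulusProtocol(n_chirp_trials=1, n_bar_trials=1,
                            spont_pre_duration_s=60.0, spont_cno_duration_s=60.0)


@pytest.fixture(scope="session")
def small_scene_dataset(protocol):
    """A small mixed scene with spikes for every epoch (shared, read-only)."""
    cfg = SceneConfig(n_somata=30)
    scene = make_scene(cfg, seed=11)
    ds = simulate_spikes(scene, protocol, seed=11)
    return scene, ds


@pytest.fixture(scope="session")
def spont_scene_dataset(protocol):
    """Default planted scene with spontaneous epochs only (activity tests)."""
    cfg = SceneConfig()
    scene = make_scene(cfg, seed=5)
    ds = simulate_spikes(scene, protocol, seed=5, epoch_kinds=("spont_pre", "spont_cno"))
    return scene, ds
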