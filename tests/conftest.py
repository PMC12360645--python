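import numpy as np
import pytest

from wormtrack.shapespace import fit_shape_space, resample_equal_arclength
from wormtrack.simulate import simulate_recording


@pytest.fixture(scope="session")
def recording_8s():
    """3 crawling worms, just over 8 s at 25 fps, 256x256 (an 11-frame clip
    spanning 8 s needs 201 frames)."""
    return simulate_recording(3, 8.2, seed=11, frame_shape=(256, 256))


@pytest.fixture(scope="session")
def sim_skeletons(recording_8s):
    """Normalised (equal-spacing) simulated skeletons pooled over worms and
    frames: (M, 49, 2) with M = 600."""
    rec = recording_8s
    skels = rec.skeletons.reshape(-1, rec.skeletons.shape[2], 2)
    return np.stack([resample_equal_arclength(s, 49) for s in skels])


@pytest.fixture(scope="session")
def shape_space_72(sim_skeletons):
    return fit_shape_space(sim_skeletons, n_components=72)
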