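import numpy as np
import pytest

from repairscope.simulate import SFMSimParams, SPTSimParams


@pytest.fixture
def big_mask():
    """Whole-field nucleus mask (no boundary effects)."""
    return np.ones((256, 256), dtype=bool)


def single_state_params(state: int, **kwargs) -> SPTSimParams:
    """SPT params locked to one diffusive state (identity transitions)."""
    probs = [0.0, 0.0, 0.0]
    probs[state] = 1.0
    defaults = dict(
        transition_matrix=np.eye(3),
        initial_state_probs=probs,
        bleach_prob=0.0,
        n_frames=100,
        n_particles=20,
        seed=1,
    )
    defaults.update(kwargs)
    return SPTSimParams(**defaults)


def clean_sfm_params(**kwargs) -> SFMSimParams:
    """SFM params with all artifacts switched off."""
    defaults = dict(
        tip_sigma=0.0,
        plane_tilt=0.0,
        line_offset_sigma=0.0,
        height_noise_sigma=0.0,
        n_particles=5,
        seed=1,
    )
    defaults.update(kwargs)
    return SFMSimParams(**defaults)
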