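import numpy as np
import pytest

from luxepi.light import bin_half_hour, mask_nonwear
from luxepi.synthetic import LightGenConfig, generate_light_recording


@pytest.fixture(scope="session")
def light_cohort():
    """500 synthetic participant-weeks plus their 48-bin profiles."""
    cfg = LightGenConfig(n_participants=500, seed=7, nonwear_gap_rate=0.2)
    recs = [generate_light_recording(cfg, i) for i in range(cfg.n_participants)]
    profiles = [bin_half_hour(mask_nonwear(r)) for r in recs]
    return cfg, recs, profiles


@pytest.fixture(scope="session")
def profile_matrix(light_cohort):
    _, _, profiles = light_cohort
    return np.stack([p.bin_means for p in profiles])
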