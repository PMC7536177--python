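import numpy as np
import pytest

from palmblink import BlinkStats, preset_config, sample_traces, summarize


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def surrogate_ps_stats() -> BlinkStats:
    """Synthetic stand-in for a measured PS-CFP2 (4% PFA) blinking histogram.

    Built from the preset generator at large n so that the empirical N
    distribution has the measured mean and a realistic shape; used wherever
    a measured-fluorophore N source is needed.
    """
    gen = np.random.default_rng(777)
    cfg = preset_config("ps_cfp2_pfa", sigma_loc=15.0)
    return summarize(sample_traces(3000, cfg, gen), condition_label="surrogate ps-cfp2")
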