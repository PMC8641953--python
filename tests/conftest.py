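import numpy as np
import pytest

from prfmap.hemodynamics import make_hrf
from prfmap.stimulus import make_protocol, render_effective_stimulus


@pytest.fixture(scope="session")
def fmri_protocol():
    return make_protocol("fmri")


@pytest.fixture(scope="session")
def ephys_protocol():
    return make_protocol("ephys")


@pytest.fixture(scope="session")
def small_fmri_stim():
    """fMRI protocol rendered coarsely (3 px/dva) to keep fits fast."""
    return render_effective_stimulus(make_protocol("fmri", pixels_per_dva=3))


@pytest.fixture(scope="session")
def small_ephys_stim():
    """Ephys protocol rendered coarsely (2 px/dva)."""
    return render_effective_stimulus(make_protocol("ephys", pixels_per_dva=2))


@pytest.fixture(scope="session")
def monkey_hrf():
    return make_hrf("monkey")


@pytest.fixture(scope="session")
def human_hrf():
    return make_hrf("human")


@pytest.fixture(scope="session")
def toy_stim():
    """A tiny 8x8 stimulus (single sweep, no blanks) for oracle checks."""
    proto = make_protocol(
        aperture_diameter=8.0,
        bar_width=2.0,
        n_steps_per_sweep=5,
        step_duration=1.0,
        sweep_directions=(0.0, 90.0),
        pixels_per_dva=1,
    )
    return render_effective_stimulus(proto)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
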