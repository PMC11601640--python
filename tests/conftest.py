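import numpy as np
import pytest

from cyclekit.synthetic import SimMovieConfig, render_movie


@pytest.fixture(scope="session")
def small_movie():
    """9-cell movie with three scheduled divisions and mixed fates."""
    cfg = SimMovieConfig(
        field_size_px=(512, 512),
        n_frames=20,
        n_cells_initial=9,
        seed=3,
        noise_sd=5.0,
        division_schedule=[(0, 5, (0.5, 0.5)), (1, 8, (0.47, 0.53)), (2, 10, (0.52, 0.48))],
        fate_assignment={0: "cdk2_increasing", 1: "transient_g0", 2: "prolonged_g0"},
    )
    stack, truth = render_movie(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def clean_movie():
    """Noise- and bias-free movie for exact geometry checks."""
    cfg = SimMovieConfig(
        field_size_px=(384, 384),
        n_frames=4,
        n_cells_initial=4,
        seed=11,
        noise_sd=0.0,
        bias_amplitude=0.0,
    )
    stack, truth = render_movie(cfg)
    return cfg, stack, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
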