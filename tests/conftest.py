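import numpy as np
import pytest

from puffkit.preprocess import MovieStack
from puffkit.synthetic import SimMovieConfig, simulate_movie


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_noiseless_movie():
    """Tiny noiseless movie with one site and one event, for exact checks."""
    cfg = SimMovieConfig(
        field_size_px=40, n_frames=500, flash_frame=100, flash_artifact_frames=2,
        baseline_level=1000.0, noise_sd=0.0,
        site_positions_um=[(3.2, 3.2)], n_sites=1, min_separation_um=0.0,
        event_rate_per_site_hz=0.0, seed=0)
    stack, truth = simulate_movie(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def recovery_movie():
    """Mid-size noisy movie with known events, shared across recovery tests."""
    cfg = SimMovieConfig(field_size_px=80, n_frames=1500, flash_frame=400,
                         n_sites=5, event_rate_per_site_hz=0.4, seed=11)
    stack, truth = simulate_movie(cfg)
    return cfg, stack, truth


def constant_stack(value=100.0, shape=(20, 8, 8), **kw):
    kw.setdefault("pixel_size_um", 0.16)
    kw.setdefault("frame_interval_s", 0.005)
    return MovieStack(np.full(shape, float(value)), **kw)
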