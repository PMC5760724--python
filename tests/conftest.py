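import numpy as np
import pytest

from dimtrack import ParticleSpec, SyntheticMovieSpec, TrackingConfig, simulate_movie


@pytest.fixture
def config():
    return TrackingConfig()  # 15x15 scan, 5x5 window, gaussian


@pytest.fixture
def spot_movie():
    """Factory: single-particle movie with chosen noise/motion/blinking."""

    def _make(n_frames=30, start=(30.0, 25.0), noise_sigma=0.0, seed=0,
              motion=None, blink_frames=(), amplitude=100.0, shape=(64, 64)):
        from dimtrack import MotionModel

        particle = ParticleSpec(
            start=start,
            motion=motion or MotionModel(),
            amplitude=amplitude,
            blink_frames=frozenset(blink_frames),
        )
        spec = SyntheticMovieSpec(
            n_frames=n_frames,
            height=shape[0],
            width=shape[1],
            particles=(particle,),
            noise_sigma=noise_sigma,
            seed=seed,
        )
        return simulate_movie(spec)

    return _make


@pytest.fixture
def rendered_spot():
    """Noiseless Gaussian spot on a zero background."""

    def _make(A=100.0, x_c=10.3, y_c=12.7, w_x=1.5, w_y=1.5, shape=(30, 30)):
        from dimtrack import render_spot

        img = np.zeros(shape)
        render_spot(img, A, x_c, y_c, w_x, w_y)
        return img

    return _make
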