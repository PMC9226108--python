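import numpy as np
import pytest

import sonotkv as sk


@pytest.fixture(scope="session")
def sphere_spec():
    """A 10 mm sphere fully inside the field of view at 1 mm spacing."""
    depth = 200.0
    # place the sphere centre 16 mm below the frame top
    cx = 16.0 - (0.55 * depth - 2.0)
    return sk.PhantomSpec(
        semi_axes=(10.0, 10.0, 10.0), cysts=(), center=(cx, 0.0, 0.0),
        sector_depth=depth, sector_width_deg=80.0, sector_apex=(2.0, 0.0),
        spacing=(1.0, 1.0, 1.0), in_plane_size=64, n_frames=48,
        blank_margin=0.0, speckle_scale=0.0, gain=0.68, seed=11)


@pytest.fixture(scope="session")
def rendered_phantom():
    spec = sk.sample_spec(3, "centered")
    stack, mask, vol = sk.render_phantom(spec)
    return spec, stack, mask, vol


@pytest.fixture(scope="session")
def experiment_report():
    """The 12-phantom-patient desk-scale study (8/1/3 split), run once."""
    cfg = sk.ExperimentConfig(seed=1)
    return sk.run_phantom_experiment(cfg)


def random_mask_pair(rng, shape=(8, 8, 8), p=0.35):
    a = (rng.random(shape) < p).astype(np.uint8)
    b = (rng.random(shape) < p).astype(np.uint8)
    return a, b
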