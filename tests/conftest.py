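import numpy as np
import pytest

from ellipsoidfit.synthetic import (
    ClickSimulation,
    random_ellipsoid,
    sample_surface_points,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_instance(rng, dim, n, noise_frac, seed):
    """One random fitting instance: ground truth + sampled boundary points."""
    geom = random_ellipsoid(rng, dim=dim)
    sim = ClickSimulation(
        ellipsoid=geom,
        n_points=n,
        noise_sigma=noise_frac * float(geom.semilengths.mean()),
        seed=seed,
    )
    return geom, sample_surface_points(sim)


def instance_battery(seed=0, trials=60):
    """Mixed battery: d in {2,3}, n in {9,20,200}, noise 0-5% of mean radius."""
    rng = np.random.default_rng(seed)
    for trial in range(trials):
        dim = 2 if trial % 2 == 0 else 3
        n = [9, 20, 200][trial % 3]
        noise = [0.0, 0.01, 0.05][trial % 3]
        yield make_instance(rng, dim, max(n, 9), noise, seed=trial)
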