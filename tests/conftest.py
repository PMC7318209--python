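import numpy as np
import pytest

import boundline as bl
from boundline.fit_select import FitConfig

# latent truth used across simulation tests (generator defaults)
TRUTH_BOUNDARY = bl.BoundaryParams(-21.05, 10.15, 13.64)
TRUTH_LATENT = bl.LatentBivariate(mu_y=12.0, mu_x=4.0, sigma_y=2.5, sigma_x=0.5, rho=0.3)

# lean optimizer settings for simulation-heavy tests (problem-size choice;
# the library default is 8 jittered restarts)
FAST_FIT = FitConfig(n_extra_starts=2, rng_seed=0)
FAST_FIT_NOCOV = FitConfig(n_extra_starts=2, rng_seed=0, compute_cov=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def iid_bl_dataset(seed: int, n_farms: int = 186):
    """Zones drawn iid from the censored model at the default truth."""
    spec = bl.GeneratorSpec(n_farms=n_farms, zones_per_farm=27, spatial=None,
                            rng_seed=seed)
    _, trace = bl.generate_zones(spec, return_trace=True)
    return trace["y_obs"], trace["x_log"]


def iid_mvn_dataset(seed: int, n_farms: int = 74):
    """Uncensored iid bivariate-normal zones (plus observation noise)."""
    spec = bl.GeneratorSpec(n_farms=n_farms, zones_per_farm=27, spatial=None,
                            boundary=None, rng_seed=seed)
    _, trace = bl.generate_zones(spec, return_trace=True)
    return trace["y_obs"], trace["x_log"]
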