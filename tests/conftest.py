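import numpy as np
import pytest

from diffinfo.distributions import NormalizedObservation, wilson_prior_z


@pytest.fixture
def rng():
    return np.random.default_rng(20200225)


def sample_posterior_z(obs: NormalizedObservation, n: int, rng) -> np.ndarray:
    """Draw true normalized intensities from p(Z | Z_O) by grid inversion.

    Independent of the package's quadrature machinery: builds the
    unnormalized posterior on a fine grid and inverts the empirical CDF.
    """
    z_o, s = obs.z_obs, obs.sigma_z
    upper = max(z_o, 0.0) + 12.0 * s + 20.0
    # log-spaced head resolves the centric 1/sqrt(z) singularity
    grid = np.unique(np.concatenate([
        np.geomspace(1e-12, min(1.0, upper), 4000),
        np.linspace(min(1.0, upper), upper, 20000),
    ]))
    dens = wilson_prior_z(grid, obs.centric) * np.exp(-0.5 * ((z_o - grid) / s) ** 2)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(grid))])
    cdf /= cdf[-1]
    u = rng.uniform(size=n)
    return np.interp(u, cdf, grid)
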