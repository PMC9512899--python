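import numpy as np
import pytest

from d50track import SimConfig, predict_alsfrsr, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-parameter cohort, shared across read-only tests."""
    return simulate_cohort(SimConfig(seed=42))


@pytest.fixture
def noiseless_trajectory():
    """Dense noiseless samples of a (D50=30, dx=6) sigmoid."""
    t = np.arange(3.0, 48.0, 6.0)
    return t, predict_alsfrsr(t, 30.0, 6.0)


def grid_search_oracle(times, scores, d50_grid=None, dx_grid=None):
    """Brute-force least-squares oracle on a dense (D50, dx) grid.

    Independent of the package optimizer: evaluates the sigmoid RSS on the
    full grid and returns (d50, dx, rss) of the best cell.
    """
    if d50_grid is None:
        d50_grid = np.arange(0.5, 120.0 + 1e-9, 0.05)
    if dx_grid is None:
        dx_grid = np.arange(0.5, 30.0 + 1e-9, 0.05)
    t = np.asarray(times, dtype=float)
    y = np.asarray(scores, dtype=float)
    best = (np.nan, np.nan, np.inf)
    # chunk over d50 to bound memory: (chunk, n_dx, n_obs)
    for start in range(0, d50_grid.size, 200):
        d50c = d50_grid[start:start + 200][:, None, None]
        dxc = dx_grid[None, :, None]
        z = (t[None, None, :] - d50c) / dxc
        pred = 48.0 / (1.0 + np.exp(np.clip(z, -700, 700)))
        rss = ((pred - y[None, None, :]) ** 2).sum(axis=-1)
        i, j = np.unravel_index(np.argmin(rss), rss.shape)
        if rss[i, j] < best[2]:
            best = (float(d50_grid[start + i]), float(dx_grid[j]),
                    float(rss[i, j]))
    return best
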