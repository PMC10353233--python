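import numpy as np
import pytest

from spindex import (
    PriceSchedule,
    PriceTableau,
    ServiceItem,
    SyntheticConfig,
    generate_system,
)


def make_tableau(prices, headings=None, regions=None, heading_set=None):
    """Build a small tableau from a plain M x N price array."""
    prices = np.asarray(prices, dtype=float)
    m, n = prices.shape
    regions = regions or [f"R{i}" for i in range(m)]
    headings = headings or ["h0"] * n
    heading_set = heading_set or tuple(dict.fromkeys(headings))
    codes = [f"c{i:03d}" for i in range(n)]
    return PriceTableau(regions=tuple(regions), codes=tuple(codes),
                        headings=tuple(headings),
                        heading_set=tuple(heading_set), prices=prices)


def make_schedule(region, rows, heading_set=None):
    """rows: iterable of (code, heading, price)."""
    items = [ServiceItem(region_id=region, code=c, name=f"svc {c}",
                         heading=h, price=p) for c, h, p in rows]
    heading_set = heading_set or tuple(dict.fromkeys(h for _, h, _ in rows))
    return PriceSchedule(region_id=region, items=items,
                         heading_set=heading_set)


def random_fisher(rng, m, spread=0.1):
    """A valid (positive, reciprocal, diag-1) but non-transitive matrix."""
    v = rng.normal(0.0, 0.5, size=m)
    e = rng.normal(0.0, spread, size=(m, m))
    logf = (v[:, None] - v[None, :]) + (e - e.T) / 2.0
    np.fill_diagonal(logf, 0.0)
    return np.exp(logf)


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


@pytest.fixture
def noise_free_system():
    cfg = SyntheticConfig(noise_sigma=0.0, n_services=25, seed=7)
    schedules, weights, truth = generate_system(cfg)
    return cfg, schedules, weights, truth


@pytest.fixture
def noisy_system():
    cfg = SyntheticConfig(noise_sigma=0.3, n_services=200, seed=11)
    schedules, weights, truth = generate_system(cfg)
    return cfg, schedules, weights, truth
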