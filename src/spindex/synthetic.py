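"""Synthetic multi-region price systems with known ground truth.

Real fee schedules and expenditure weights are administrative data that are
not freely redistributable, so every pipeline stage is exercised on
generated systems instead. The generator emulates the structure of a
provincial medical-services price system: a few regions sharing one basket
of services partitioned into four basic headings, heavily right-skewed
positive prices (log-normal base prices, median around 150 CNY with a long
right tail), region-specific true price-level multipliers lambda_r, optional
per-heading tilts (which create Laspeyres-Paasche spread and hence
non-trivial spanning trees), item-level multiplicative log-normal noise, and
Dirichlet-drawn expenditure-weight vectors. The exact lambda ratios are
returned as a truth record, so recovery can be asserted: with zero noise the
full pipeline returns the configured ratios exactly; with noise the Jevons
estimator of a heading PPP is unbiased for the log ratio with standard
error noise_sigma * sqrt(2/n) per heading.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .schedule_io import (
    DEFAULT_HEADINGS,
    ExpenditureWeights,
    PriceSchedule,
    ServiceItem,
)
from .timeseries import CPISeries

#: Default true price-level multipliers, mirroring the estimated ordering of
#: the four Yangtze River Delta regions (reference region Zhejiang = 1).
DEFAULT_REGION_LEVELS: dict[str, float] = {
    "Shanghai": 1.28,
    "Jiangsu": 0.93,
    "Zhejiang": 1.00,
    "Anhui": 1.03,
}


@dataclass
class SyntheticConfig:
    """Parameters of a generated price system.

    Attributes
    ----------
    region_levels : mapping region -> lambda
        True price-level multipliers (reference region lambda = 1).
    n_services : int
        Services per basic heading (default 750, i.e. ~3,000 matched items
        over the four headings).
    headings : sequence of str
        Basic headings; defaults to the four national categories.
    base_price_log_mu, base_price_log_sigma : float
        Log-normal location/scale of heading-shared base prices
        (defaults give median 150 CNY and a heavy right tail).
    noise_sigma : float
        Std. dev. of item-level log-normal noise, per (item, region).
    heading_tilt : mapping (region, heading) -> multiplier, optional
        Per-heading deviations from lambda_r; default none, so a single
        multiplier per region and exact noise-free recovery.
    weight_alpha : float
        Symmetric Dirichlet concentration for per-region weight draws.
    zero_reference_noise : bool
        Zero the noise of the reference (lambda == 1) region's prices.
    seed : int
        Seed for all randomness; recorded in the truth record.
    """

    region_levels: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_LEVELS))
    n_services: int = 750
    headings: tuple[str, ...] = DEFAULT_HEADINGS
    base_price_log_mu: float = float(np.log(150.0))
    base_price_log_sigma: float = 2.0
    noise_sigma: float = 0.3
    heading_tilt: dict[tuple[str, str], float] = field(default_factory=dict)
    weight_alpha: float = 4.0
    zero_reference_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.region_levels) < 2:
            raise ValidationError("need at least 2 regions")
        if any(l <= 0 for l in self.region_levels.values()):
            raise ValidationError("region levels must be positive")
        if self.n_services < 1:
            raise ValidationError("n_services must be >= 1")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.weight_alpha <= 0:
            raise ValidationError("weight_alpha must be positive")
        if any(t <= 0 for t in self.heading_tilt.values()):
            raise ValidationError("heading tilts must be positive")
        self.headings = tuple(self.headings)


def _tilt(config: SyntheticConfig, region: str, heading: str) -> float:
    return config.heading_tilt.get((region, heading), 1.0)


def generate_system(
    config: SyntheticConfig,
) -> tuple[list[PriceSchedule], dict[str, ExpenditureWeights], dict]:
    """Generate schedules, weights and a ground-truth record.

    Price of service i in region r is
    ``base_i * lambda_r * tilt(r, heading_i) * exp(noise)`` with
    ``noise ~ Normal(0, noise_sigma^2)`` independent per (i, r).
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    regions = list(config.region_levels)
    headings = list(config.headings)
    n = config.n_services

    codes = [f"{hi + 1:02d}{i + 1:05d}" for hi in range(len(headings))
             for i in range(n)]
    svc_headings = [h for h in headings for _ in range(n)]
    base = np.exp(rng.normal(config.base_price_log_mu,
                             config.base_price_log_sigma,
                             size=len(codes)))

    schedules: list[PriceSchedule] = []
    for region in regions:
        lam = config.region_levels[region]
        noise = rng.normal(0.0, config.noise_sigma, size=len(codes))
        if config.zero_reference_noise and lam == 1.0:
            noise[:] = 0.0
        tilt = np.array([_tilt(config, region, h) for h in svc_headings])
        prices = base * lam * tilt * np.exp(noise)
        items = [
            ServiceItem(region_id=region, code=c,
                        name=f"service {c}", heading=h, price=float(p))
            for c, h, p in zip(codes, svc_headings, prices)
        ]
        schedules.append(PriceSchedule(region_id=region, items=items,
                                       heading_set=tuple(headings)))

    weights = {
        region: ExpenditureWeights(
            region_id=region,
            weights=dict(zip(headings, rng.dirichlet(
                np.full(len(headings), config.weight_alpha)))),
        )
        for region in regions
    }

    lam = np.array([config.region_levels[r] for r in regions])
    truth = {
        "seed": config.seed,
        "regions": regions,
        "lambda": {r: config.region_levels[r] for r in regions},
        # exact level of region j with region k as base, per heading
        "heading_ppp": {
            h: [[(config.region_levels[rj] * _tilt(config, rj, h))
                 / (config.region_levels[rk] * _tilt(config, rk, h))
                 for rk in regions] for rj in regions]
            for h in headings
        },
        "level_ratio": (lam[:, None] / lam[None, :]).tolist(),
        "n_services": len(codes),
    }
    return schedules, weights, truth


def generate_cpi(
    regions: Sequence[str],
    years: Sequence[int],
    drift: Mapping[str, float] | float = 102.0,
    sigma: float = 0.01,
    seed: int = 0,
) -> dict[str, CPISeries]:
    """Generate previous-year = 100 CPI series.

    Each year's value is ``drift_r * exp(Normal(0, sigma^2))`` — mean annual
    medical-services inflation of (drift_r - 100)% with lognormal
    year-to-year variation. Deterministic given ``seed``.
    """
    years = [int(y) for y in years]
    if not years or len(set(years)) != len(years):
        raise ValidationError("years must be a non-empty set of distinct years")
    if not isinstance(drift, Mapping):
        drift = {r: float(drift) for r in regions}
    missing = [r for r in regions if r not in drift]
    if missing:
        raise ValidationError(f"no drift for regions {missing}")
    if any(d <= 0 for d in drift.values()):
        raise ValidationError("drift must be positive")
    rng = np.random.default_rng(seed)
    out: dict[str, CPISeries] = {}
    for region in regions:
        vals = drift[region] * np.exp(rng.normal(0.0, sigma, size=len(years)))
        out[region] = CPISeries(region_id=region,
                                values=dict(zip(years, vals)))
    return out
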