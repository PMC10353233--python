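"""Bilateral price indexes between regions.

Within each basic heading the purchasing-power parity between two regions is
the unweighted geometric mean of the matched services' price ratios (the
Jevons elementary index), or equivalently on a complete tableau the
exponentiated region effect of a country-product-dummy (CPD) regression of
log prices on region and service dummies. Heading PPPs are then aggregated
with expenditure weights into Laspeyres (arithmetic mean, base-region
weights), Paasche (harmonic mean, comparison-region weights) and Fisher
(their geometric mean) indexes, plus the Paasche-Laspeyres spread
|log(L/P)| used to weight bilateral links.

Orientation convention, shared with :mod:`spindex.multilateral`: matrix
entry ``[j, k]`` is the price level of region ``j`` expressed with region
``k`` as base, so row = compared region, column = reference region, as in
published comparison tables.

All products of ratios are accumulated in log space: with thousands of
matched services a raw product of price ratios under- or overflows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ComputationError, ValidationError
from .schedule_io import ExpenditureWeights, PriceTableau


@dataclass
class HeadingPPPMatrix:
    """Region x region PPP matrix for one basic heading.

    ``ppp[j, k]`` = price level of region j with region k as base;
    diagonal 1, reciprocal by construction.
    """

    heading: str
    regions: tuple[str, ...]
    ppp: np.ndarray
    n_services: int = 0

    def __post_init__(self) -> None:
        self.ppp = np.asarray(self.ppp, dtype=float)
        m = len(self.regions)
        if self.ppp.shape != (m, m):
            raise ValidationError("PPP matrix shape mismatch")
        if not np.all(np.isfinite(self.ppp)) or np.any(self.ppp <= 0):
            raise ComputationError(
                f"heading {self.heading!r}: PPPs must be positive and finite"
            )


@dataclass
class BilateralIndexSet:
    """All bilateral indexes for every ordered region pair.

    Matrices follow the row-compared / column-base convention; ``pls`` is the
    symmetric Paasche-Laspeyres spread with a zero diagonal.
    """

    regions: tuple[str, ...]
    laspeyres: np.ndarray
    paasche: np.ndarray
    fisher: np.ndarray
    pls: np.ndarray
    heading_ppps: list[HeadingPPPMatrix] = field(default_factory=list)
    meta: dict = field(default_factory=dict)


def _log_price_means(tableau: PriceTableau, heading: str) -> np.ndarray:
    cols = tableau.heading_columns(heading)
    if cols.size == 0:
        raise ComputationError(f"heading {heading!r} has no services")
    return np.log(tableau.prices[:, cols]).mean(axis=1)


def jevons_heading_ppp(tableau: PriceTableau, heading: str) -> HeadingPPPMatrix:
    """Jevons PPP matrix for one basic heading.

    Entry (j, k) is the geometric mean over the heading's services of
    P_ij / P_ik — region j's price level with k as base — computed as
    exp(mean log-price difference).
    """
    mbar = _log_price_means(tableau, heading)
    ppp = np.exp(mbar[:, None] - mbar[None, :])
    np.fill_diagonal(ppp, 1.0)
    return HeadingPPPMatrix(heading=heading, regions=tableau.regions, ppp=ppp,
                            n_services=int(tableau.heading_columns(heading).size))


def cpd_heading_ppp(
    tableau: PriceTableau,
    heading: str,
    base_region: str | None = None,
    mask: np.ndarray | None = None,
) -> HeadingPPPMatrix:
    """Country-product-dummy PPP matrix for one basic heading.

    Fits ``log p_ir = alpha_r + beta_i + eps`` by least squares with the base
    region's effect fixed at 0 (dummy coding) and returns
    ``exp(alpha_j - alpha_k)``. On a complete tableau this coincides with the
    Jevons matrix; ``mask`` (regions x heading-services boolean, True = cell
    observed) permits incomplete tableaus, where the two differ.
    """
    base_region = base_region or tableau.regions[0]
    b = tableau.region_index(base_region)
    cols = tableau.heading_columns(heading)
    if cols.size == 0:
        raise ComputationError(f"heading {heading!r} has no services")
    logp = np.log(tableau.prices[:, cols])
    m, n = logp.shape
    if mask is None:
        mask = np.ones((m, n), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (m, n):
        raise ValidationError("mask shape must be regions x heading services")

    rows = np.repeat(np.arange(m), n)[mask.ravel()]
    svcs = np.tile(np.arange(n), m)[mask.ravel()]
    y = logp.ravel()[mask.ravel()]
    # design: region dummies (base omitted) then service dummies
    region_cols = [r for r in range(m) if r != b]
    X = np.zeros((y.size, (m - 1) + n))
    for c, r in enumerate(region_cols):
        X[rows == r, c] = 1.0
    X[np.arange(y.size), (m - 1) + svcs] = 1.0
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ComputationError(
            f"heading {heading!r}: CPD design is rank-deficient "
            "(too few observed cells to identify all effects)"
        )
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    alpha = np.zeros(m)
    for c, r in enumerate(region_cols):
        alpha[r] = coef[c]
    ppp = np.exp(alpha[:, None] - alpha[None, :])
    np.fill_diagonal(ppp, 1.0)
    return HeadingPPPMatrix(heading=heading, regions=tableau.regions, ppp=ppp,
                            n_services=int(n))


def _aligned(heading_ppps: Sequence[HeadingPPPMatrix],
             weights: ExpenditureWeights) -> tuple[np.ndarray, list[str]]:
    """Heading PPP values stacked in the weight vector's heading order."""
    by_heading = {h.heading: h for h in heading_ppps}
    missing = [h for h in weights.weights if h not in by_heading]
    if missing:
        raise ValidationError(f"no PPP matrix for headings {missing}")
    extra = [h for h in by_heading if h not in weights.weights]
    if extra:
        raise ValidationError(f"no weight for headings {extra}")
    order = [h for h in weights.weights]
    return np.stack([by_heading[h].ppp for h in order]), order


def laspeyres_index(
    heading_ppps: Sequence[HeadingPPPMatrix],
    weights: ExpenditureWeights,
    j: int,
    k: int,
) -> float:
    """Laspeyres index of region j with base k: arithmetic mean of heading
    PPPs under the base region's expenditure weights.

    ``weights`` must be the base region k's weights.
    """
    stack, order = _aligned(heading_ppps, weights)
    w = weights.vector(order)
    return float(np.dot(stack[:, j, k], w))


def paasche_index(
    heading_ppps: Sequence[HeadingPPPMatrix],
    weights: ExpenditureWeights,
    j: int,
    k: int,
) -> float:
    """Paasche index of region j with base k: harmonic mean of heading PPPs
    under the comparison region's expenditure weights.

    ``weights`` must be the compared region j's weights.
    """
    stack, order = _aligned(heading_ppps, weights)
    w = weights.vector(order)
    return float(1.0 / np.dot(1.0 / stack[:, j, k], w))


def fisher_index(laspeyres: float, paasche: float) -> float:
    """Fisher ideal index: geometric mean of Laspeyres and Paasche."""
    if laspeyres <= 0 or paasche <= 0:
        raise ComputationError("Fisher requires positive L and P")
    return math.sqrt(laspeyres * paasche)


def pls_spread(laspeyres: float, paasche: float) -> float:
    """Paasche-Laspeyres spread |log(L/P)|; 0 when the two agree."""
    if laspeyres <= 0 or paasche <= 0:
        raise ComputationError("PLS requires positive L and P")
    return abs(math.log(laspeyres) - math.log(paasche))


def compute_bilateral_set(
    tableau: PriceTableau,
    all_weights: Mapping[str, ExpenditureWeights],
    method: str = "jevons",
) -> BilateralIndexSet:
    """Full bilateral index set for every ordered region pair.

    ``method`` selects the basic-heading estimator (``jevons`` or ``cpd``;
    identical on a complete tableau). Diagonals are exactly 1 (L, P, F)
    and 0 (PLS).
    """
    missing = [r for r in tableau.regions if r not in all_weights]
    if missing:
        raise ValidationError(f"no expenditure weights for regions {missing}")
    for r in tableau.regions:
        if tuple(all_weights[r].weights) != tableau.heading_set:
            w = all_weights[r]
            if set(w.weights) != set(tableau.heading_set):
                raise ValidationError(
                    f"weights for {r!r} cover headings {sorted(w.weights)}, "
                    f"tableau has {sorted(tableau.heading_set)}"
                )

    if method == "jevons":
        hp = [jevons_heading_ppp(tableau, h) for h in tableau.heading_set]
    elif method == "cpd":
        hp = [cpd_heading_ppp(tableau, h) for h in tableau.heading_set]
    else:
        raise ValidationError(f"unknown basic-heading method {method!r}")

    m = tableau.n_regions
    stack = np.stack([h.ppp for h in hp])  # headings x M x M
    W = np.column_stack([
        all_weights[r].vector(tableau.heading_set) for r in tableau.regions
    ])  # headings x M

    L = np.einsum("hjk,hk->jk", stack, W)          # base-region (col) weights
    P = 1.0 / np.einsum("hjk,hj->jk", 1.0 / stack, W)  # compared (row) weights
    F = np.sqrt(L * P)
    pls = np.abs(np.log(L) - np.log(P))
    for M_ in (L, P, F):
        np.fill_diagonal(M_, 1.0)
    np.fill_diagonal(pls, 0.0)
    # enforce exact symmetry of the spread against rounding noise
    pls = 0.5 * (pls + pls.T)
    return BilateralIndexSet(
        regions=tableau.regions, laspeyres=L, paasche=P, fisher=F, pls=pls,
        heading_ppps=hp, meta={"method": method},
    )
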