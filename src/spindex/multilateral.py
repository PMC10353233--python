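"""Transitive multilateral price-level matrices: GEKS and MST methods.

A bilateral Fisher matrix is generally not transitive: comparing two regions
through a third does not reproduce the direct comparison. The GEKS method
(Gini; Eltetö-Köves; Szulc) transitivizes it by geometric averaging over all
bridge regions, treating every region symmetrically. The minimum-spanning-tree
method of Hill instead keeps a subset of the bilateral Fisher links — those
with the smallest Paasche-Laspeyres spread, i.e. the most reliable pairwise
comparisons — chosen as the minimum spanning tree over the complete region
graph with PLS edge weights, and chains Fisher links along tree paths.
Tree paths are unique, so the result is transitive by construction.

Levels follow the row-compared / column-base convention of
:mod:`spindex.bilateral`: ``levels[j, k]`` is region j's price level with
region k as base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ComputationError, ValidationError

Edge = tuple[str, str]


@dataclass
class MultilateralResult:
    """A transitive M x M price-level matrix with its provenance.

    ``tree`` is the spanning tree (undirected edges with PLS weights) for
    the MST method, empty for GEKS.
    """

    method: str
    regions: tuple[str, ...]
    levels: np.ndarray
    tree: list[tuple[str, str, float]] = field(default_factory=list)
    base_region: str | None = None
    meta: dict = field(default_factory=dict)

    def level(self, region: str, base: str) -> float:
        j = self.regions.index(region)
        k = self.regions.index(base)
        return float(self.levels[j, k])


def _check_fisher(fisher: np.ndarray, regions: Sequence[str]) -> np.ndarray:
    fisher = np.asarray(fisher, dtype=float)
    m = len(regions)
    if fisher.ndim != 2 or fisher.shape != (m, m):
        raise ValidationError("Fisher matrix must be square and match regions")
    if not np.all(np.isfinite(fisher)) or np.any(fisher <= 0):
        raise ComputationError("Fisher matrix must be positive and finite")
    return fisher


def geks(fisher: np.ndarray, regions: Sequence[str]) -> MultilateralResult:
    """GEKS multilateral levels from a bilateral Fisher matrix.

    ``levels[j, k]`` is the geometric mean over all bridge regions i of
    ``F[j, i] * F[i, k]``, computed in log space. The result is transitive
    and reciprocal; an already-transitive input is returned unchanged.
    """
    fisher = _check_fisher(fisher, regions)
    logf = np.log(fisher)
    # mean_i (log F[j,i] + log F[i,k])
    loglevels = (logf.mean(axis=1)[:, None] + logf.mean(axis=0)[None, :])
    levels = np.exp(loglevels)
    np.fill_diagonal(levels, 1.0)
    return MultilateralResult(method="GEKS", regions=tuple(regions),
                              levels=levels)


def build_mst(pls: np.ndarray, regions: Sequence[str]) -> list[tuple[str, str, float]]:
    """Minimum spanning tree over regions with PLS edge weights.

    Kruskal's greedy algorithm with edges taken in ascending
    ``(weight, region pair)`` order, so ties in edge weight are broken by
    lexicographic region-pair order and the tree is deterministic.
    """
    pls = np.asarray(pls, dtype=float)
    m = len(regions)
    if m < 2:
        raise ValidationError("MST needs at least 2 regions")
    if pls.shape != (m, m):
        raise ValidationError("PLS matrix must be square and match regions")
    if np.any(pls < 0) or not np.allclose(pls, pls.T):
        raise ValidationError("PLS matrix must be symmetric and non-negative")

    candidates = sorted(
        (float(pls[i, j]),) + tuple(sorted((regions[i], regions[j])))
        for i in range(m) for j in range(i + 1, m)
    )
    parent = {r: r for r in regions}

    def find(r: str) -> str:
        while parent[r] != r:
            parent[r] = parent[parent[r]]
            r = parent[r]
        return r

    tree: list[tuple[str, str, float]] = []
    for w, u, v in candidates:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            tree.append((u, v, w))
        if len(tree) == m - 1:
            break
    return sorted(tree)


def mst_levels(
    tree: Sequence[tuple[str, str, float]] | Sequence[Edge],
    fisher: np.ndarray,
    regions: Sequence[str],
) -> MultilateralResult:
    """Chain bilateral Fisher links along tree paths into transitive levels.

    ``levels[j, k]`` is the product of Fisher indexes along the unique tree
    path from base k to region j, each step oriented as
    F[step_to, step_from]. Tree-adjacent pairs therefore reproduce the
    bilateral Fisher index exactly.
    """
    fisher = _check_fisher(fisher, regions)
    regions = tuple(regions)
    idx = {r: i for i, r in enumerate(regions)}
    t = nx.Graph()
    t.add_nodes_from(regions)
    norm_tree: list[tuple[str, str, float]] = []
    for e in tree:
        u, v = e[0], e[1]
        w = float(e[2]) if len(e) > 2 else float("nan")
        if u not in idx or v not in idx:
            raise ValidationError(f"tree edge ({u!r}, {v!r}) outside regions")
        t.add_edge(u, v)
        norm_tree.append((u, v, w) if u <= v else (v, u, w))
    if t.number_of_edges() != len(regions) - 1 or not nx.is_connected(t):
        raise ValidationError("tree must span all regions with M-1 edges")

    m = len(regions)
    levels = np.ones((m, m))
    logf = np.log(fisher)
    paths = dict(nx.all_pairs_shortest_path(t))
    for k, base in enumerate(regions):
        for j, reg in enumerate(regions):
            if j == k:
                continue
            path = paths[base][reg]
            levels[j, k] = np.exp(sum(
                logf[idx[b], idx[a]] for a, b in zip(path, path[1:])
            ))
    return MultilateralResult(method="MST", regions=regions, levels=levels,
                              tree=sorted(norm_tree))


def rebase(
    result: MultilateralResult,
    base_region: str,
    scale: float = 100.0,
    decimals: int | None = 2,
) -> pd.DataFrame:
    """Presentation matrix: rows = regions, columns = reference regions.

    Every column is scaled so its own reference region reads ``scale``
    (transitivity makes the relative levels base-invariant, so rebasing only
    selects which column to read). Rounding is half-even and presentation
    only; the result's internal levels stay unrounded. The chosen
    ``base_region`` is recorded in ``DataFrame.attrs``.
    """
    if base_region not in result.regions:
        raise ValidationError(f"unknown region {base_region!r}")
    mat = result.levels * scale
    df = pd.DataFrame(mat, index=list(result.regions),
                      columns=list(result.regions))
    if decimals is not None:
        # numpy rounds half-even, matching published-table convention
        df = df.round(decimals)
    df.attrs.update(base_region=base_region, scale=scale,
                    method=result.method)
    return df
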