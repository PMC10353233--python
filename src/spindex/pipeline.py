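"""End-to-end orchestration: config in, published-table-shaped outputs out.

`run_pipeline` wires the library stages together — read schedules, match,
bilateral indexes, multilateral levels, optional back-cast — and writes
delimited matrices plus a JSON run report carrying provenance metadata
(input file hashes, settings in effect, package version). The command-line
interface in :mod:`spindex.cli` is a thin wrapper around this module.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .bilateral import compute_bilateral_set
from .errors import ValidationError
from .multilateral import build_mst, geks, mst_levels, rebase
from .schedule_io import (
    DEFAULT_HEADINGS,
    Dialect,
    match_services,
    read_schedule,
    read_weights,
)
from .timeseries import backcast_levels, levels_to_frame, read_cpi

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``schedules`` maps region id to its price-schedule file; weights (and
    optionally CPI) tables have one row per region. ``ref_region`` sets the
    presentation base; methods select the basic-heading estimator and the
    multilateral method(s).
    """

    schedules: dict[str, str]
    weights: str
    ref_region: str
    cpi: str | None = None
    heading_set: tuple[str, ...] = DEFAULT_HEADINGS
    heading_method: str = "jevons"
    multilateral: str = "both"  # geks | mst | both
    ref_year: int | None = None
    span: tuple[int, int] | None = None
    outdir: str = "spindex-out"
    decimals: int = 2
    keep_highest: bool = False
    dialect: Dialect = field(default_factory=Dialect)

    def __post_init__(self) -> None:
        if len(self.schedules) < 2:
            raise ValidationError("config must list at least 2 schedules")
        if self.ref_region not in self.schedules:
            raise ValidationError(
                f"reference region {self.ref_region!r} not among schedules"
            )
        if self.multilateral not in ("geks", "mst", "both"):
            raise ValidationError(
                f"unknown multilateral method {self.multilateral!r}"
            )
        for region, path in self.schedules.items():
            if not Path(path).exists():
                raise ValidationError(f"schedule for {region!r}: no file {path}")
        if not Path(self.weights).exists():
            raise ValidationError(f"no weights file {self.weights}")
        if self.cpi is not None and not Path(self.cpi).exists():
            raise ValidationError(f"no CPI file {self.cpi}")


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline and write outputs under ``config.outdir``.

    Deterministic given its inputs. Returns the run report (also written as
    ``report.json``): matrices written, MST edge list, matched/excluded item
    counts, input hashes and all settings in effect.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    schedules = [
        read_schedule(path, region, dialect=config.dialect,
                      heading_set=config.heading_set,
                      keep_highest=config.keep_highest)
        for region, path in config.schedules.items()
    ]
    tableau = match_services(schedules)
    weights = read_weights(config.weights, heading_set=config.heading_set)
    bil = compute_bilateral_set(tableau, weights, method=config.heading_method)

    report: dict = {
        "package": "spindex",
        "version": __import__("spindex").__version__,
        "inputs": {
            "schedules": {r: {"path": p, "sha256": _sha256(p)}
                          for r, p in config.schedules.items()},
            "weights": {"path": config.weights,
                        "sha256": _sha256(config.weights)},
        },
        "settings": {
            "heading_method": config.heading_method,
            "multilateral": config.multilateral,
            "ref_region": config.ref_region,
            "decimals": config.decimals,
            "keep_highest": config.keep_highest,
            "matching_key": "code",
            "quartile_method": "linear interpolation",
        },
        "matching": tableau.meta,
        "outputs": {},
    }

    def emit(name: str, df) -> None:
        path = outdir / f"{name}.csv"
        df.to_csv(path)
        report["outputs"][name] = str(path)

    emit("fisher", rebase_like(bil.fisher, bil.regions, config))
    results = {}
    if config.multilateral in ("geks", "both"):
        results["geks"] = geks(bil.fisher, bil.regions)
    if config.multilateral in ("mst", "both"):
        tree = build_mst(bil.pls, bil.regions)
        results["mst"] = mst_levels(tree, bil.fisher, bil.regions)
        report["mst_tree"] = [list(e) for e in tree]
    for name, res in results.items():
        emit(name, rebase(res, config.ref_region, decimals=config.decimals))

    if config.cpi is not None:
        if config.ref_year is None or config.span is None:
            raise ValidationError("CPI back-cast needs ref_year and span")
        cpi = read_cpi(config.cpi)
        base = results.get("geks") or next(iter(results.values()))
        levels = backcast_levels(base, cpi, config.ref_region,
                                 config.ref_year, config.span)
        emit("levels_by_year", levels_to_frame(levels).set_index("region"))
        report["inputs"]["cpi"] = {"path": config.cpi,
                                   "sha256": _sha256(config.cpi)}

    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    logger.info("pipeline outputs written to %s", outdir)
    return report


def rebase_like(matrix, regions, config: RunConfig):
    """Base-100 presentation of a bilateral matrix (same shape as rebase)."""
    import pandas as pd
    df = pd.DataFrame(matrix * 100.0, index=list(regions),
                      columns=list(regions))
    return df.round(config.decimals)
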