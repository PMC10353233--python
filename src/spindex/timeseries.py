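"""Back-casting a reference-year spatial comparison with CPI series.

A multilateral comparison is benchmarked in one reference year. Earlier
years' levels are obtained by deflating each region's reference-year level
with its own CPI-for-medical-services series, then re-expressing the whole
panel relative to the reference region at the reference year (= 100). This
is pure deflation: the cross-region comparability of earlier years is
inherited from the reference year, a deliberately preliminary construction
— no year-specific re-matching of services is attempted.

The default CPI convention is "previous year = 100" (the Chinese statistical
yearbook convention); ``convention='fixed_base'`` accepts series already on
a common base year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError
from .multilateral import MultilateralResult


@dataclass
class CPISeries:
    """One region's CPI for medical services, year -> index value."""

    region_id: str
    values: dict[int, float]
    convention: str = "previous_year"

    def __post_init__(self) -> None:
        self.values = {int(y): float(v) for y, v in self.values.items()}
        if any(v <= 0 or not np.isfinite(v) for v in self.values.values()):
            raise ValidationError(
                f"region {self.region_id!r}: CPI values must be positive"
            )
        if self.convention not in ("previous_year", "fixed_base"):
            raise ValidationError(f"unknown CPI convention {self.convention!r}")


@dataclass
class LevelSeries:
    """One region's back-cast price levels, year -> level (ref = 100)."""

    region_id: str
    values: dict[int, float]
    meta: dict = field(default_factory=dict)


def backcast_levels(
    base_levels: MultilateralResult,
    cpi: Mapping[str, CPISeries],
    ref_region: str,
    ref_year: int,
    span: tuple[int, int],
) -> dict[str, LevelSeries]:
    """Back-cast reference-year levels over ``span`` = (first, last) years.

    With the previous-year convention, level(r, t) is the reference-year
    level divided by the accumulated inflation factors
    prod_{s=t+1..ref_year} CPI_r(s)/100; a fixed-base series contributes
    CPI_r(t)/CPI_r(ref_year) directly. The panel is then scaled so the
    reference region at the reference year reads exactly 100.
    """
    first, last = int(span[0]), int(span[1])
    if first > last:
        raise ValidationError(f"invalid span {span}")
    if last > ref_year:
        raise ValidationError("span may not extend past the reference year")
    if ref_region not in base_levels.regions:
        raise ValidationError(f"unknown reference region {ref_region!r}")

    k = base_levels.regions.index(ref_region)
    out: dict[str, LevelSeries] = {}
    for j, region in enumerate(base_levels.regions):
        if region not in cpi:
            raise ValidationError(f"no CPI series for region {region!r}")
        series = cpi[region]
        ref_level = float(base_levels.levels[j, k]) * 100.0
        values: dict[int, float] = {}
        for year in range(last, first - 1, -1):
            if series.convention == "previous_year":
                factor = 1.0
                for s in range(year + 1, ref_year + 1):
                    if s not in series.values:
                        raise ValidationError(
                            f"region {region!r}: missing CPI for year {s}"
                        )
                    factor *= series.values[s] / 100.0
                values[year] = ref_level / factor
            else:  # fixed_base
                for y in (year, ref_year):
                    if y not in series.values:
                        raise ValidationError(
                            f"region {region!r}: missing CPI for year {y}"
                        )
                values[year] = (ref_level * series.values[year]
                                / series.values[ref_year])
        out[region] = LevelSeries(
            region_id=region, values=dict(sorted(values.items())),
            meta={"ref_region": ref_region, "ref_year": ref_year,
                  "cpi_convention": series.convention},
        )
    return out


def read_cpi(path: str | Path, convention: str = "previous_year",
             sep: str | None = None) -> dict[str, CPISeries]:
    """Read a CPI table (rows = regions, columns = years)."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    if sep is None:
        head = path.read_text().splitlines()[:1]
        sep = "\t" if head and "\t" in head[0] else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    try:
        years = [int(c) for c in df.columns]
    except ValueError as exc:
        raise SchemaError(f"{path}: CPI columns must be years") from exc
    return {
        str(r): CPISeries(region_id=str(r),
                          values=dict(zip(years, row.astype(float))),
                          convention=convention)
        for r, row in df.iterrows()
    }


def levels_to_frame(levels: Mapping[str, LevelSeries]) -> pd.DataFrame:
    """Tidy long-format table (region, year, level)."""
    rows = [
        {"region": r, "year": y, "level": v}
        for r, ls in levels.items() for y, v in sorted(ls.values.items())
    ]
    return pd.DataFrame(rows)


def plot_levels(levels: Mapping[str, LevelSeries], path: str | Path) -> None:
    """Line chart of back-cast price levels over time, one line per region."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for region, ls in levels.items():
        years = sorted(ls.values)
        ax.plot(years, [ls.values[y] for y in years], marker="o", label=region)
    ax.set_xlabel("year")
    ax.set_ylabel("price level (reference = 100)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
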