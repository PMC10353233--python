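"""Regional price schedules: reading, validation, cross-region matching.

A *price schedule* is one region's fee table for medical services: one row per
service with a national-specification code, a name, a basic-heading category
and a price in CNY. Schedules from several regions are cross-matched on the
service code to form a complete regions x services *price tableau*, the input
to every index computation. Expenditure weights over the basic headings are
read from a companion table, one row per region.
"""

from __future__ import annotations

import logging
import math
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ComputationError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: The four basic headings of the Chinese national specification of medical
#: services, used as the default category set.
DEFAULT_HEADINGS: tuple[str, ...] = (
    "general medical services",
    "medical diagnosis services",
    "clinical treatment services",
    "traditional medicine services",
)


@dataclass(frozen=True)
class ServiceItem:
    """One priced medical service in one region."""

    region_id: str
    code: str
    name: str
    heading: str
    price: float


@dataclass
class PriceSchedule:
    """A region's validated price schedule.

    Attributes
    ----------
    region_id : str
        Region identifier.
    items : list of ServiceItem
        All services, each carrying ``region_id``.
    heading_set : tuple of str
        Ordered basic headings every item must belong to.
    meta : dict
        Read/validation report (rejected rows, source path, ...).
    """

    region_id: str
    items: list[ServiceItem]
    heading_set: tuple[str, ...] = DEFAULT_HEADINGS
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heading_set = tuple(self.heading_set)
        seen: set[str] = set()
        dups: list[str] = []
        for it in self.items:
            if it.region_id != self.region_id:
                raise ValidationError(
                    f"item {it.code!r} carries region {it.region_id!r}, "
                    f"schedule is {self.region_id!r}"
                )
            if not it.code:
                raise ValidationError("empty service code")
            if it.heading not in self.heading_set:
                raise ValidationError(
                    f"service {it.code!r}: unknown heading {it.heading!r} "
                    f"(expected one of {list(self.heading_set)})"
                )
            if not math.isfinite(it.price) or it.price < 0:
                raise ValidationError(
                    f"service {it.code!r}: price must be finite and >= 0, "
                    f"got {it.price!r}"
                )
            if it.code in seen:
                dups.append(it.code)
            seen.add(it.code)
        if dups:
            raise ValidationError(
                f"duplicate service codes in region {self.region_id!r}: "
                f"{sorted(set(dups))}"
            )

    def prices(self) -> np.ndarray:
        return np.array([it.price for it in self.items], dtype=float)

    def __len__(self) -> int:
        return len(self.items)


@dataclass
class PriceTableau:
    """Complete regions x matched-services price matrix.

    ``prices[r, s]`` is the price of service ``codes[s]`` in ``regions[r]``;
    every cell is finite and strictly positive. Columns are partitioned into
    basic headings via ``headings`` (one label per service code).
    """

    regions: tuple[str, ...]
    codes: tuple[str, ...]
    headings: tuple[str, ...]
    heading_set: tuple[str, ...]
    prices: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.regions = tuple(self.regions)
        self.codes = tuple(self.codes)
        self.headings = tuple(self.headings)
        self.heading_set = tuple(self.heading_set)
        self.prices = np.asarray(self.prices, dtype=float)
        m, n = len(self.regions), len(self.codes)
        if m < 2:
            raise ValidationError("a tableau needs at least 2 regions")
        if self.prices.shape != (m, n):
            raise ValidationError(
                f"price matrix shape {self.prices.shape} != ({m}, {n})"
            )
        if len(self.headings) != n:
            raise ValidationError("one heading label per service required")
        bad = set(self.headings) - set(self.heading_set)
        if bad:
            raise ValidationError(f"headings outside heading_set: {sorted(bad)}")
        for h in self.heading_set:
            if h not in self.headings:
                raise ValidationError(f"basic heading {h!r} has no services")
        if not np.all(np.isfinite(self.prices)) or np.any(self.prices <= 0):
            raise ValidationError("tableau must be complete with prices > 0")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_services(self) -> int:
        return len(self.codes)

    def heading_columns(self, heading: str) -> np.ndarray:
        """Column indices of the services in ``heading``."""
        if heading not in self.heading_set:
            raise ValidationError(f"unknown heading {heading!r}")
        return np.array([i for i, h in enumerate(self.headings) if h == heading])

    def region_index(self, region_id: str) -> int:
        try:
            return self.regions.index(region_id)
        except ValueError:
            raise ValidationError(f"unknown region {region_id!r}") from None

    def to_frame(self) -> pd.DataFrame:
        """Regions x services DataFrame with a heading row attached as attrs."""
        df = pd.DataFrame(self.prices, index=list(self.regions),
                          columns=list(self.codes))
        df.attrs["headings"] = dict(zip(self.codes, self.headings))
        return df


@dataclass
class ExpenditureWeights:
    """Per-region expenditure shares over the basic headings (sum to 1)."""

    region_id: str
    weights: dict[str, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = np.array(list(self.weights.values()), dtype=float)
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValidationError(
                f"region {self.region_id!r}: weights must be finite and >= 0"
            )
        total = vals.sum()
        if total <= 0:
            raise ValidationError(f"region {self.region_id!r}: weights sum to 0")
        if abs(total - 1.0) > 1e-9:
            if abs(total - 1.0) > 1e-6:
                self.meta["renormalized_from"] = float(total)
                logger.warning(
                    "weights for %s summed to %.6g; renormalized", self.region_id, total
                )
            self.weights = {h: w / total for h, w in self.weights.items()}

    def vector(self, heading_order: Sequence[str]) -> np.ndarray:
        """Weights as an array aligned to ``heading_order``."""
        missing = [h for h in heading_order if h not in self.weights]
        if missing:
            raise ValidationError(
                f"region {self.region_id!r}: no weight for headings {missing}"
            )
        return np.array([self.weights[h] for h in heading_order], dtype=float)


@dataclass(frozen=True)
class Dialect:
    """Column-name and format mapping for delimited/spreadsheet inputs."""

    code: str = "code"
    name: str = "name"
    heading: str = "category"
    price: str = "price"
    sep: str | None = None  # None: sniff comma vs tab
    decimal: str = "."
    encoding: str = "utf-8"


def _read_table(path: str | Path, dialect: Dialect) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    if path.suffix.lower() in {".xlsx", ".xls"}:
        return pd.read_excel(path, dtype=str)
    sep = dialect.sep
    if sep is None:
        head = path.read_text(encoding=dialect.encoding).splitlines()[:1]
        sep = "\t" if head and "\t" in head[0] else ","
    return pd.read_csv(path, sep=sep, dtype=str, encoding=dialect.encoding,
                       skipinitialspace=True)


def read_schedule(
    path: str | Path,
    region_id: str,
    dialect: Dialect | None = None,
    heading_set: Sequence[str] = DEFAULT_HEADINGS,
    keep_highest: bool = False,
) -> PriceSchedule:
    """Read one region's price schedule from a delimited or spreadsheet file.

    Rows whose price cannot be parsed as a non-negative number are rejected
    and reported in ``schedule.meta['rejected_rows']``, never silently
    dropped. With ``keep_highest``, multiple rows per code (price tiers) are
    reduced to the maximum-price row before validation.

    Raises
    ------
    SchemaError
        If the file or a required column is missing.
    ValidationError
        On duplicate codes or unknown heading labels.
    """
    dialect = dialect or Dialect()
    df = _read_table(path, dialect)
    required = {
        "code": dialect.code, "name": dialect.name,
        "heading": dialect.heading, "price": dialect.price,
    }
    for logical, col in required.items():
        if col not in df.columns:
            raise SchemaError(
                f"{path}: missing required column {col!r} (maps to {logical!r})"
            )

    raw_price = df[dialect.price].astype(str)
    if dialect.decimal != ".":
        raw_price = raw_price.str.replace(dialect.decimal, ".", regex=False)

    def _parse(s: str) -> float:
        # float() is correctly rounded; pandas' fast parser is not
        try:
            return float(s.replace(",", ""))
        except ValueError:
            return float("nan")

    price = raw_price.map(_parse)
    bad = price.isna() | ~np.isfinite(price) | (price < 0)
    rejected = [
        {"row": int(i), "code": str(df[dialect.code].iloc[i]),
         "price": str(df[dialect.price].iloc[i])}
        for i in np.flatnonzero(bad.to_numpy())
    ]
    if rejected:
        logger.warning("%s: rejected %d rows with unparseable prices",
                       path, len(rejected))
    keep = df.loc[~bad.to_numpy()].assign(_price=price[~bad.to_numpy()])

    if keep_highest:
        keep = (keep.sort_values("_price")
                .drop_duplicates(subset=dialect.code, keep="last"))

    items = [
        ServiceItem(region_id=region_id,
                    code=str(row[dialect.code]).strip(),
                    name=str(row[dialect.name]).strip(),
                    heading=str(row[dialect.heading]).strip(),
                    price=float(row["_price"]))
        for _, row in keep.iterrows()
    ]
    sched = PriceSchedule(region_id=region_id, items=items,
                          heading_set=tuple(heading_set))
    sched.meta.update(source=str(path), rejected_rows=rejected,
                      n_read=int(len(df)), n_kept=len(items))
    return sched


def write_schedule(schedule: PriceSchedule, path: str | Path,
                   dialect: Dialect | None = None) -> None:
    """Write a schedule back to delimited text (inverse of read_schedule)."""
    dialect = dialect or Dialect()
    df = pd.DataFrame(
        {dialect.code: [it.code for it in schedule.items],
         dialect.name: [it.name for it in schedule.items],
         dialect.heading: [it.heading for it in schedule.items],
         dialect.price: [repr(it.price) for it in schedule.items]}
    )
    df.to_csv(path, sep=dialect.sep or ",", index=False,
              encoding=dialect.encoding)


def _norm_name(name: str) -> str:
    return " ".join(unicodedata.normalize("NFKC", name).casefold().split())


@dataclass(frozen=True)
class MatchingRule:
    """How services are matched across regions.

    ``key='code'`` (default) matches on exact service-code equality, the
    national-specification key. ``name_fallback`` additionally matches, by
    case/whitespace-folded name, codes present in only some regions.
    """

    key: str = "code"
    name_fallback: bool = False


def match_services(
    schedules: Sequence[PriceSchedule],
    rule: MatchingRule | None = None,
) -> PriceTableau:
    """Cross-match schedules into a complete price tableau.

    Only services present in *all* regions under the matching key are kept;
    any matched service priced <= 0 in at least one region is excluded (a
    geometric mean of price ratios requires positive prices) and counted in
    ``tableau.meta['excluded_nonpositive']``. Columns are ordered by sorted
    code, making the result independent of the schedule order.
    """
    rule = rule or MatchingRule()
    if len(schedules) < 2:
        raise ValidationError("matching needs at least 2 schedules")
    hsets = {s.heading_set for s in schedules}
    if len(hsets) != 1:
        raise ValidationError("schedules declare inconsistent heading sets")
    heading_set = schedules[0].heading_set

    maps: list[dict[str, ServiceItem]] = []
    for s in schedules:
        by_key: dict[str, ServiceItem] = {}
        for it in s.items:
            k = it.code if rule.key == "code" else _norm_name(it.name)
            by_key[k] = it
        if rule.name_fallback and rule.key == "code":
            for it in s.items:
                by_key.setdefault(_norm_name(it.name), it)
        maps.append(by_key)

    common = set(maps[0])
    for m in maps[1:]:
        common &= set(m)
    if not common:
        raise ValidationError("no comparable items across regions")

    codes, headings, cols = [], [], []
    excluded_nonpositive = 0
    heading_conflicts = []
    for key in sorted(common):
        items = [m[key] for m in maps]
        hs = {it.heading for it in items}
        if len(hs) > 1:
            heading_conflicts.append(key)
            continue
        p = np.array([it.price for it in items])
        if np.any(p <= 0):
            excluded_nonpositive += 1
            continue
        codes.append(items[0].code)
        headings.append(items[0].heading)
        cols.append(p)
    if heading_conflicts:
        raise ValidationError(
            "matched services mapped to different headings across regions: "
            f"{heading_conflicts[:20]}"
        )
    if not codes:
        raise ValidationError("no comparable items with positive prices")

    regions = tuple(s.region_id for s in schedules)
    tableau = PriceTableau(
        regions=regions, codes=tuple(codes), headings=tuple(headings),
        heading_set=heading_set, prices=np.column_stack(cols),
    )
    tableau.meta.update(
        matched=len(codes),
        excluded_nonpositive=excluded_nonpositive,
        per_region_input={s.region_id: len(s) for s in schedules},
        matching_key=rule.key,
    )
    logger.info("matched %d services across %d regions (%d excluded for "
                "non-positive prices)", len(codes), len(regions),
                excluded_nonpositive)
    return tableau


def describe_schedule(schedule: PriceSchedule) -> dict[str, float]:
    """Descriptive price statistics: mean, max, min, median, Q1, Q3.

    Quartiles use linear interpolation between order statistics (the
    convention numpy calls ``linear``), recorded in the output.
    """
    if not schedule.items:
        raise ComputationError(f"empty schedule for {schedule.region_id!r}")
    p = schedule.prices()
    q1, med, q3 = np.percentile(p, [25, 50, 75])
    return {
        "region_id": schedule.region_id,
        "n": int(p.size),
        "mean": float(p.mean()),
        "max": float(p.max()),
        "min": float(p.min()),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "quartile_method": "linear interpolation",
    }


def read_weights(
    path: str | Path,
    heading_set: Sequence[str] = DEFAULT_HEADINGS,
    region_id: str | None = None,
    sep: str | None = None,
) -> dict[str, ExpenditureWeights] | ExpenditureWeights:
    """Read expenditure weights (rows = regions, columns = basic headings).

    Returns a mapping region -> ExpenditureWeights, or a single
    ExpenditureWeights when ``region_id`` is given. Shares are renormalized
    to sum to 1; deviations beyond 1e-6 are recorded in ``meta``.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    if sep is None:
        head = path.read_text().splitlines()[:1]
        sep = "\t" if head and "\t" in head[0] else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    missing = [h for h in heading_set if h not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing heading columns {missing}")
    extra = [c for c in df.columns if c not in heading_set]
    if extra:
        raise SchemaError(f"{path}: unexpected heading columns {extra}")
    out: dict[str, ExpenditureWeights] = {}
    for region, row in df.iterrows():
        out[str(region)] = ExpenditureWeights(
            region_id=str(region),
            weights={h: float(row[h]) for h in heading_set},
        )
    if region_id is not None:
        if region_id not in out:
            raise ValidationError(f"{path}: no weights row for {region_id!r}")
        return out[region_id]
    return out


def write_weights(weights: Mapping[str, ExpenditureWeights],
                  path: str | Path,
                  heading_set: Sequence[str] = DEFAULT_HEADINGS) -> None:
    """Write a region x heading weight table (inverse of read_weights)."""
    rows = {r: [w.weights[h] for h in heading_set] for r, w in weights.items()}
    pd.DataFrame.from_dict(rows, orient="index",
                           columns=list(heading_set)).to_csv(path)
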