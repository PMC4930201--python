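"""Turn raw monthly/annual series into the normalised candidate table.

Monthly series are annually and seasonally averaged; every resulting annual
column is max-normalised — positive-only series into [0, 1], mixed-sign
series into [-1, 1] — so that series spanning very different magnitudes
(e.g. fish abundance ~1e7 vs. climate indices ~1e0) become comparable and
only their dynamics matter.  Missing years are carried as NaN and never
interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RawSeries",
    "SeasonScheme",
    "FeatureTable",
    "CLIMATE_SEASONS",
    "HYDROGRAPHIC_SEASONS",
    "monthly_to_annual",
    "seasonal_average",
    "normalize",
    "assemble_feature_table",
    "read_csv_inputs",
    "write_feature_table",
]

CATEGORIES = ("physical", "bottom_up", "top_down", "target")

# Season -> ordered (year offset, month) pairs.  Offset -1 means the month
# belongs to the PREVIOUS calendar year (December in the climate winter of
# year Y is Dec(Y-1), the standard DJF convention).
CLIMATE_SEASONS: dict[str, list[tuple[int, int]]] = {
    "winter": [(-1, 12), (0, 1), (0, 2)],
    "spring": [(0, 3), (0, 4), (0, 5)],
    "summer": [(0, 6), (0, 7), (0, 8)],
    "autumn": [(0, 9), (0, 10), (0, 11)],
}

# Hydrographic seasons lag one month behind climatic: winter is Jan-Mar, etc.
HYDROGRAPHIC_SEASONS: dict[str, list[tuple[int, int]]] = {
    "winter": [(0, 1), (0, 2), (0, 3)],
    "spring": [(0, 4), (0, 5), (0, 6)],
    "summer": [(0, 7), (0, 8), (0, 9)],
    "autumn": [(0, 10), (0, 11), (0, 12)],
}

SEASON_TAGS = {"winter": "w", "spring": "sp", "summer": "sm", "autumn": "a"}


@dataclass
class SeasonScheme:
    """A partition of twelve consecutive months into four seasons."""

    dialect: str
    mapping: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.mapping:
            if self.dialect == "climate":
                self.mapping = CLIMATE_SEASONS
            elif self.dialect == "hydrographic":
                self.mapping = HYDROGRAPHIC_SEASONS
            else:
                raise ValueError(f"unknown season dialect: {self.dialect!r}")
        months = [m for spec in self.mapping.values() for (_, m) in spec]
        if sorted(months) != list(range(1, 13)):
            raise ValueError("seasons must partition the 12 months exactly once")

    @property
    def seasons(self) -> list[str]:
        return list(self.mapping)


@dataclass
class RawSeries:
    """A single named time series with per-series metadata.

    ``values`` maps either ``year -> value`` (annual) or
    ``(year, month) -> value`` (monthly); missing entries are simply absent
    or NaN.
    """

    name: str
    category: str
    frequency: str
    values: dict
    season_dialect: str = "none"
    units: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.frequency not in ("monthly", "annual"):
            raise ValueError(f"unknown frequency {self.frequency!r}")
        clean = {k: v for k, v in self.values.items() if v is not None and np.isfinite(v)}
        if not clean:
            raise ValueError(f"series {self.name!r} has no non-missing value")
        self.values = dict(sorted(clean.items()))


@dataclass
class FeatureTable:
    """Year-indexed matrix of normalised candidate columns plus the target.

    ``data`` holds candidate columns (NaN marks a missing year), ``target``
    the normalised target series aligned on the same years, and ``meta`` one
    row per candidate column (base variable, season tag or "annual",
    category).
    """

    data: pd.DataFrame
    target: pd.Series
    target_name: str
    meta: pd.DataFrame

    @property
    def years(self) -> np.ndarray:
        return self.data.index.to_numpy()

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def column_array(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)


def monthly_to_annual(series: RawSeries, min_months: int = 4) -> RawSeries:
    """Average a monthly series to annual values.

    A year is kept only when at least ``min_months`` months are present; the
    default of 4 discards yearly averages built from 3 or fewer monthly
    values, which are too unreliable to use.
    """
    if series.frequency != "monthly":
        raise ValueError(f"series {series.name!r} is not monthly")
    by_year: dict[int, list[float]] = {}
    for (year, _month), v in series.values.items():
        by_year.setdefault(year, []).append(v)
    annual = {
        y: float(np.mean(vals)) for y, vals in by_year.items() if len(vals) >= min_months
    }
    if not annual:
        raise ValueError(f"series {series.name!r}: no year with >= {min_months} months")
    return RawSeries(
        name=series.name,
        category=series.category,
        frequency="annual",
        values=annual,
        season_dialect=series.season_dialect,
        units=series.units,
    )


def seasonal_average(
    series: RawSeries, scheme: SeasonScheme, season: str, year: int, min_months: int = 2
) -> float:
    """Mean of one season of one year, or NaN when too few months exist.

    Months with a negative year offset (December in the climate winter)
    are read from the previous calendar year.
    """
    if series.frequency != "monthly":
        raise ValueError(f"series {series.name!r} is not monthly")
    if season not in scheme.mapping:
        raise ValueError(f"unknown season {season!r} for dialect {scheme.dialect!r}")
    vals = [
        series.values[(year + off, month)]
        for off, month in scheme.mapping[season]
        if (year + off, month) in series.values
    ]
    if len(vals) < min_months:
        return float("nan")
    return float(np.mean(vals))


def normalize(values: np.ndarray | list) -> np.ndarray:
    """Max-normalise a sequence; NaNs pass through.

    All-non-negative input is divided by its maximum (range [0, 1]);
    input with any negative value is divided by the maximum absolute value
    (range [-1, 1]).  Either way some entry attains absolute value 1.
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size == 0:
        raise ValueError("cannot normalise an all-missing sequence")
    denom = float(np.max(np.abs(finite)))
    if denom == 0.0:
        raise ValueError("cannot normalise an all-zero sequence")
    return arr / denom


def _seasonal_series(series: RawSeries, years: range) -> dict[str, dict[int, float]]:
    """Annual + four seasonal expansions of one monthly, dialect-tagged series."""
    scheme = SeasonScheme(series.season_dialect)
    out: dict[str, dict[int, float]] = {}
    annual = monthly_to_annual(series)
    out[series.name] = annual.values
    for season in scheme.seasons:
        tag = SEASON_TAGS[season]
        col: dict[int, float] = {}
        for y in years:
            v = seasonal_average(series, scheme, season, y)
            if np.isfinite(v):
                col[y] = v
        if col:
            out[f"{tag}{series.name}"] = col
    return out


def assemble_feature_table(
    series: list[RawSeries], expand_seasons: bool = True
) -> FeatureTable:
    """Build the normalised candidate table from raw series.

    Each monthly, season-dialect-tagged series contributes one annual plus
    four seasonal columns; every other series contributes one annual column.
    Exactly one input must carry category ``target``; it is normalised the
    same way but stored separately from the candidates.
    """
    if not series:
        raise ValueError("no input series")
    targets = [s for s in series if s.category == "target"]
    if len(targets) != 1:
        raise ValueError(f"need exactly one target series, got {len(targets)}")

    # Year span across all inputs (monthly keys are (year, month) tuples).
    def _series_years(s: RawSeries):
        if s.frequency == "annual":
            return [int(k) for k in s.values]
        return [int(k[0]) for k in s.values]

    all_years = sorted({y for s in series for y in _series_years(s)})
    years = range(all_years[0], all_years[-1] + 1)

    columns: dict[str, dict[int, float]] = {}
    meta_rows: list[dict] = []

    def _add(name: str, vals: dict[int, float], base: str, season: str, cat: str) -> None:
        if name in columns:
            raise ValueError(f"duplicate column name after expansion: {name!r}")
        columns[name] = vals
        meta_rows.append({"name": name, "base": base, "season": season, "category": cat})

    for s in series:
        if s.category == "target":
            continue
        if s.frequency == "monthly" and s.season_dialect != "none" and expand_seasons:
            for name, vals in _seasonal_series(s, years).items():
                season = "annual" if name == s.name else name[: len(name) - len(s.name)]
                season_name = {v: k for k, v in SEASON_TAGS.items()}.get(season, "annual")
                _add(name, vals, s.name, season_name, s.category)
        else:
            annual = s if s.frequency == "annual" else monthly_to_annual(s)
            _add(s.name, annual.values, s.name, "annual", s.category)

    tgt = targets[0]
    tgt_annual = tgt if tgt.frequency == "annual" else monthly_to_annual(tgt)
    if tgt.name in columns:
        raise ValueError(f"target name {tgt.name!r} collides with a candidate column")

    idx = pd.Index(list(years), name="year")
    data = pd.DataFrame(
        {name: pd.Series(vals, dtype=float) for name, vals in columns.items()},
        index=idx,
    )
    data = data.dropna(axis=1, how="all")
    data = data.apply(lambda col: pd.Series(normalize(col.to_numpy()), index=col.index))

    target = pd.Series(tgt_annual.values, index=idx, dtype=float)
    target = pd.Series(normalize(target.to_numpy()), index=idx, name=tgt.name)

    meta = pd.DataFrame([r for r in meta_rows if r["name"] in data.columns])
    return FeatureTable(data=data, target=target, target_name=tgt.name, meta=meta)


def read_csv_inputs(data_csv: str, meta_csv: str) -> list[RawSeries]:
    """Read a wide data CSV (first column ``year``) plus a metadata CSV.

    Monthly series use fractional encoding in the metadata only; the wide
    CSV layout supports annual data directly and monthly data via a
    ``month`` column alongside ``year``.
    """
    meta = pd.read_csv(meta_csv)
    required = {"name", "category", "frequency", "season_dialect"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata CSV must have columns {sorted(required)}")
    df = pd.read_csv(data_csv)
    if "year" not in df.columns:
        raise ValueError("data CSV must have a 'year' column")
    monthly_layout = "month" in df.columns

    out: list[RawSeries] = []
    for row in meta.itertuples(index=False):
        name = row.name
        if name not in df.columns:
            raise ValueError(f"series {name!r} listed in metadata but absent from data CSV")
        values: dict = {}
        if row.frequency == "monthly":
            if not monthly_layout:
                raise ValueError("monthly series require a 'month' column in the data CSV")
            for y, m, v in zip(df["year"], df["month"], df[name]):
                if np.isfinite(v):
                    values[(int(y), int(m))] = float(v)
        else:
            sub = df if not monthly_layout else df.drop_duplicates("year")
            for y, v in zip(sub["year"], sub[name]):
                if np.isfinite(v):
                    values[int(y)] = float(v)
        out.append(
            RawSeries(
                name=name,
                category=row.category,
                frequency=row.frequency,
                values=values,
                season_dialect=row.season_dialect,
                units=getattr(row, "units", "") or "",
            )
        )
    return out


def write_feature_table(table: FeatureTable, data_csv: str, meta_csv: str) -> None:
    """Write the normalised table as wide CSV plus a companion metadata CSV."""
    wide = table.data.copy()
    wide[table.target_name] = table.target
    wide.to_csv(data_csv)
    meta = table.meta.copy()
    meta.to_csv(meta_csv, index=False)
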