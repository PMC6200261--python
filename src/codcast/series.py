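"""Annual time series: data model, CSV I/O and preprocessing.

The whole pipeline trades in one currency: a named scalar series on
consecutive calendar years, with explicit missing values (NaN).  Gaps in the
calendar are never dropped -- a year that has no observation is present with
a missing value, so that every lag is a plain integer offset between year
labels and never index arithmetic on a compacted array.

Preprocessing mirrors standard practice for hydrographic/stock series:
anomalies relative to a fixed baseline window, linear detrending, a running-
mean high-pass split, and harvest rate (catch / total stock biomass).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    AlignmentError,
    BaselineError,
    CodcastError,
    SeriesFormatError,
    SeriesLengthError,
)

__all__ = [
    "AnnualSeries",
    "AlignedDesign",
    "read_series",
    "write_series",
    "to_anomalies",
    "detrend_linear",
    "lowpass",
    "highpass",
    "harvest_rate",
    "align",
]


@dataclass
class AnnualSeries:
    """A named annual scalar time series on consecutive calendar years.

    Parameters
    ----------
    name : str
        Identifier, e.g. ``"AMO"`` or ``"TSB"``.
    years : array of int
        Strictly increasing, consecutive calendar years.
    values : array of float
        Same length as *years*; missing values are NaN.
    units : str
        Free-text units (may be empty).
    """

    name: str
    years: np.ndarray
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.ndim != 1 or self.values.ndim != 1:
            raise SeriesFormatError(f"{self.name}: years/values must be 1-D")
        if len(self.years) != len(self.values):
            raise SeriesFormatError(
                f"{self.name}: {len(self.years)} years vs {len(self.values)} values"
            )
        if len(self.years) and not np.all(np.diff(self.years) == 1):
            raise SeriesFormatError(
                f"{self.name}: years must be consecutive integers "
                "(represent gaps as missing values)"
            )
        if np.isfinite(self.values).sum() < 2:
            raise SeriesFormatError(
                f"{self.name}: needs at least 2 non-missing values"
            )

    # -- basic accessors ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.years)

    @property
    def start_year(self) -> int:
        return int(self.years[0])

    @property
    def end_year(self) -> int:
        return int(self.years[-1])

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of non-missing entries."""
        return np.isfinite(self.values)

    def value(self, year: int) -> float:
        """Value in *year* (NaN if missing or outside the span)."""
        if year < self.start_year or year > self.end_year:
            return float("nan")
        return float(self.values[year - self.start_year])

    def values_at(self, years: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`value`."""
        years = np.asarray(years, dtype=int)
        out = np.full(len(years), np.nan)
        inside = (years >= self.start_year) & (years <= self.end_year)
        out[inside] = self.values[years[inside] - self.start_year]
        return out

    def with_values(self, values: np.ndarray, name: str | None = None,
                    units: str | None = None) -> "AnnualSeries":
        return AnnualSeries(
            name=self.name if name is None else name,
            years=self.years.copy(),
            values=np.asarray(values, dtype=float),
            units=self.units if units is None else units,
        )

    def equals(self, other: "AnnualSeries", atol: float = 0.0) -> bool:
        return (
            self.name == other.name
            and np.array_equal(self.years, other.years)
            and np.allclose(self.values, other.values, atol=atol, rtol=0.0,
                            equal_nan=True)
        )


@dataclass
class AlignedDesign:
    """A complete-case regression design built by lag-aware alignment.

    Row *i* pairs the predictand value in ``years[i]`` with each predictor's
    value ``lead`` years earlier; only years where the predictand and every
    lagged predictor are non-missing appear.
    """

    predictand: str
    predictor_names: list[str]
    leads: list[int]
    years: np.ndarray          # design row years (predictand years)
    y: np.ndarray
    X: np.ndarray              # (n_rows, n_predictors)
    orthogonalized: bool = False
    degenerate: list[str] = field(default_factory=list)
    # affine map from the original augmented design [1 X] to the current
    # columns; identity unless orthogonalized
    transform: np.ndarray | None = None

    @property
    def n_rows(self) -> int:
        return len(self.years)

    @property
    def n_predictors(self) -> int:
        return self.X.shape[1]

    def augmented(self) -> np.ndarray:
        """Design with a leading column of ones."""
        return np.column_stack([np.ones(self.n_rows), self.X])


# -- I/O -------------------------------------------------------------------


def read_series(path: str | Path, name: str | None = None,
                units: str = "") -> AnnualSeries:
    """Read a two-column ``year,value`` CSV (one header line, UTF-8).

    Missing values are empty fields.  Non-consecutive input years are
    densified: the returned series covers the full year range with missing
    values inserted for absent years.
    """
    path = Path(path)
    rows: dict[int, float] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            next(reader)  # header
        except StopIteration:
            raise SeriesFormatError(f"{path}: empty file") from None
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2:
                raise SeriesFormatError(f"{path}:{lineno}: expected 2 columns")
            try:
                year = int(row[0].strip())
            except ValueError:
                raise SeriesFormatError(
                    f"{path}:{lineno}: unparseable year {row[0]!r}"
                ) from None
            raw = row[1].strip()
            if raw == "":
                value = float("nan")
            else:
                try:
                    value = float(raw)
                except ValueError:
                    raise SeriesFormatError(
                        f"{path}:{lineno}: unparseable value {row[1]!r}"
                    ) from None
            if year in rows:
                raise SeriesFormatError(
                    f"{path}:{lineno}: duplicate year {year}"
                )
            rows[year] = value
    if not rows:
        raise SeriesFormatError(f"{path}: no data rows")
    years = np.arange(min(rows), max(rows) + 1)
    values = np.array([rows.get(int(y), float("nan")) for y in years])
    return AnnualSeries(name=name or path.stem, years=years, values=values,
                        units=units)


def write_series(series: AnnualSeries, path: str | Path) -> None:
    """Write ``year,value`` CSV; missing values become empty fields.

    Values are written with shortest round-trip float formatting so that
    ``read_series(write_series(s))`` reproduces *s* exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["year", "value"])
        for year, value in zip(series.years, series.values):
            writer.writerow([int(year), "" if not np.isfinite(value)
                             else repr(float(value))])


# -- preprocessing ---------------------------------------------------------


def to_anomalies(series: AnnualSeries, baseline_start: int = 1950,
                 baseline_end: int = 2012) -> AnnualSeries:
    """Departures from the mean over a fixed baseline window.

    The baseline mean uses non-missing years inside
    [*baseline_start*, *baseline_end*] only; at least 10 are required.
    """
    in_window = (series.years >= baseline_start) & (series.years <= baseline_end)
    usable = in_window & series.mask
    if usable.sum() < 10:
        raise BaselineError(
            f"{series.name}: only {int(usable.sum())} non-missing years in "
            f"baseline {baseline_start}-{baseline_end} (need >= 10)"
        )
    return series.with_values(series.values - series.values[usable].mean())


def detrend_linear(series: AnnualSeries) -> AnnualSeries:
    """Remove the OLS straight line fit to (year, value) pairs.

    Missing values stay missing; needs >= 3 non-missing values.
    """
    mask = series.mask
    if mask.sum() < 3:
        raise SeriesLengthError(
            f"{series.name}: need >= 3 non-missing values to detrend"
        )
    t = series.years[mask] - series.years[mask].mean()
    slope, intercept = np.polyfit(t, series.values[mask], 1)
    trend = slope * (series.years - series.years[mask].mean()) + intercept
    out = series.values - trend
    out[~mask] = np.nan
    return series.with_values(out)


def lowpass(series: AnnualSeries, cutoff_years: int = 5) -> AnnualSeries:
    """Centered running mean of width *cutoff_years* (edges use the
    available window; missing values are skipped within each window)."""
    if cutoff_years < 2:
        raise CodcastError(f"cutoff_years must be >= 2, got {cutoff_years}")
    if len(series) < cutoff_years:
        raise SeriesLengthError(
            f"{series.name}: length {len(series)} < cutoff {cutoff_years}"
        )
    half = (cutoff_years - 1) // 2
    # for even cutoffs the window is shifted one year toward the past
    left, right = cutoff_years - 1 - half, half
    values = series.values
    out = np.full_like(values, np.nan)
    for i in range(len(values)):
        window = values[max(0, i - left): i + right + 1]
        finite = window[np.isfinite(window)]
        if finite.size:
            out[i] = finite.mean()
    out[~series.mask] = np.nan
    return series.with_values(out)


def highpass(series: AnnualSeries, cutoff_years: int = 5) -> AnnualSeries:
    """Series minus its :func:`lowpass`; ``highpass + lowpass == original``
    exactly on non-missing years."""
    lp = lowpass(series, cutoff_years)
    return series.with_values(series.values - lp.values)


def harvest_rate(catch: AnnualSeries, tsb: AnnualSeries) -> AnnualSeries:
    """Annual catch divided by total stock biomass on the year intersection.

    Dimensionless relative measure of fishing effort; TSB must be strictly
    positive wherever both series are observed.
    """
    start = max(catch.start_year, tsb.start_year)
    end = min(catch.end_year, tsb.end_year)
    if start > end:
        raise AlignmentError(
            f"no overlap: {catch.name} {catch.start_year}-{catch.end_year} vs "
            f"{tsb.name} {tsb.start_year}-{tsb.end_year}"
        )
    years = np.arange(start, end + 1)
    c = catch.values_at(years)
    b = tsb.values_at(years)
    both = np.isfinite(c) & np.isfinite(b)
    if np.any(b[both] <= 0):
        bad = years[both][b[both] <= 0]
        raise CodcastError(f"{tsb.name} <= 0 in year(s) {bad.tolist()}")
    out = np.full(len(years), np.nan)
    out[both] = c[both] / b[both]
    return AnnualSeries(name="harvest_rate", years=years, values=out, units="")


# -- alignment -------------------------------------------------------------


def align(predictand: AnnualSeries,
          predictors_with_leads: Sequence[tuple[AnnualSeries, int]],
          ) -> AlignedDesign:
    """Build the complete-case design pairing y_i with x_{i-l,n}.

    Each predictor comes with its own lead l >= 0 (years by which it leads
    the predictand).  A design row exists for year i exactly when y_i and
    every x_{i-l_n,n} are non-missing.
    """
    for series, lead in predictors_with_leads:
        if lead < 0:
            raise AlignmentError(f"{series.name}: negative lead {lead}")
    years = predictand.years
    cols = []
    complete = predictand.mask.copy()
    for series, lead in predictors_with_leads:
        col = series.values_at(years - lead)
        complete &= np.isfinite(col)
        cols.append(col)
    if not complete.any():
        coverage = ", ".join(
            f"{s.name} (lead {l}): {s.start_year}-{s.end_year}"
            for s, l in predictors_with_leads
        )
        raise AlignmentError(
            f"no complete rows aligning {predictand.name} "
            f"({predictand.start_year}-{predictand.end_year}) with {coverage}"
        )
    X = (np.column_stack(cols)[complete]
         if cols else np.empty((int(complete.sum()), 0)))
    return AlignedDesign(
        predictand=predictand.name,
        predictor_names=[s.name for s, _ in predictors_with_leads],
        leads=[int(l) for _, l in predictors_with_leads],
        years=years[complete],
        y=predictand.values[complete],
        X=X,
    )
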