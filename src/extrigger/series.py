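"""Yearly abundance timeseries for a single-population threatened species.

The raw input to every analysis in this package is a sequence of
(calendar year, observed abundance) pairs for one population.  Years must be
strictly increasing integers (gaps between survey years are allowed; elapsed
time is always measured in calendar years), abundances are non-negative reals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AbundanceSeries", "SeriesFormatError", "read_series", "write_series"]


class SeriesFormatError(ValueError):
    """Raised when an abundance CSV or series violates the input contract."""


@dataclass(frozen=True)
class AbundanceSeries:
    """Observed (year, abundance) pairs for one population.

    Parameters
    ----------
    years : array-like of int
        Calendar years, strictly increasing.
    abundances : array-like of float
        Observed abundance in each year, non-negative.
    """

    years: np.ndarray
    abundances: np.ndarray
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        years = np.asarray(self.years)
        abund = np.asarray(self.abundances, dtype=float)
        if years.ndim != 1 or abund.ndim != 1:
            raise SeriesFormatError("years and abundances must be 1-D")
        if len(years) != len(abund):
            raise SeriesFormatError("years and abundances differ in length")
        if len(years) == 0:
            raise SeriesFormatError("empty series")
        if not np.all(np.isfinite(years)) or np.any(years != np.round(years)):
            raise SeriesFormatError("years must be finite integers")
        years = years.astype(int)
        if np.any(np.diff(years) <= 0):
            raise SeriesFormatError("years must be strictly increasing")
        if not np.all(np.isfinite(abund)):
            raise SeriesFormatError("abundances must be finite")
        if np.any(abund < 0):
            raise SeriesFormatError("abundances must be non-negative")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "abundances", abund)

    def __len__(self) -> int:
        return len(self.years)

    @property
    def first_year(self) -> int:
        return int(self.years[0])

    @property
    def last_year(self) -> int:
        return int(self.years[-1])

    @property
    def first_abundance(self) -> float:
        return float(self.abundances[0])

    @property
    def last_abundance(self) -> float:
        return float(self.abundances[-1])

    def truncate(self, year: int) -> "AbundanceSeries":
        """Return the sub-series of observations up to and including `year`."""
        mask = self.years <= year
        if not mask.any():
            raise SeriesFormatError(f"no observations at or before year {year}")
        return AbundanceSeries(self.years[mask], self.abundances[mask], name=self.name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "abundance": self.abundances})


def read_series(path) -> AbundanceSeries:
    """Read an abundance timeseries from a two-column CSV.

    The file must have a header row naming the columns ``year`` and
    ``abundance``.  Blank lines are ignored.  Malformed rows are reported with
    their line number (1-based, counting the header as line 1).
    """
    df = pd.read_csv(path, skip_blank_lines=True, comment="#")
    cols = {c.strip().lower(): c for c in df.columns}
    if "year" not in cols or "abundance" not in cols:
        raise SeriesFormatError(
            f"{path}: expected columns 'year' and 'abundance', found {list(df.columns)}"
        )
    years = pd.to_numeric(df[cols["year"]], errors="coerce")
    abund = pd.to_numeric(df[cols["abundance"]], errors="coerce")
    # pandas drops blank lines before assigning the RangeIndex, so row k of the
    # frame is data line k+2 only when the file has no blanks; reconstruct line
    # numbers from the raw text instead.
    line_of_row = _data_line_numbers(path, len(df))
    for row, (y, a) in enumerate(zip(years, abund)):
        if pd.isna(y) or pd.isna(a):
            raise SeriesFormatError(
                f"{path}: non-numeric value on line {line_of_row[row]}"
            )
        if a < 0:
            raise SeriesFormatError(
                f"{path}: negative abundance on line {line_of_row[row]}"
            )
    yr = years.to_numpy()
    if np.any(yr != np.round(yr)):
        bad = int(np.argmax(yr != np.round(yr)))
        raise SeriesFormatError(f"{path}: non-integer year on line {line_of_row[bad]}")
    if np.any(np.diff(yr) <= 0):
        bad = int(np.argmax(np.diff(yr) <= 0)) + 1
        raise SeriesFormatError(
            f"{path}: years not strictly increasing at line {line_of_row[bad]}"
        )
    return AbundanceSeries(yr.astype(int), abund.to_numpy(dtype=float))


def _data_line_numbers(path, n_rows: int) -> list[int]:
    """Physical line number of each data row, skipping blanks and comments."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            lines = fh.readlines()
    except (TypeError, OSError):  # file-like object already consumed
        return [r + 2 for r in range(n_rows)]
    numbers = []
    seen_header = False
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if not seen_header:
            seen_header = True
            continue
        numbers.append(lineno)
    if len(numbers) < n_rows:  # fallback, should not happen
        numbers += [numbers[-1] + k + 1 if numbers else k + 2 for k in range(n_rows - len(numbers))]
    return numbers


def write_series(series: AbundanceSeries, path) -> None:
    """Write a series as a `year,abundance` CSV (round-trips with read_series)."""
    series.to_frame().to_csv(path, index=False)
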