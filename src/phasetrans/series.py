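"""Time-series containers, CSV ingestion, and elementary windowed statistics.

Everything downstream (complexity, entropy, spectral, recurrence,
synchronization, change-point layers) operates on the two containers defined
here:

* :class:`TimeSeries` — an ordered, equidistantly sampled sequence of real
  observations with a 1-based time origin ``t0``.
* :class:`DerivedSeries` — the output of a trailing-window indicator, which is
  shorter than its source; it remembers the window width and the original
  time index of its first value so that every derived position can be mapped
  back onto the raw time axis.

Windowed indicators use **trailing** alignment throughout: the value computed
from observations ``t-w+1 .. t`` is assigned to time ``t``.  This is the only
alignment usable for prospective monitoring (no future data enter a value).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd


class DegenerateSeriesError(ValueError):
    """Raised when an operation is undefined on the input (e.g. zero variance)."""


class CsvFormatError(ValueError):
    """Raised on malformed CSV input; the message names the offending row."""


def _as_float_array(values: Sequence[float]) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("series values must be one-dimensional")
    if arr.size < 1:
        raise ValueError("series must contain at least one value")
    if not np.all(np.isfinite(arr)):
        raise ValueError("series must not contain missing or non-finite values")
    return arr


@dataclass(frozen=True)
class TimeSeries:
    """Equidistant univariate series with a 1-based integer time origin."""

    values: np.ndarray
    label: str = "x"
    t0: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", _as_float_array(self.values))

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Original time indices, ``t0 .. t0+N-1``."""
        return np.arange(self.t0, self.t0 + len(self))


@dataclass(frozen=True)
class DerivedSeries:
    """Trailing-window indicator series.

    ``offset`` is the original time index of the first derived value; for a
    window of width ``w`` over a source starting at ``t0`` it equals
    ``t0 + w - 1``.  Derived position ``i`` (1-based) corresponds to original
    time ``offset + i - 1``.  Undefined values (e.g. an all-flat
    synchronization window) are stored as NaN and skipped by downstream
    consumers together with their time stamp.
    """

    values: np.ndarray
    window: int
    offset: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("derived series must be a nonempty 1-d sequence")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.offset, self.offset + len(self))


@dataclass(frozen=True)
class MultiSeries:
    """Several equal-length series observed on the same time axis."""

    columns: tuple[TimeSeries, ...]

    def __post_init__(self) -> None:
        cols = tuple(self.columns)
        if len(cols) < 1:
            raise ValueError("MultiSeries needs at least one column")
        n = len(cols[0])
        if any(len(c) != n for c in cols):
            raise ValueError("all columns must have identical length")
        labels = [c.label for c in cols]
        if len(set(labels)) != len(labels):
            raise ValueError("column labels must be distinct")
        if any(c.t0 != cols[0].t0 for c in cols):
            raise ValueError("all columns must share the same time origin")
        object.__setattr__(self, "columns", cols)

    def __len__(self) -> int:
        return len(self.columns[0])

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.columns]

    @property
    def t0(self) -> int:
        return self.columns[0].t0

    def matrix(self) -> np.ndarray:
        """N x V value matrix (rows = time)."""
        return np.column_stack([c.values for c in self.columns])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix(), columns=self.labels)


SeriesLike = Union[TimeSeries, DerivedSeries]


def z_transform(s: TimeSeries) -> TimeSeries:
    """Standardize to mean 0, sample SD 1 (ddof=1).

    All series entering the transition pipeline are z-transformed first so
    that indicators computed on different variables share a common scale.
    Raises :class:`DegenerateSeriesError` on constant input.
    """
    if len(s) < 2:
        raise DegenerateSeriesError("z-transform needs at least 2 points")
    sd = float(np.std(s.values, ddof=1))
    if sd == 0.0:
        raise DegenerateSeriesError("z-transform undefined for zero-variance series")
    z = (s.values - np.mean(s.values)) / sd
    return TimeSeries(z, label=s.label, t0=s.t0)


def _source_offset(s: SeriesLike) -> int:
    return s.offset if isinstance(s, DerivedSeries) else s.t0


def _windows(values: np.ndarray, w: int) -> np.ndarray:
    if w > values.size:
        raise ValueError(f"window {w} exceeds series length {values.size}")
    return np.lib.stride_tricks.sliding_window_view(values, w)


def moving_average(s: SeriesLike, w: int) -> DerivedSeries:
    """Trailing-window arithmetic mean; value for window ``t-w+1..t`` sits at ``t``."""
    if w < 1:
        raise ValueError("window must be >= 1")
    out = _windows(s.values, w).mean(axis=1)
    return DerivedSeries(out, window=w, offset=_source_offset(s) + w - 1)


def moving_variance(s: SeriesLike, w: int) -> DerivedSeries:
    """Trailing-window sample variance (denominator ``w - 1``)."""
    if w < 2:
        raise ValueError("moving variance needs window >= 2")
    out = _windows(s.values, w).var(axis=1, ddof=1)
    return DerivedSeries(out, window=w, offset=_source_offset(s) + w - 1)


# ---------------------------------------------------------------------------
# CSV ingestion
# ---------------------------------------------------------------------------

_TIME_NAMES = {"t", "time", "index", "day", "iteration"}


def _looks_like_header(fields: list[str]) -> bool:
    for f in fields:
        try:
            float(f)
        except ValueError:
            return True
    return False


def read_csv(
    path: str | Path,
    *,
    column: str | None = None,
    columns: Sequence[str] | None = None,
    time_column: str | None = None,
    t0: int = 1,
) -> TimeSeries | MultiSeries:
    """Read a plain comma-separated file of one column per variable.

    A header row is auto-detected (any non-numeric cell in the first row).
    A leading time/index column named like ``t``/``time``/``index`` is dropped
    automatically; ``time_column`` names one explicitly.  ``column`` selects a
    single variable (returns :class:`TimeSeries`), ``columns`` a subset
    (returns :class:`MultiSeries`); by default all variables are returned, as
    a TimeSeries when there is exactly one.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    if not first.strip():
        raise CsvFormatError(f"{path}: empty file")
    has_header = _looks_like_header([f.strip() for f in first.rstrip("\n").split(",")])

    try:
        df = pd.read_csv(path, header=0 if has_header else None, dtype=str,
                         skip_blank_lines=True)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise CsvFormatError(f"{path}: {exc}") from exc
    if not has_header:
        df.columns = [f"x{i + 1}" for i in range(df.shape[1])]

    if time_column is None:
        for name in df.columns:
            if str(name).strip().lower() in _TIME_NAMES:
                time_column = str(name)
                break
    if time_column is not None and time_column in df.columns:
        df = df.drop(columns=[time_column])

    if column is not None:
        if column not in df.columns:
            raise CsvFormatError(f"{path}: no column named {column!r}")
        df = df[[column]]
    elif columns is not None:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise CsvFormatError(f"{path}: no column(s) named {missing}")
        df = df[list(columns)]

    header_rows = 1 if has_header else 0
    parsed = {}
    for name in df.columns:
        col = pd.to_numeric(df[name], errors="coerce")
        bad = col.index[col.isna() & df[name].notna()]
        if len(bad) > 0:
            row = int(bad[0]) + 1 + header_rows
            raise CsvFormatError(
                f"{path}: non-numeric value {df[name].iloc[bad[0]]!r} "
                f"in column {name!r}, row {row}"
            )
        if col.isna().any():
            row = int(col.index[col.isna()][0]) + 1 + header_rows
            raise CsvFormatError(f"{path}: missing value in column {name!r}, row {row}")
        parsed[str(name)] = col.to_numpy(dtype=float)

    series = [TimeSeries(v, label=k, t0=t0) for k, v in parsed.items()]
    if len(series) == 1:
        return series[0]
    return MultiSeries(tuple(series))


def write_csv(obj: TimeSeries | MultiSeries, path: str | Path) -> None:
    """Write a series (or multivariate set) back to CSV with a header row."""
    if isinstance(obj, TimeSeries):
        df = pd.DataFrame({obj.label: obj.values})
    else:
        df = obj.to_frame()
    df.to_csv(path, index=False)
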